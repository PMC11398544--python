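"""Vessel segments and geometry-to-parameter maps.

Each anatomical branch (a length of artery between bifurcations) maps to a
single segment carrying Poiseuille resistance, inertance, compliance and an
optional quadratic stenosis loss  dP = S * |Q| * Q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

BLOOD_DENSITY = 1.06      # g/cm^3
BLOOD_VISCOSITY = 0.04    # dyn*s/cm^2 (poise)

# Effective wall stiffness E*h/r used by the linear compliance map; a single
# documented constant (dyn/cm^2) chosen to give arterial-scale distensibility.
WALL_STIFFNESS = 8.0e5

# Empirical expansion-loss coefficient for the quadratic stenosis law.
STENOSIS_KT = 1.52


def poiseuille_resistance(length: float, diameter: float,
                          viscosity: float = BLOOD_VISCOSITY) -> float:
    """R = 128 * mu * l / (pi * d^4)."""
    return 128.0 * viscosity * length / (np.pi * diameter**4)


def inertance(length: float, diameter: float, density: float = BLOOD_DENSITY) -> float:
    """L = 4 * rho * l / (pi * d^2)."""
    return 4.0 * density * length / (np.pi * diameter**2)


def compliance(length: float, diameter: float,
               wall_stiffness: float = WALL_STIFFNESS) -> float:
    """Linear compliance per unit length: C = 3 * pi * d^3 * l / (16 * Eh/r)."""
    return 3.0 * np.pi * diameter**3 * length / (16.0 * wall_stiffness)


def stenosis_coefficient(diameter: float, severity: float,
                         density: float = BLOOD_DENSITY,
                         kt: float = STENOSIS_KT) -> float:
    """Quadratic-loss coefficient S (dyn*s^2/cm^8) from diameter-reduction
    severity in [0, 1):  S = Kt * rho / (2*A0^2) * (A0/As - 1)^2 with
    As = A0 * (1 - severity)^2.  severity == 0 gives S == 0."""
    if not (0.0 <= severity < 1.0):
        raise ValueError(f"stenosis severity must be in [0, 1), got {severity}")
    if severity == 0.0:
        return 0.0
    a0 = np.pi * diameter**2 / 4.0
    a_s = a0 * (1.0 - severity) ** 2
    return kt * density / (2.0 * a0**2) * (a0 / a_s - 1.0) ** 2


def stenosis_pressure_loss(S: float, Q: float) -> float:
    """dP = S * |Q| * Q; odd in Q."""
    if S < 0:
        raise ValueError("stenosis coefficient must be >= 0")
    return S * abs(Q) * Q


@dataclass
class VesselSegment:
    """One branch of the arterial tree as a lumped R-L-C(+S) segment."""

    id: str
    length: float      # cm
    diameter: float    # cm
    resistance: float
    capacitance: float
    inductance: float
    stenosis_coefficient: float = 0.0
    parent: str | None = None
    is_outlet: bool = False
    perfuses_lv: bool = False
    outlet_xyz: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"segment {self.id}: length and diameter must be > 0")
        for attr in ("resistance", "capacitance", "inductance", "stenosis_coefficient"):
            if getattr(self, attr) < 0:
                raise ValueError(f"segment {self.id}: {attr} must be >= 0")

    @classmethod
    def from_geometry(cls, id: str, length: float, diameter: float,
                      severity: float = 0.0,
                      resistance_fn: Callable = poiseuille_resistance,
                      compliance_fn: Callable = compliance,
                      inertance_fn: Callable = inertance,
                      **kwargs) -> "VesselSegment":
        if length <= 0 or diameter <= 0:
            raise ValueError(f"segment {id}: length and diameter must be > 0")
        return cls(
            id=id, length=length, diameter=diameter,
            resistance=resistance_fn(length, diameter),
            capacitance=compliance_fn(length, diameter),
            inductance=inertance_fn(length, diameter),
            stenosis_coefficient=stenosis_coefficient(diameter, severity),
            **kwargs,
        )
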