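"""Time-varying elastance heart chambers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HeartChamber:
    """Elastance chamber: P(t, V) = E(t) * (V - V0).

    E(t) ramps smoothly from ``elastance_min`` to ``elastance_max`` and back
    over the activation window using a double-cosine ("two-Hill"-style)
    shape.  Units are CGS: elastances in dyn/cm^2 per mL, volumes in mL.
    """

    name: str
    elastance_max: float
    elastance_min: float
    activation_onset: float
    activation_duration: float
    unstressed_volume: float = 0.0
    initial_volume: float = 100.0
    period: float = 0.8

    def __post_init__(self) -> None:
        if not (self.elastance_max >= self.elastance_min > 0):
            raise ValueError("require elastance_max >= elastance_min > 0")
        if not (0.0 <= self.activation_duration <= self.period):
            raise ValueError("activation_duration must lie in [0, period]")

    def activation(self, t: float) -> float:
        """Normalized activation in [0, 1]; double-cosine in the window."""
        if self.activation_duration == 0.0:
            return 0.0
        tau = (t - self.activation_onset) % self.period
        if tau >= self.activation_duration:
            return 0.0
        x = tau / self.activation_duration
        # rise over the first 2/3, relax over the last 1/3
        if x < 2.0 / 3.0:
            return 0.5 * (1.0 - np.cos(np.pi * x / (2.0 / 3.0)))
        return 0.5 * (1.0 + np.cos(np.pi * (x - 2.0 / 3.0) / (1.0 / 3.0)))

    def elastance(self, t: float) -> float:
        a = self.activation(t)
        return self.elastance_min + (self.elastance_max - self.elastance_min) * a

    def pressure(self, volume: float, t: float) -> float:
        """Chamber pressure at time t (t reduced modulo the period)."""
        return self.elastance(t) * (volume - self.unstressed_volume)


def chamber_pressure(chamber: HeartChamber, volume: float, t: float) -> float:
    """Functional form of :meth:`HeartChamber.pressure`."""
    return chamber.pressure(volume, t)
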