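"""Outlet boundary conditions: aortic Windkessel and coronary beds."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass
class WindkesselBC:
    """Three-element RCR Windkessel: proximal R, compliance, distal R."""

    Rp: float
    C: float
    Rd: float
    Pref: float = 0.0

    def __post_init__(self) -> None:
        if min(self.Rp, self.C, self.Rd) < 0:
            raise ValueError("Windkessel parameters must be >= 0")

    @property
    def total_resistance(self) -> float:
        return self.Rp + self.Rd


@dataclass
class CoronaryOutletBC:
    """Coronary outlet bed: Ra - Ca - Ramicro - Cim - Rv, with the Cim
    capacitor referenced to an intramyocardial pressure source."""

    Ra: float
    Ramicro: float
    Rv: float
    Ca: float
    Cim: float
    im_pressure_source: str = "lv"   # chamber driving the intramyocardial pressure
    im_scale: float = 1.0            # fraction of chamber pressure applied

    def __post_init__(self) -> None:
        if min(self.Ra, self.Ramicro, self.Rv, self.Ca, self.Cim) < 0:
            raise ValueError("coronary BC parameters must be >= 0")

    @property
    def total_resistance(self) -> float:
        return self.Ra + self.Ramicro + self.Rv

    def scaled(self, factor: float) -> "CoronaryOutletBC":
        """Return a copy with all resistances scaled by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return replace(self, Ra=self.Ra * factor, Ramicro=self.Ramicro * factor,
                       Rv=self.Rv * factor)

    @classmethod
    def from_total(cls, total: float, split=(0.32, 0.52, 0.16),
                   Ca: float = 1e-6, Cim: float = 1e-5, **kwargs) -> "CoronaryOutletBC":
        """Distribute a total distal resistance over Ra/Ramicro/Rv."""
        fa, fm, fv = split
        if abs(fa + fm + fv - 1.0) > 1e-9:
            raise ValueError("resistance split fractions must sum to 1")
        return cls(Ra=total * fa, Ramicro=total * fm, Rv=total * fv,
                   Ca=Ca, Cim=Cim, **kwargs)
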