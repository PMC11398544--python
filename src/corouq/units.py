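"""Unit conversion constants.

All internal computations use CGS units (dyn, cm, s).  Pressures are
dyn/cm^2, flows cm^3/s, resistances dyn*s/cm^5.  Conversions to clinical
units (mmHg, mL/min) happen only at I/O boundaries.
"""

MMHG_TO_DYNCM2 = 1333.22387415
DYNCM2_TO_MMHG = 1.0 / MMHG_TO_DYNCM2

MLMIN_TO_CM3S = 1.0 / 60.0
CM3S_TO_MLMIN = 60.0


def mmhg(p_dyncm2: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return p_dyncm2 * DYNCM2_TO_MMHG


def dyncm2(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYNCM2
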