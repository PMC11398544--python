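"""Closed-loop circulation network: anatomy ingestion, boundary conditions,
hyperemia scaling, Murray-law resistance splitting, and transient simulation."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ..units import dyncm2
from . import system as sy
from .boundary import CoronaryOutletBC, WindkesselBC
from .chambers import HeartChamber
from .vessels import BLOOD_DENSITY, BLOOD_VISCOSITY, VesselSegment

TREE_COLUMNS = [
    "branch_id", "parent_id", "length_cm", "diameter_cm", "stenosis_severity",
    "outlet_flag", "perfuses_LV_flag", "outlet_x", "outlet_y", "outlet_z",
]


class StructuralError(ValueError):
    """Raised when the vessel graph is disconnected or malformed."""


def default_chambers(period: float = 0.8) -> dict[str, HeartChamber]:
    """Physiologic placeholder chamber parameters (values not published for
    the reference closed-loop model; all overridable via config)."""
    mmhg_ml = dyncm2(1.0)  # 1 mmHg/mL in CGS
    vent_onset, vent_dur = 0.0, 0.38 * period / 0.8
    atr_onset, atr_dur = 0.88 * period, 0.14 * period
    return {
        "lv": HeartChamber("lv", 2.2 * mmhg_ml, 0.07 * mmhg_ml, vent_onset, vent_dur,
                           unstressed_volume=10.0, initial_volume=125.0, period=period),
        "la": HeartChamber("la", 0.28 * mmhg_ml, 0.16 * mmhg_ml, atr_onset, atr_dur,
                           unstressed_volume=5.0, initial_volume=60.0, period=period),
        "rv": HeartChamber("rv", 0.55 * mmhg_ml, 0.05 * mmhg_ml, vent_onset, vent_dur,
                           unstressed_volume=10.0, initial_volume=130.0, period=period),
        "ra": HeartChamber("ra", 0.22 * mmhg_ml, 0.12 * mmhg_ml, atr_onset, atr_dur,
                           unstressed_volume=5.0, initial_volume=60.0, period=period),
    }


@dataclass
class SystemicParams:
    """Placeholder systemic/pulmonary loop parameters (CGS)."""

    R_pulmonary: float = 180.0
    C_pulm_arterial: float = 3.0e-3
    C_pulm_venous: float = 5.0e-3
    R_pulm_venous: float = 40.0
    R_systemic_venous: float = 40.0
    C_systemic_venous: float = 3.0e-2
    valve_R_open: float = 5.0
    valve_R_closed: float = 1.0e7
    valve_steepness: float = 0.05


@dataclass
class CircuitNetwork:
    """Closed-loop 0D circulation with an embedded coronary tree."""

    segments: dict[str, VesselSegment]
    chambers: dict[str, HeartChamber]
    aortic_bc: WindkesselBC
    coronary_bcs: dict[str, CoronaryOutletBC]
    systemic: SystemicParams = field(default_factory=SystemicParams)
    blood_density: float = BLOOD_DENSITY
    blood_viscosity: float = BLOOD_VISCOSITY
    cardiac_period: float = 0.8
    n_cycles: int = 5
    steps_per_cycle: int = 1000

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        self.validate()

    # -- structure ------------------------------------------------------------

    def roots(self) -> list[str]:
        return [s.id for s in self.segments.values() if s.parent is None]

    def outlets(self) -> list[str]:
        return [s.id for s in self.segments.values() if s.is_outlet]

    def lv_outlets(self) -> list[str]:
        return [s.id for s in self.segments.values() if s.is_outlet and s.perfuses_lv]

    def children(self, branch_id: str) -> list[str]:
        return [s.id for s in self.segments.values() if s.parent == branch_id]

    def validate(self) -> None:
        ids = set(self.segments)
        for s in self.segments.values():
            if s.parent is not None and s.parent not in ids:
                raise StructuralError(f"segment {s.id}: unknown parent {s.parent}")
        roots = self.roots()
        if not roots:
            raise StructuralError("tree has no root segment")
        seen: set[str] = set()
        stack = list(roots)
        while stack:
            b = stack.pop()
            if b in seen:
                raise StructuralError(f"cycle detected at segment {b}")
            seen.add(b)
            stack.extend(self.children(b))
        if seen != ids:
            raise StructuralError(f"disconnected segments: {sorted(ids - seen)}")
        for o in self.outlets():
            if o not in self.coronary_bcs:
                raise StructuralError(f"outlet {o} has no boundary condition")

    # -- transformations ------------------------------------------------------

    def with_hyperemia(self, factor: float = 0.24) -> "CircuitNetwork":
        """Scale all coronary-bed distal resistances (Ra, Ramicro, Rv)."""
        if factor <= 0:
            raise ValueError("hyperemia factor must be > 0")
        net = copy.deepcopy(self)
        net.coronary_bcs = {k: bc.scaled(factor) for k, bc in self.coronary_bcs.items()}
        return net

    def with_outlet_resistances(self, totals: dict[str, float]) -> "CircuitNetwork":
        """Replace per-outlet total distal resistance, preserving splits."""
        net = copy.deepcopy(self)
        for oid, total in totals.items():
            bc = net.coronary_bcs[oid]
            net.coronary_bcs[oid] = bc.scaled(total / bc.total_resistance)
        return net

    # -- assembly -------------------------------------------------------------

    def build_system(self) -> sy.CircuitSystem:
        p = self.systemic
        elements: list[sy.Element] = []
        nodes = ["ra", "rv", "pa", "pv", "la", "lv", "aorta", "wk", "sysven"]
        for name, ch in self.chambers.items():
            elements.append(sy.ElastanceChamber(
                name=f"vol_{name}", node=name, elastance=ch.elastance,
                V0=ch.unstressed_volume, V_init=ch.initial_volume))
        vk = dict(R_open=p.valve_R_open, R_closed=p.valve_R_closed,
                  steepness=p.valve_steepness)
        elements += [
            sy.Valve(name="tricuspid", a="ra", b="rv", **vk),
            sy.Valve(name="pulmonic", a="rv", b="pa", **vk),
            sy.Capacitor(name="c_pa", a="pa", b=sy.GROUND, C=p.C_pulm_arterial),
            sy.Resistor(name="r_pulm", a="pa", b="pv", R=p.R_pulmonary),
            sy.Capacitor(name="c_pv", a="pv", b=sy.GROUND, C=p.C_pulm_venous),
            sy.Resistor(name="r_pv", a="pv", b="la", R=p.R_pulm_venous),
            sy.Valve(name="mitral", a="la", b="lv", **vk),
            sy.Valve(name="aortic_valve", a="lv", b="aorta", **vk),
            sy.Resistor(name="wk_rp", a="aorta", b="wk", R=self.aortic_bc.Rp),
            sy.Capacitor(name="wk_c", a="wk", b=sy.GROUND, C=self.aortic_bc.C),
            sy.Resistor(name="wk_rd", a="wk", b="sysven", R=self.aortic_bc.Rd),
            sy.Capacitor(name="c_sysven", a="sysven", b=sy.GROUND, C=p.C_systemic_venous),
            sy.Resistor(name="r_sysven", a="sysven", b="ra", R=p.R_systemic_venous),
        ]
        im_sources: set[str] = set()
        for sid, seg in self.segments.items():
            prox = "aorta" if seg.parent is None else f"n_{seg.parent}"
            dist = f"n_{sid}"
            nodes.append(dist)
            elements.append(sy.Branch(name=f"seg_{sid}", a=prox, b=dist,
                                      R=seg.resistance, L=seg.inductance,
                                      S=seg.stenosis_coefficient))
            if seg.capacitance > 0:
                elements.append(sy.Capacitor(name=f"c_{sid}", a=dist, b=sy.GROUND,
                                             C=seg.capacitance))
        for oid, bc in self.coronary_bcs.items():
            src = f"pim_{bc.im_pressure_source}"
            if src not in im_sources:
                im_sources.add(src)
                nodes.append(src)
                elements.append(sy.LinkedPressureSource(
                    name=src, node=src, ref_node=bc.im_pressure_source,
                    scale=bc.im_scale))
            na, nc = f"ca_{oid}", f"cim_{oid}"
            nodes += [na, nc]
            elements += [
                sy.Resistor(name=f"ra_{oid}", a=f"n_{oid}", b=na, R=bc.Ra),
                sy.Capacitor(name=f"cca_{oid}", a=na, b=sy.GROUND, C=bc.Ca),
                sy.Resistor(name=f"ram_{oid}", a=na, b=nc, R=bc.Ramicro),
                sy.Capacitor(name=f"ccim_{oid}", a=nc, b=src, C=bc.Cim),
                sy.Resistor(name=f"rv_{oid}", a=nc, b="sysven", R=bc.Rv),
            ]
        return sy.CircuitSystem(nodes, elements)

    def simulate(self, n_cycles: int | None = None,
                 steps_per_cycle: int | None = None) -> sy.SimulationResult:
        """Run the transient closed-loop model and retain the final cycle."""
        csys = self.build_system()
        y0 = csys.initial_state(pressures=self._initial_pressures())
        # convergence monitored on aortic pressure and outlet branch flows
        mon = [csys.node_index("aorta")]
        mon += [csys.n_nodes + csys.flow_names.index(f"seg_{o}") for o in self.outlets()]
        res = sy.run_periodic(csys, y0, self.cardiac_period,
                              n_cycles or self.n_cycles,
                              steps_per_cycle or self.steps_per_cycle,
                              conv_indices=mon)
        if res.cycle_convergence > 0.05:
            import warnings
            warnings.warn(f"cycle-to-cycle change {res.cycle_convergence:.2%} > 5%; "
                          "consider more cycles", stacklevel=2)
        return res

    def _initial_pressures(self) -> dict[str, float]:
        p0 = dyncm2(80.0)
        init = {"aorta": p0, "wk": p0 * 0.95, "sysven": dyncm2(8.0),
                "pa": dyncm2(15.0), "pv": dyncm2(10.0)}
        for sid in self.segments:
            init[f"n_{sid}"] = p0
        for oid in self.coronary_bcs:
            init[f"ca_{oid}"] = p0 * 0.8
            init[f"cim_{oid}"] = p0 * 0.5
        return init


# ---------------------------------------------------------------------------
# Anatomy ingestion


def read_tree(path_or_df) -> pd.DataFrame:
    """Read a coronary-tree description (CSV/TSV with TREE_COLUMNS)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python")
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tree description missing columns: {missing}")
    df["branch_id"] = df["branch_id"].astype(str)
    df["parent_id"] = df["parent_id"].astype(object).where(df["parent_id"].notna(), None)
    df.loc[df["parent_id"].notna(), "parent_id"] = (
        df.loc[df["parent_id"].notna(), "parent_id"].astype(str))
    return df


def segments_from_tree(tree: pd.DataFrame) -> dict[str, VesselSegment]:
    segs: dict[str, VesselSegment] = {}
    for _, row in tree.iterrows():
        if row["length_cm"] <= 0 or row["diameter_cm"] <= 0:
            raise ValueError(f"branch {row['branch_id']}: nonpositive geometry")
        parent = row["parent_id"]
        if parent is not None and (parent == "" or str(parent).lower() in ("nan", "none")):
            parent = None
        xyz = None
        if bool(row["outlet_flag"]):
            xyz = (float(row["outlet_x"]), float(row["outlet_y"]), float(row["outlet_z"]))
        segs[str(row["branch_id"])] = VesselSegment.from_geometry(
            id=str(row["branch_id"]), length=float(row["length_cm"]),
            diameter=float(row["diameter_cm"]),
            severity=float(row["stenosis_severity"]),
            parent=parent, is_outlet=bool(row["outlet_flag"]),
            perfuses_lv=bool(row["perfuses_LV_flag"]), outlet_xyz=xyz)
    return segs


def murray_resistance_split(total_R: float, diameters: Iterable[float],
                            exponent: float = 2.6) -> np.ndarray:
    """Split a parallel total resistance over outlets with conductances
    proportional to diameter**exponent."""
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0) or total_R <= 0:
        raise ValueError("diameters and total_R must be > 0")
    weights = d**exponent
    conductances = weights / weights.sum() / total_R
    return 1.0 / conductances


def build_network_from_anatomy(tree, bc_params: dict | None = None) -> CircuitNetwork:
    """Construct a closed-loop CircuitNetwork from a coronary-tree description.

    ``bc_params`` keys (all optional): total_lv_resistance, total_other_resistance,
    murray_exponent, aortic_bc {Rp, C, Rd}, cardiac_period, n_cycles,
    steps_per_cycle, im_scale, coronary_split, chambers, systemic, hyperemia_factor.
    """
    bc = dict(bc_params or {})
    df = read_tree(tree)
    segs = segments_from_tree(df)
    period = bc.get("cardiac_period", 0.8)
    chambers = bc.get("chambers") or default_chambers(period)
    wk = bc.get("aortic_bc") or {}
    aortic = WindkesselBC(Rp=wk.get("Rp", 120.0), C=wk.get("C", 1.8e-3),
                          Rd=wk.get("Rd", 1200.0))
    lv_ids = [s.id for s in segs.values() if s.is_outlet and s.perfuses_lv]
    other_ids = [s.id for s in segs.values() if s.is_outlet and not s.perfuses_lv]
    total_lv = bc.get("total_lv_resistance", 2.0e5)
    total_other = bc.get("total_other_resistance", 5.0e5)
    exponent = bc.get("murray_exponent", 2.6)
    split = bc.get("coronary_split", (0.32, 0.52, 0.16))
    im_scale = bc.get("im_scale", 1.0)
    coronary_bcs: dict[str, CoronaryOutletBC] = {}

    def _make(ids: list[str], total: float, im_src_default: str) -> None:
        if not ids:
            return
        diams = [segs[i].diameter for i in ids]
        totals = murray_resistance_split(total, diams, exponent)
        for oid, r in zip(ids, totals):
            coronary_bcs[oid] = CoronaryOutletBC.from_total(
                float(r), split=split, im_pressure_source=im_src_default,
                im_scale=im_scale)

    _make(lv_ids, total_lv, "lv")
    _make(other_ids, total_other, "rv")
    net = CircuitNetwork(
        segments=segs, chambers=chambers, aortic_bc=aortic,
        coronary_bcs=coronary_bcs, systemic=bc.get("systemic") or SystemicParams(),
        cardiac_period=period, n_cycles=bc.get("n_cycles", 5),
        steps_per_cycle=bc.get("steps_per_cycle", 1000))
    factor = bc.get("hyperemia_factor")
    if factor is not None:
        net = net.with_hyperemia(factor)
    return net
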