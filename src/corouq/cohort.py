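"""Seeded synthetic fixtures: coronary trees, LV point clouds, MBF fields.

These generators emulate the statistical structure of the clinical inputs the
pipeline consumes (branch geometry with stenoses, an LV myocardium point
cloud with a smooth spatially varying myocardial-blood-flow field) at a scale
suitable for tests and desk-scale studies.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zerod.network import TREE_COLUMNS

MAIN_BRANCHES = ("LAD", "LCx", "RCA")

# Angular cluster centers (azimuth phi, polar band) for outlet placement on
# the LV shell: LAD anterior, LCx lateral, RCA inferior/right.
_MAIN_PHI = {"LAD": 0.0, "LCx": 2.0 * np.pi / 3.0, "RCA": 4.0 * np.pi / 3.0}


@dataclass
class TreeConfig:
    stenosis_severity: float = 0.6       # one stenosis per main branch
    main_diameter: float = 0.34          # cm
    taper_exponent: float = 2.6
    taper_jitter: float = 0.06
    length_range: tuple[float, float] = (1.5, 3.5)
    outlet_length_range: tuple[float, float] = (1.0, 2.0)
    shell_semiaxes: tuple[float, float, float] = (3.5, 3.5, 4.5)  # cm
    shell_scale: float = 1.15            # outlets sit just outside the LV wall
    lv_fraction: float = 1.0             # fraction of outlets flagged perfuses_LV


@dataclass
class LVConfig:
    semiaxes: tuple[float, float, float] = (3.5, 3.5, 4.5)    # outer wall, cm
    wall_fraction: float = 0.65          # inner cavity scale relative to outer
    base_cut: float = 0.55               # keep z < base_cut * c (basal plane)
    total_flow: float = 180.0            # mL/min at rest-like perfusion
    smooth_amplitude: float = 0.25       # relative smooth spatial variation
    deficit_scale: float = 0.0           # relative depth of a regional deficit
    deficit_width: float = 1.2           # cm
    deficit_center: tuple[float, float, float] = (2.4, 1.2, -1.5)


@dataclass
class LVPointCloud:
    points: np.ndarray                    # (N, 3) cm
    voxel_volume: float                   # cm^3 per point
    mbf: np.ndarray                       # mL/min per mL tissue
    config: LVConfig = field(default_factory=LVConfig)

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("empty point cloud")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be > 0")
        if np.any(self.mbf < 0):
            raise ValueError("mbf must be >= 0")

    @property
    def total_flow(self) -> float:
        """Sum of mbf * voxel_volume over all points (mL/min)."""
        return float(self.mbf.sum() * self.voxel_volume)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
            "voxel_volume": self.voxel_volume, "mbf": self.mbf})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LVPointCloud":
        df = pd.read_csv(path)
        return cls(points=df[["x", "y", "z"]].to_numpy(),
                   voxel_volume=float(df["voxel_volume"].iloc[0]),
                   mbf=df["mbf"].to_numpy())


def _split_leaves(n: int) -> tuple[int, int]:
    return (n + 1) // 2, n // 2


def generate_tree(n_outlets: int, seed: int, config: TreeConfig | None = None) -> pd.DataFrame:
    """Binary coronary tree with three main branches, tapering diameters,
    one stenosis per main, and outlet coordinates on a shell around the LV."""
    if n_outlets < 3:
        raise ValueError("need at least 3 outlets (one per main branch)")
    cfg = config or TreeConfig()
    rng = np.random.default_rng(seed)
    a, b, c = cfg.shell_semiaxes
    rows: list[dict] = []
    # distribute outlets over mains: LAD-dominant, like typical anatomy
    counts = [n_outlets - 2 * (n_outlets // 3), n_outlets // 3, n_outlets // 3]
    outlet_slots: list[tuple[str, int, int]] = []  # (main, index within main, count)

    def grow(branch_id: str, parent_id: str | None, main: str, n_leaves: int,
             diameter: float, depth: int) -> None:
        is_outlet = n_leaves == 1
        lo, hi = cfg.outlet_length_range if is_outlet else cfg.length_range
        length = float(rng.uniform(lo, hi))
        severity = cfg.stenosis_severity if depth == 0 else 0.0
        rows.append({
            "branch_id": branch_id, "parent_id": parent_id, "length_cm": length,
            "diameter_cm": diameter, "stenosis_severity": severity,
            "outlet_flag": int(is_outlet), "perfuses_LV_flag": 0,
            "outlet_x": np.nan, "outlet_y": np.nan, "outlet_z": np.nan})
        if is_outlet:
            outlet_slots.append((main, len([s for s in outlet_slots if s[0] == main]),
                                 len(rows) - 1))
            return
        n1, n2 = _split_leaves(n_leaves)
        for j, nk in enumerate((n1, n2)):
            frac = nk / n_leaves
            jit = float(np.clip(1.0 + rng.normal(0.0, cfg.taper_jitter), 0.75, 0.98))
            d_child = diameter * frac ** (1.0 / cfg.taper_exponent) * jit
            d_child = min(d_child, 0.98 * diameter)
            grow(f"{branch_id}_{j}", branch_id, main, nk, d_child, depth + 1)

    for main, n_leaves in zip(MAIN_BRANCHES, counts):
        d0 = cfg.main_diameter * float(rng.uniform(0.92, 1.08))
        grow(main, None, main, max(n_leaves, 1), d0, 0)

    df = pd.DataFrame(rows, columns=TREE_COLUMNS)
    # outlet coordinates clustered per main on the shell
    per_main = {m: sum(1 for s in outlet_slots if s[0] == m) for m in MAIN_BRANCHES}
    for main, k, row_idx in outlet_slots:
        n_m = per_main[main]
        phi = _MAIN_PHI[main] + 1.6 * (k - (n_m - 1) / 2.0) / max(n_m, 1)
        phi += float(rng.normal(0.0, 0.08))
        theta = float(rng.uniform(0.45, 0.80)) * np.pi  # mid-to-apical band
        r = cfg.shell_scale
        df.loc[row_idx, ["outlet_x", "outlet_y", "outlet_z"]] = (
            r * a * np.sin(theta) * np.cos(phi),
            r * b * np.sin(theta) * np.sin(phi),
            r * c * np.cos(theta))
    # flag LV-perfusing outlets (first fraction in deterministic order)
    out_rows = df.index[df["outlet_flag"] == 1].tolist()
    n_lv = max(1, int(round(cfg.lv_fraction * len(out_rows))))
    df.loc[out_rows[:n_lv], "perfuses_LV_flag"] = 1
    return df


def generate_lv(n_points: int, seed: int, config: LVConfig | None = None) -> LVPointCloud:
    """Ellipsoidal-shell LV point cloud with a smooth MBF field.

    The field is a smooth base level with optional regional deficit; it is
    rescaled so the integrated flow equals ``config.total_flow`` exactly.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    cfg = config or LVConfig()
    rng = np.random.default_rng(seed)
    a, b, c = cfg.semiaxes
    pts = np.empty((0, 3))
    n_drawn = 0
    n_try_total = 0
    while len(pts) < n_points:
        m = max(2 * (n_points - len(pts)), 1000)
        cand = rng.uniform(-1.0, 1.0, size=(m, 3)) * np.array([a, b, c])
        u = (cand / np.array([a, b, c])) ** 2
        rho2 = u.sum(axis=1)
        keep = (rho2 <= 1.0) & (rho2 >= cfg.wall_fraction**2) & (cand[:, 2] < cfg.base_cut * c)
        pts = np.vstack([pts, cand[keep]])
        n_drawn += keep.sum()
        n_try_total += m
    pts = pts[:n_points]
    # Monte Carlo shell volume from the acceptance fraction of the bounding box
    box_vol = 8.0 * a * b * c
    shell_vol = box_vol * n_drawn / n_try_total
    voxel_volume = shell_vol / n_points

    # smooth base variation plus optional deficit
    base = 1.0 + cfg.smooth_amplitude * (
        0.6 * np.sin(np.pi * pts[:, 0] / a) * np.cos(0.5 * np.pi * pts[:, 2] / c)
        + 0.4 * np.cos(np.pi * pts[:, 1] / b))
    if cfg.deficit_scale > 0:
        d2 = ((pts - np.asarray(cfg.deficit_center)) ** 2).sum(axis=1)
        base = base * (1.0 - cfg.deficit_scale * np.exp(-d2 / (2.0 * cfg.deficit_width**2)))
    base = np.maximum(base, 0.05)
    mbf = base * (cfg.total_flow / (base.sum() * voxel_volume))
    return LVPointCloud(points=pts, voxel_volume=voxel_volume, mbf=mbf, config=cfg)
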