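"""Perfusion territories and uncertainty-aware branch flow targets.

Each LV point is assigned to its closest LV-perfusing coronary outlet
(a Voronoi tessellation); branch flow targets are the integral of myocardial
blood flow over each territory.  Uncertainty is characterized by Monte Carlo
realizations with two noise sources: Gaussian noise on every point-outlet
distance (sd = 10% of the deterministic distance) and Gaussian multiplicative
noise on MBF (sd = 20% of the baseline value).  The sample mean and
covariance over realizations form the flow-target set for Bayesian
personalization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LVPointCloud
from .units import MLMIN_TO_CM3S


@dataclass
class OutletSet:
    """LV-relevant coronary outlets with 3D coordinates."""

    ids: list[str]
    coords: np.ndarray           # (n, 3)
    perfuses_lv: np.ndarray      # bool per outlet

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.perfuses_lv = np.asarray(self.perfuses_lv, bool)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("outlet coordinates must be finite")
        if self.n_lv < 1:
            raise ValueError("need at least one LV-perfusing outlet")

    @property
    def n_lv(self) -> int:
        return int(self.perfuses_lv.sum())

    @property
    def lv_ids(self) -> list[str]:
        return [i for i, f in zip(self.ids, self.perfuses_lv) if f]

    @classmethod
    def from_tree(cls, tree: pd.DataFrame) -> "OutletSet":
        out = tree[tree["outlet_flag"] == 1]
        return cls(ids=[str(b) for b in out["branch_id"]],
                   coords=out[["outlet_x", "outlet_y", "outlet_z"]].to_numpy(),
                   perfuses_lv=out["perfuses_LV_flag"].to_numpy().astype(bool))


@dataclass
class TerritoryAssignment:
    outlet_ids: list[str]        # LV-perfusing outlets, in order
    labels: np.ndarray           # per-point index into outlet_ids
    territory_volumes: np.ndarray

    @property
    def total_volume(self) -> float:
        return float(self.territory_volumes.sum())


def _lv_distances(lv: LVPointCloud, outlets: OutletSet) -> tuple[list[str], np.ndarray]:
    lv_mask = outlets.perfuses_lv
    coords = outlets.coords[lv_mask]
    ids = outlets.lv_ids
    d = np.linalg.norm(lv.points[:, None, :] - coords[None, :, :], axis=2)
    return ids, d


def assign_territories(lv: LVPointCloud, outlets: OutletSet,
                       distance_noise_sd_frac: float = 0.10,
                       seed: int | np.random.Generator | None = None) -> TerritoryAssignment:
    """Assign each LV point to the outlet with minimum (noisy) distance.

    Noise is drawn independently per (point, outlet) pair with standard
    deviation ``frac`` times the deterministic distance; frac = 0 gives the
    deterministic Voronoi tessellation.  Ties break to the lowest outlet
    index.
    """
    ids, d = _lv_distances(lv, outlets)
    if distance_noise_sd_frac > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        d = d + rng.normal(0.0, distance_noise_sd_frac * d)
    labels = np.argmin(d, axis=1)  # argmin takes the first (lowest) index on ties
    vols = np.bincount(labels, minlength=len(ids)).astype(float) * lv.voxel_volume
    return TerritoryAssignment(outlet_ids=ids, labels=labels, territory_volumes=vols)


def branch_flows(lv: LVPointCloud, assignment: TerritoryAssignment,
                 mbf_noise_sd_frac: float = 0.20,
                 seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Integrate (noisy) MBF over each territory -> flow per outlet, mL/min.

    Each point's MBF is perturbed multiplicatively: mbf * (1 + eps),
    eps ~ N(0, frac^2), i.i.d. per point.
    """
    mbf = lv.mbf
    if mbf_noise_sd_frac > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        mbf = mbf * (1.0 + rng.normal(0.0, mbf_noise_sd_frac, size=mbf.shape))
    n_out = len(assignment.outlet_ids)
    sums = np.bincount(assignment.labels, weights=mbf, minlength=n_out)
    return sums * lv.voxel_volume


@dataclass
class FlowTargetSet:
    """Mean branch-flow targets and their covariance over realizations."""

    outlet_ids: list[str]
    mean: np.ndarray             # mL/min
    cov: np.ndarray              # (Nc, Nc), mL^2/min^2
    n_realizations: int
    realizations: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if self.cov.shape != (len(self.mean), len(self.mean)):
            raise ValueError("covariance shape mismatch")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10 * (1 + abs(self.cov).max())):
            raise ValueError("covariance must be symmetric")
        if np.any(self.mean < 0):
            raise ValueError("mean targets must be >= 0")

    @property
    def n_outlets(self) -> int:
        return len(self.outlet_ids)

    def mean_cm3s(self) -> np.ndarray:
        return self.mean * MLMIN_TO_CM3S

    def cov_cm3s(self) -> np.ndarray:
        return self.cov * MLMIN_TO_CM3S**2

    def with_mean(self, mean: np.ndarray) -> "FlowTargetSet":
        return FlowTargetSet(outlet_ids=list(self.outlet_ids),
                             mean=np.asarray(mean, float), cov=self.cov.copy(),
                             n_realizations=self.n_realizations,
                             provenance=dict(self.provenance))

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": 1,
            "outlet_ids": self.outlet_ids,
            "mean_ml_min": self.mean.tolist(),
            "cov_ml2_min2": self.cov.tolist(),
            "n_realizations": self.n_realizations,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "FlowTargetSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(outlet_ids=payload["outlet_ids"],
                   mean=np.array(payload["mean_ml_min"]),
                   cov=np.array(payload["cov_ml2_min2"]),
                   n_realizations=payload["n_realizations"],
                   provenance=payload.get("provenance", {}))


def repair_psd(cov: np.ndarray, clip_frac: float = 1e-12) -> np.ndarray:
    """Clip eigenvalues below clip_frac * trace to restore positive
    semi-definiteness (sampling covariances can dip slightly negative)."""
    w, v = np.linalg.eigh(cov)
    floor = clip_frac * max(np.trace(cov), 0.0)
    if w.min() >= floor:
        return cov
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def build_flow_targets(lv: LVPointCloud, outlets: OutletSet,
                       n_realizations: int = 2500,
                       distance_noise_sd_frac: float = 0.10,
                       mbf_noise_sd_frac: float = 0.20,
                       seed: int | None = None,
                       keep_realizations: bool = False) -> FlowTargetSet:
    """Monte Carlo characterization of branch-flow targets.

    Draws ``n_realizations`` of (territory tessellation + MBF noise),
    accumulates per-outlet flows, and returns their sample mean and sample
    covariance (PSD-repaired).
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    rng = np.random.default_rng(seed)
    ids, d0 = _lv_distances(lv, outlets)
    nc = len(ids)
    flows = np.empty((n_realizations, nc))
    zero_counts = np.zeros(nc, dtype=int)
    for k in range(n_realizations):
        if distance_noise_sd_frac > 0:
            d = d0 + rng.normal(0.0, distance_noise_sd_frac * d0)
        else:
            d = d0
        labels = np.argmin(d, axis=1)
        mbf = lv.mbf
        if mbf_noise_sd_frac > 0:
            mbf = mbf * (1.0 + rng.normal(0.0, mbf_noise_sd_frac, size=mbf.shape))
        f = np.bincount(labels, weights=mbf, minlength=nc) * lv.voxel_volume
        flows[k] = f
        zero_counts += np.bincount(labels, minlength=nc) == 0
    mean = flows.mean(axis=0)
    cov = np.cov(flows, rowvar=False) if n_realizations > 1 else np.zeros((nc, nc))
    cov = repair_psd(np.atleast_2d(cov))
    degenerate = [ids[i] for i in np.nonzero(zero_counts > n_realizations // 2)[0]]
    if degenerate:
        warnings.warn(f"degenerate territories (empty in >50% of realizations): "
                      f"{degenerate}", stacklevel=2)
    prov = {
        "n_realizations": n_realizations,
        "distance_noise_sd_frac": distance_noise_sd_frac,
        "mbf_noise_sd_frac": mbf_noise_sd_frac,
        "seed": seed,
        "degenerate_outlets": degenerate,
    }
    return FlowTargetSet(outlet_ids=ids, mean=np.maximum(mean, 0.0), cov=cov,
                         n_realizations=n_realizations,
                         realizations=flows if keep_realizations else None,
                         provenance=prov)
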