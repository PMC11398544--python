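"""End-to-end pipeline orchestration: fixtures -> targets -> personalization
-> input sampling -> estimation, with JSON/CSV artifacts and provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import LVConfig, TreeConfig, generate_lv, generate_tree
from .estimators import SamplePairSet, mc_estimate, mfmc_estimate
from .personalize import (
    DreamConfig,
    GaussianFlowLikelihood,
    PriorSpec,
    dream_sample,
    reference_resistances,
)
from .qoi import S_SUPPORT, hf_surrogate, HFSurrogateConfig, UncertainInputs
from .sharedspace import ArchConfig, mfmc_ae_estimate, train_shared_space
from .targets import FlowTargetSet, OutletSet, build_flow_targets
from .units import CM3S_TO_MLMIN, dyncm2
from .zerod import SteadyTreeModel, build_network_from_anatomy, read_tree

log = logging.getLogger("corouq.pipeline")

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 1,
    "output_dir": "runs/demo",
    "stages": {"fixtures": True, "targets": True, "personalize": True, "estimate": True},
    "fixtures": {"n_outlets": 14, "n_lv_points": 3000, "stenosis_severity": 0.6,
                 "total_flow_ml_min": 240.0},
    "targets": {"n_realizations": 500, "distance_noise": 0.10, "mbf_noise": 0.20},
    "personalize": {"chains": 12, "generations": 600, "burn_in": 0.5,
                    "inlet_pressure_mmhg": 93.0, "venous_pressure_mmhg": 5.0,
                    "hyperemia_factor": 0.24},
    "estimate": {"n_hf": 80, "n_lf": 800, "qoi_outlet": None,
                 "distortion": "osi_proxy", "distortion_strength": 0.5,
                 "arch": {"max_epochs": 500, "stage2_max_epochs": 200}},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, other: dict) -> None:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def make_flow_model(tree_df, cfg: dict, lv_outlet_ids: list[str]):
    """Steady flow-split model f(r) -> LV-outlet flows in mL/min.

    Non-LV outlets keep their Murray-law resistances; r applies to the
    LV-perfusing outlets only.  The network is evaluated under hyperemia.
    """
    pcfg = cfg["personalize"]
    net = build_network_from_anatomy(tree_df).with_hyperemia(pcfg["hyperemia_factor"])
    model = SteadyTreeModel(net, inlet_pressure=dyncm2(pcfg["inlet_pressure_mmhg"]),
                            venous_pressure=dyncm2(pcfg["venous_pressure_mmhg"]))
    fixed = {o: net.coronary_bcs[o].total_resistance for o in model.outlet_ids
             if o not in lv_outlet_ids}
    f_cm3s = model.outlet_flow_fn(outlet_subset=lv_outlet_ids, fixed=fixed)

    def f(r: np.ndarray) -> np.ndarray:
        return f_cm3s(r) * CM3S_TO_MLMIN

    return f, model, net


def run_pipeline(cfg: dict) -> Path:
    """Execute the enabled stages; returns the run directory."""
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    provenance = {"schema_version": cfg["schema_version"], "version": __version__,
                  "seed": seed, "config_hash": config_hash(cfg)}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    summary: dict = {"schema_version": 1, "provenance": provenance, "stages": {}}
    stages = cfg["stages"]
    t_start = time.time()

    tree_path, lv_path = out / "tree.csv", out / "lv.csv"
    if stages.get("fixtures", True):
        t0 = time.time()
        fx = cfg["fixtures"]
        tree = generate_tree(fx["n_outlets"], seed=seed,
                             config=TreeConfig(stenosis_severity=fx["stenosis_severity"]))
        lv = generate_lv(fx["n_lv_points"], seed=seed + 1,
                         config=LVConfig(total_flow=fx["total_flow_ml_min"]))
        tree.to_csv(tree_path, index=False)
        lv.write_csv(lv_path)
        summary["stages"]["fixtures"] = {
            "n_outlets": fx["n_outlets"], "n_lv_points": fx["n_lv_points"],
            "wall_time_s": round(time.time() - t0, 3)}
        log.info("fixtures: %d outlets, %d LV points", fx["n_outlets"], fx["n_lv_points"])

    targets_path = out / "targets.json"
    if stages.get("targets", True):
        t0 = time.time()
        from .cohort import LVPointCloud
        tree = read_tree(tree_path)
        lv = LVPointCloud.read_csv(lv_path)
        outlets = OutletSet.from_tree(tree)
        tcfg = cfg["targets"]
        targets = build_flow_targets(
            lv, outlets, n_realizations=tcfg["n_realizations"],
            distance_noise_sd_frac=tcfg["distance_noise"],
            mbf_noise_sd_frac=tcfg["mbf_noise"], seed=seed + 2)
        targets.to_json(targets_path)
        summary["stages"]["targets"] = {
            "n_outlets_lv": targets.n_outlets,
            "total_flow_ml_min": float(targets.mean.sum()),
            "n_realizations": targets.n_realizations,
            "wall_time_s": round(time.time() - t0, 3)}
        log.info("targets: %d LV outlets, total %.1f mL/min",
                 targets.n_outlets, targets.mean.sum())

    posterior = None
    if stages.get("personalize", True):
        t0 = time.time()
        tree = read_tree(tree_path)
        targets = FlowTargetSet.from_json(targets_path)
        pcfg = cfg["personalize"]
        f, model, net = make_flow_model(tree, cfg, targets.outlet_ids)
        dp = dyncm2(pcfg["inlet_pressure_mmhg"] - pcfg["venous_pressure_mmhg"])
        total_lv = dp / (targets.mean.sum() / CM3S_TO_MLMIN)
        r_hat = reference_resistances(total_lv, targets.mean)
        prior = PriorSpec(r_hat=r_hat)
        lik = GaussianFlowLikelihood(targets, f, jitter_frac=1e-8)
        dream_cfg = DreamConfig(n_chains=pcfg["chains"],
                                n_generations=pcfg["generations"],
                                burn_in_fraction=pcfg["burn_in"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            posterior = dream_sample(prior, lik, total_lv_resistance=total_lv,
                                     config=dream_cfg, seed=seed + 3)
        summ = posterior.summary()
        summ.insert(0, "outlet", targets.outlet_ids)
        summ.to_csv(out / "posterior_summary.csv", index=False)
        np.save(out / "chains.npy", posterior.chains)  # scratch-scale artifact
        summary["stages"]["personalize"] = {
            "n_chains": pcfg["chains"], "n_generations": pcfg["generations"],
            "acceptance_rate": posterior.acceptance_rate,
            "max_rhat": float(np.max(posterior.gelman_rubin)),
            "total_lv_resistance": total_lv,
            "wall_time_s": round(time.time() - t0, 3)}
        log.info("personalize: max Rhat %.3f, acceptance %.2f",
                 np.max(posterior.gelman_rubin), posterior.acceptance_rate)

    if stages.get("estimate", True):
        t0 = time.time()
        if posterior is None:
            raise RuntimeError("estimation requires the personalize stage")
        tree = read_tree(tree_path)
        targets = FlowTargetSet.from_json(targets_path)
        ecfg = cfg["estimate"]
        qoi_outlet = ecfg["qoi_outlet"] or targets.outlet_ids[0]
        k = targets.outlet_ids.index(qoi_outlet)
        f, model, net = make_flow_model(tree, cfg, targets.outlet_ids)

        def lf_model(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            vals = np.empty(len(theta))
            for i, row in enumerate(theta):
                r, s = np.abs(row[:-1]) + 1e-9, row[-1]
                vals[i] = f(r * s)[k]
            return vals

        flat = posterior.flat()
        idx = rng.integers(0, len(flat), size=int(ecfg["n_lf"]))
        s = rng.uniform(*S_SUPPORT, size=int(ecfg["n_lf"]))
        theta = np.column_stack([flat[idx], s])
        q_scale = float(np.mean(lf_model(theta[:20])))
        sur_cfg = HFSurrogateConfig(distortion=ecfg["distortion"],
                                    distortion_strength=ecfg["distortion_strength"],
                                    q_scale=q_scale)

        def hf_model(theta: np.ndarray) -> np.ndarray:
            lf_vals = lf_model(theta)
            return np.array([
                hf_surrogate(UncertainInputs(r=np.abs(row[:-1]) + 1e-9, s=row[-1]),
                             lambda u, v=val: v, sur_cfg)
                for row, val in zip(np.atleast_2d(theta), lf_vals)])

        n_hf, n_lf = int(ecfg["n_hf"]), int(ecfg["n_lf"])
        hf_vals = hf_model(theta[:n_hf])
        lf_vals = lf_model(theta)
        results = {}
        results["mc"] = mc_estimate(hf_vals)
        pairs = SamplePairSet(hf_values=hf_vals, lf_values_at_hf_inputs=lf_vals[:n_hf],
                              lf_values_extra=lf_vals[n_hf:])
        results["mfmc"] = mfmc_estimate(pairs)
        arch = ArchConfig(**ecfg.get("arch", {}))
        smap = train_shared_space(theta[:n_hf], hf_vals, theta[:n_hf], lf_vals[:n_hf],
                                  lf_model=lf_model,
                                  lf_values_at_hf_inputs=lf_vals[:n_hf],
                                  arch=arch, seed=seed + 4)
        results["mfmc_ae"] = mfmc_ae_estimate(smap, theta[:n_hf], hf_vals, theta[n_hf:])
        report_rows = []
        for name, res in results.items():
            res.to_json(out / f"estimator_{name}.json")
            report_rows.append({"estimator": res.estimator, "qoi": f"surrogate:{qoi_outlet}",
                                **res.to_dict()})
        summary["stages"]["estimate"] = {
            "qoi_outlet": qoi_outlet, "n_hf": n_hf, "n_lf": n_lf,
            "rho_original": smap.rho_original, "rho_ae": smap.rho_ae,
            "wall_time_s": round(time.time() - t0, 3)}
        pd.DataFrame(report_rows).to_csv(out / "estimators.csv", index=False)
        log.info("estimate: rho %.3f -> rho_AE %.3f", smap.rho_original, smap.rho_ae)

    summary["wall_time_s"] = round(time.time() - t_start, 3)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return out


def report(run_dir) -> str:
    """Human-readable summary of a completed (possibly partial) run."""
    run_dir = Path(run_dir)
    lines = [f"corouq run report: {run_dir}"]
    missing = []
    spath = run_dir / "summary.json"
    if spath.exists():
        with open(spath) as fh:
            summary = json.load(fh)
        for stage, info in summary.get("stages", {}).items():
            lines.append(f"  [{stage}] " + ", ".join(f"{k}={v}" for k, v in info.items()))
    else:
        missing.append("summary.json")
    ppath = run_dir / "posterior_summary.csv"
    if ppath.exists():
        df = pd.read_csv(ppath)
        lines.append("  posterior (per outlet):")
        lines.append("    " + df.to_string(index=False).replace("\n", "\n    "))
    epath = run_dir / "estimators.csv"
    if epath.exists():
        df = pd.read_csv(epath)
        lines.append("  estimators:")
        lines.append("    " + df.to_string(index=False).replace("\n", "\n    "))
        if {"estimator", "variance"} <= set(df.columns) and len(df) >= 2:
            base = df.loc[df["estimator"] == "MC", "variance"]
            if len(base):
                ratios = np.sqrt(df["variance"] / float(base.iloc[0]))
                lines.append("  interval half-width ratios vs MC: "
                             + ", ".join(f"{e}={r:.3f}" for e, r in
                                         zip(df["estimator"], ratios)))
    else:
        missing.append("estimators.csv")
    if missing:
        lines.append(f"  missing artifacts: {missing}")
    return "\n".join(lines)
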