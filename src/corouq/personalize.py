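"""Bayesian personalization of coronary outlet resistances.

Samples the posterior of LV-perfusing outlet resistances given noisy
branch-flow targets, using a differential-evolution adaptive Metropolis
(DREAM-style) sampler with parallel chains, subspace crossover, adaptive
crossover probabilities during burn-in, and a per-generation rescaling that
preserves the total (parallel) coronary resistance fixed by the first
estimation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .targets import FlowTargetSet


# ---------------------------------------------------------------------------
# Priors and algebra on resistances


@dataclass
class PriorSpec:
    """Componentwise-uniform prior on [lower*r_hat, upper*r_hat]."""

    r_hat: np.ndarray
    lower: float = 0.5
    upper: float = 2.0

    def __post_init__(self) -> None:
        self.r_hat = np.asarray(self.r_hat, float)
        if np.any(self.r_hat <= 0):
            raise ValueError("reference resistances must be > 0")
        if not self.lower < self.upper:
            raise ValueError("lower factor must be < upper factor")

    @property
    def lo(self) -> np.ndarray:
        return self.lower * self.r_hat

    @property
    def hi(self) -> np.ndarray:
        return self.upper * self.r_hat

    def contains(self, r: np.ndarray) -> np.ndarray:
        r = np.atleast_2d(r)
        return np.all((r >= self.lo) & (r <= self.hi), axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, len(self.r_hat)))


def parallel_total(r: np.ndarray) -> float:
    """Parallel combination 1 / sum(1/r_i)."""
    r = np.asarray(r, float)
    return 1.0 / np.sum(1.0 / r)


def reference_resistances(total_lv_resistance: float, target_flows: np.ndarray) -> np.ndarray:
    """Distribute a total (parallel) resistance over outlets with
    conductances proportional to the target flows."""
    f = np.asarray(target_flows, float)
    if np.any(f <= 0):
        raise ValueError("target flows must be > 0")
    if total_lv_resistance <= 0:
        raise ValueError("total resistance must be > 0")
    g = f / f.sum() / total_lv_resistance
    return 1.0 / g


def rescale_preserve_total(r: np.ndarray, total_lv_resistance: float) -> np.ndarray:
    """Scale all conductances by one factor so the parallel combination
    equals ``total_lv_resistance``; flow splits are unchanged.  Accepts a
    single vector or a batch (last axis is the component axis)."""
    r = np.asarray(r, float)
    c = (1.0 / total_lv_resistance) / np.sum(1.0 / r, axis=-1, keepdims=True)
    return r / c


# ---------------------------------------------------------------------------
# Likelihood


class GaussianFlowLikelihood:
    """log p(f_CT | r) for a Gaussian target-flow model (precomputed
    Cholesky factorization of the covariance)."""

    def __init__(self, targets: FlowTargetSet, model: Callable[[np.ndarray], np.ndarray],
                 jitter_frac: float = 0.0, units: str = "ml_min"):
        from scipy.linalg import cho_factor

        self.model = model
        if units == "ml_min":
            self.f_ct = targets.mean
            cov = targets.cov
        elif units == "cm3_s":
            self.f_ct = targets.mean_cm3s()
            cov = targets.cov_cm3s()
        else:
            raise ValueError(f"unknown units {units!r}")
        nc = len(self.f_ct)
        if jitter_frac > 0:
            cov = cov + jitter_frac * np.trace(cov) / nc * np.eye(nc)
        self._cho = cho_factor(cov)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError("covariance is not positive definite; repair or add jitter")
        self._lognorm = -0.5 * (nc * np.log(2.0 * np.pi) + logdet)

    def __call__(self, r: np.ndarray) -> float:
        from scipy.linalg import cho_solve

        f = np.asarray(self.model(r), float)
        if not np.all(np.isfinite(f)):
            return -np.inf
        res = self.f_ct - f
        return float(-0.5 * res @ cho_solve(self._cho, res) + self._lognorm)

    @property
    def max_log_likelihood(self) -> float:
        """Value attained when the model matches the targets exactly."""
        return float(self._lognorm)


def log_likelihood(r: np.ndarray, targets: FlowTargetSet,
                   model: Callable[[np.ndarray], np.ndarray], **kwargs) -> float:
    """One-shot Gaussian log-likelihood (see :class:`GaussianFlowLikelihood`)."""
    return GaussianFlowLikelihood(targets, model, **kwargs)(r)


# ---------------------------------------------------------------------------
# Convergence diagnostics


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split-Rhat per component for chains of shape (m, n, d)."""
    chains = np.asarray(chains, float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, d = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 4:
        raise ValueError("need at least 4 samples per chain for split-Rhat")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    n2 = half
    means = split.mean(axis=1)                       # (2m, d)
    variances = split.var(axis=1, ddof=1)            # (2m, d)
    W = variances.mean(axis=0)
    B = n2 * means.var(axis=0, ddof=1)
    var_plus = (n2 - 1) / n2 * W + B / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


# ---------------------------------------------------------------------------
# DREAM sampler


@dataclass
class DreamConfig:
    n_chains: int = 24
    n_generations: int = 10_000
    burn_in_fraction: float = 0.5
    n_cr: int = 10                       # crossover values {0.1, ..., 1.0}
    constrain_total: bool = True         # rescale to preserve total resistance
    delta_max: int = 3                   # number of difference pairs
    jump_probability: float = 0.2        # probability of a gamma = 1 jump
    jitter_sd: float = 1e-6              # relative proposal jitter
    adapt_cr: bool = True
    outlier_check_interval: int = 200
    stagnation_window: int = 500
    stagnation_acceptance: float = 0.01


@dataclass
class PosteriorSamples:
    chains: np.ndarray               # (n_chains, n_generations, d)
    log_posterior: np.ndarray        # (n_chains, n_generations)
    prior: PriorSpec
    total_lv_resistance: float
    burn_in_fraction: float = 0.5
    acceptance_rate: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.chains.shape[1] * (1.0 - self.burn_in_fraction))

    def post_burn_in(self) -> np.ndarray:
        """Chains after discarding the burn-in fraction: (m, n_kept, d)."""
        start = self.chains.shape[1] - self.n_kept
        return self.chains[:, start:, :]

    def flat(self) -> np.ndarray:
        kept = self.post_burn_in()
        return kept.reshape(-1, kept.shape[-1])

    @property
    def gelman_rubin(self) -> np.ndarray:
        return gelman_rubin(self.post_burn_in())

    def thinned(self, thin: int = 10) -> np.ndarray:
        return self.flat()[::thin]

    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        return pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q05": np.quantile(flat, 0.05, axis=0),
            "q50": np.quantile(flat, 0.50, axis=0),
            "q95": np.quantile(flat, 0.95, axis=0),
            "rhat": self.gelman_rubin,
        })


class StagnationError(RuntimeError):
    pass


def dream_sample(prior: PriorSpec, log_lik: Callable[[np.ndarray], float],
                 total_lv_resistance: float | None = None,
                 config: DreamConfig | None = None,
                 seed: int | None = None) -> PosteriorSamples:
    """DE-MC sampling with subspace crossover and total-resistance rescaling.

    Proposals are z* = z_i + gamma(delta) * sum(z_a - z_b) + e restricted to a
    random crossover subspace, with occasional gamma = 1 mode-jumping moves.
    Each proposal is rescaled so the parallel total resistance is preserved;
    proposals leaving the prior box after rescaling are rejected.
    """
    cfg = config or DreamConfig()
    rng = np.random.default_rng(seed)
    d = len(prior.r_hat)
    m = cfg.n_chains
    if m < 2 * d:
        warnings.warn(f"{m} chains < 2*dim = {2 * d}; DREAM guidance suggests more",
                      stacklevel=2)
    if m < 4:
        raise ValueError("need at least 4 chains")
    total = (total_lv_resistance if total_lv_resistance is not None
             else parallel_total(prior.r_hat))

    def project(r: np.ndarray) -> np.ndarray:
        if not cfg.constrain_total:
            return r
        return rescale_preserve_total(r, total)

    # initialize chains inside the box after rescaling
    state = np.empty((m, d))
    filled = 0
    for _ in range(1000):
        cand = project(prior.sample(m, rng))
        ok = prior.contains(cand)
        take = min(int(ok.sum()), m - filled)
        state[filled:filled + take] = cand[ok][:take]
        filled += take
        if filled == m:
            break
    if filled < m:
        raise RuntimeError("could not initialize chains inside the prior box "
                           "after rescaling; check total resistance vs prior")
    logp = np.array([log_lik(state[i]) for i in range(m)])

    cr_values = (np.arange(cfg.n_cr) + 1.0) / cfg.n_cr
    p_cr = np.full(cfg.n_cr, 1.0 / cfg.n_cr)
    cr_counts = np.zeros(cfg.n_cr)
    cr_dist = np.zeros(cfg.n_cr)

    chains = np.empty((m, cfg.n_generations, d))
    lp_trace = np.empty((m, cfg.n_generations))
    n_burn = int(cfg.burn_in_fraction * cfg.n_generations)
    accepts = 0
    recent_accepts: list[int] = []

    for gen in range(cfg.n_generations):
        std = np.maximum(state.std(axis=0), 1e-12 * np.abs(state).mean())
        gen_accepts = 0
        delta_cap = min(cfg.delta_max, (m - 1) // 2)
        for i in range(m):
            others = np.delete(np.arange(m), i)
            delta = rng.integers(1, delta_cap + 1)
            picks = rng.choice(others, size=2 * delta, replace=False)
            diff = (state[picks[:delta]] - state[picks[delta:]]).sum(axis=0)
            icr = rng.choice(cfg.n_cr, p=p_cr)
            cr = cr_values[icr]
            mask = rng.random(d) < cr
            if not mask.any():
                mask[rng.integers(d)] = True
            d_eff = int(mask.sum())
            if rng.random() < cfg.jump_probability:
                gamma = 1.0
            else:
                gamma = 2.38 / np.sqrt(2.0 * delta * d_eff)
            prop = state[i].copy()
            e = rng.normal(0.0, cfg.jitter_sd * np.abs(state[i][mask]) + 1e-300)
            prop[mask] = state[i][mask] + gamma * diff[mask] + e
            if np.any(prop <= 0):
                chosen_logp = None  # negative resistance: reject outright
            else:
                prop = project(prop)
                chosen_logp = None
                if prior.contains(prop)[0]:
                    lp_prop = log_lik(prop)
                    if np.log(rng.random()) < lp_prop - logp[i]:
                        chosen_logp = lp_prop
            if chosen_logp is not None:
                jump = prop - state[i]
                state[i] = prop
                logp[i] = chosen_logp
                accepts += 1
                gen_accepts += 1
            else:
                jump = np.zeros(d)
            cr_counts[icr] += 1
            cr_dist[icr] += float(np.sum((jump / std) ** 2))
        chains[:, gen] = state
        lp_trace[:, gen] = logp
        recent_accepts.append(gen_accepts)
        if len(recent_accepts) > cfg.stagnation_window:
            recent_accepts.pop(0)
            rate = sum(recent_accepts) / (cfg.stagnation_window * m)
            if rate < cfg.stagnation_acceptance:
                raise StagnationError(
                    f"acceptance rate {rate:.3%} over the last "
                    f"{cfg.stagnation_window} generations; chains stagnated")
        in_burn = gen < n_burn
        if cfg.adapt_cr and in_burn and (gen + 1) % 10 == 0 and cr_counts.sum() > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(cr_counts > 0, cr_dist / cr_counts, 0.0)
            if score.sum() > 0:
                p_cr = 0.9 * p_cr + 0.1 * (score / score.sum())
                p_cr = np.maximum(p_cr, 0.01)
                p_cr /= p_cr.sum()
        # outlier-chain repair during burn-in (standard DREAM practice)
        if in_burn and (gen + 1) % cfg.outlier_check_interval == 0 and gen > 50:
            w = lp_trace[:, max(0, gen // 2):gen + 1].mean(axis=1)
            q1, q3 = np.quantile(w, [0.25, 0.75])
            bad = w < q1 - 2.0 * (q3 - q1)
            if bad.any():
                best = int(np.argmax(w))
                for i in np.nonzero(bad)[0]:
                    state[i] = state[best]
                    logp[i] = logp[best]

    return PosteriorSamples(
        chains=chains, log_posterior=lp_trace, prior=prior,
        total_lv_resistance=total, burn_in_fraction=cfg.burn_in_fraction,
        acceptance_rate=accepts / (m * cfg.n_generations),
        meta={"seed": seed, "config": cfg.__dict__.copy(), "p_cr": p_cr.tolist()})


def posterior_predictive_flows(samples: PosteriorSamples,
                               model: Callable[[np.ndarray], np.ndarray],
                               thin: int = 10):
    """Evaluate the flow model on thinned posterior samples.

    Returns (flows, summary): the raw (n, Nc) flow draws and a per-outlet
    DataFrame with mean, sd and quantiles.
    """
    draws = samples.thinned(thin)
    flows = np.array([model(r) for r in draws])
    summary = pd.DataFrame({
        "mean": flows.mean(axis=0),
        "sd": flows.std(axis=0, ddof=1),
        "q05": np.quantile(flows, 0.05, axis=0),
        "q50": np.quantile(flows, 0.50, axis=0),
        "q95": np.quantile(flows, 0.95, axis=0),
    })
    return flows, summary


# ---------------------------------------------------------------------------
# Stage-1 cardiac-function tuning (reduced)


DEFAULT_TUNABLE = ("lv_emax", "aortic_rd", "aortic_c")


def tune_cardiac_function(net, targets: dict, tunable: Sequence[str] = DEFAULT_TUNABLE,
                          n_cycles: int = 3, steps_per_cycle: int = 200,
                          maxiter: int = 40, weights: dict | None = None):
    """Reduced derivative-free tuning of gross cardiac function.

    Optimizes multiplicative scales on a small parameter subset
    (lv_emax, aortic_rd, aortic_c, lv_v0, systemic_venous_c) via Nelder-Mead
    so the closed-loop model matches targets:
    ``{"systolic_mmhg", "diastolic_mmhg", "stroke_volume_ml", "ejection_fraction"}``.
    Returns (tuned_network, result) with the scipy optimization result.
    """
    import copy

    from .units import mmhg

    w = {"systolic_mmhg": 1.0, "diastolic_mmhg": 1.0,
         "stroke_volume_ml": 1.0, "ejection_fraction": 1.0}
    w.update(weights or {})

    def apply(scales: np.ndarray):
        trial = copy.deepcopy(net)
        for name, s in zip(tunable, scales):
            s = float(np.exp(s))  # optimize in log space, always positive
            if name == "lv_emax":
                trial.chambers["lv"].elastance_max *= s
            elif name == "aortic_rd":
                trial.aortic_bc.Rd *= s
            elif name == "aortic_c":
                trial.aortic_bc.C *= s
            elif name == "lv_v0":
                trial.chambers["lv"].unstressed_volume *= s
            elif name == "systemic_venous_c":
                trial.systemic.C_systemic_venous *= s
            else:
                raise ValueError(f"unknown tunable parameter {name!r}")
        return trial

    def objective(scales: np.ndarray) -> float:
        trial = apply(scales)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = trial.simulate(n_cycles=n_cycles, steps_per_cycle=steps_per_cycle)
        except Exception:
            return 1e6
        pa = res.pressures["aorta"]
        vlv = res.volumes["vol_lv"]
        sv = float(vlv.max() - vlv.min())
        pred = {
            "systolic_mmhg": mmhg(float(pa.max())),
            "diastolic_mmhg": mmhg(float(pa.min())),
            "stroke_volume_ml": sv,
            "ejection_fraction": sv / float(vlv.max()),
        }
        err = 0.0
        for key, target in targets.items():
            err += w.get(key, 1.0) * ((pred[key] - target) / target) ** 2
        return err

    x0 = np.zeros(len(tunable))
    result = minimize(objective, x0, method="Nelder-Mead",
                      options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-5})
    return apply(result.x), result
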