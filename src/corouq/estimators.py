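"""Monte Carlo and multi-fidelity Monte Carlo (control variate) estimators.

The two-model MFMC estimator combines a pilot set of paired high/low
fidelity evaluations with extra low-fidelity evaluations:

    Q_hat = mean(HF) + alpha * (mean(LF, all) - mean(LF, pilot)),
    alpha = Cov(HF, LF) / Var(LF),
    Var[Q_hat] = Var[Q_hat_MC] * (1 - (Delta/N_lf) * rho^2).

All moments use the unbiased (N-1) sample convention.  Confidence intervals
are distribution-free Chebyshev intervals with half-width sigma/sqrt(1-level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class SamplePairSet:
    """Index-aligned paired pilot samples plus extra LF-only values."""

    hf_values: np.ndarray
    lf_values_at_hf_inputs: np.ndarray
    lf_values_extra: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.hf_values = np.asarray(self.hf_values, float)
        self.lf_values_at_hf_inputs = np.asarray(self.lf_values_at_hf_inputs, float)
        self.lf_values_extra = np.asarray(self.lf_values_extra, float)
        if self.hf_values.shape != self.lf_values_at_hf_inputs.shape:
            raise ValueError("pilot HF and LF arrays must be index-aligned")

    @property
    def n_hf(self) -> int:
        return len(self.hf_values)

    @property
    def n_lf(self) -> int:
        return self.n_hf + len(self.lf_values_extra)

    @property
    def all_lf(self) -> np.ndarray:
        return np.concatenate([self.lf_values_at_hf_inputs, self.lf_values_extra])


@dataclass
class EstimatorResult:
    estimator: str
    mean: float
    variance: float
    rho: float = np.nan
    alpha: float = np.nan
    n_hf: int = 0
    n_lf: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        return chebyshev_interval(self, level)

    def to_dict(self) -> dict:
        lo95, hi95 = self.interval(0.95)
        lo99, hi99 = self.interval(0.99)
        return {
            "estimator": self.estimator, "mean": self.mean, "variance": self.variance,
            "rho": None if np.isnan(self.rho) else self.rho,
            "alpha": None if np.isnan(self.alpha) else self.alpha,
            "ci95": [lo95, hi95], "ci99": [lo99, hi99],
            "N3D": self.n_hf, "N0D": self.n_lf,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def mc_estimate(values: np.ndarray, label: str = "MC") -> EstimatorResult:
    """Plain Monte Carlo mean with variance = sample variance / N."""
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 samples")
    return EstimatorResult(estimator=label, mean=float(values.mean()),
                           variance=float(values.var(ddof=1) / n),
                           n_hf=n, n_lf=0)


def control_coefficient(pairs: SamplePairSet) -> float:
    """Variance-optimal control coefficient Cov(HF, LF) / Var(LF) from the
    paired pilot samples."""
    lf = pairs.lf_values_at_hf_inputs
    var_lf = lf.var(ddof=1)
    if var_lf == 0:
        raise ValueError("low-fidelity pilot variance is zero")
    cov = np.cov(pairs.hf_values, lf, ddof=1)[0, 1]
    return float(cov / var_lf)


def pearson(pairs: SamplePairSet) -> float:
    hf, lf = pairs.hf_values, pairs.lf_values_at_hf_inputs
    if hf.std() == 0 or lf.std() == 0:
        return 0.0
    return float(np.corrcoef(hf, lf)[0, 1])


def mfmc_estimate(pairs: SamplePairSet, alpha: float | None = None,
                  label: str = "MFMC") -> EstimatorResult:
    """Two-model control-variate estimator with its analytic variance."""
    n_hf, n_lf = pairs.n_hf, pairs.n_lf
    if n_hf < 2:
        raise ValueError("need at least 2 pilot samples")
    if alpha is None:
        alpha = control_coefficient(pairs)
    rho = pearson(pairs)
    mean = float(pairs.hf_values.mean()
                 + alpha * (pairs.all_lf.mean() - pairs.lf_values_at_hf_inputs.mean()))
    var_mc = pairs.hf_values.var(ddof=1) / n_hf
    delta = n_lf - n_hf
    variance = float(var_mc * (1.0 - (delta / n_lf) * rho**2)) if n_lf > 0 else float(var_mc)
    return EstimatorResult(estimator=label, mean=mean, variance=variance,
                           rho=rho, alpha=float(alpha), n_hf=n_hf, n_lf=n_lf)


def chebyshev_interval(result: EstimatorResult, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free interval: half-width = sd / sqrt(1 - level)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    half = result.sd / np.sqrt(1.0 - level)
    return (float(result.mean - half), float(result.mean + half))


@dataclass
class AllocationPlan:
    budget: float
    cost_ratio: float
    gamma: float
    n_hf: int
    n_lf: int

    def total_cost(self) -> float:
        return self.n_hf + self.cost_ratio * self.n_lf


def optimal_allocation(budget: float, cost_ratio: float, rho: float) -> AllocationPlan:
    """Variance-optimal sample allocation at fixed budget (HF-equivalent
    cost units):  gamma = sqrt(rho^2 / (w * (1 - rho^2))),
    N_hf = B / (1 + w * gamma), N_lf = gamma * N_hf.

    Counts are floored (N_hf >= 1) and leftover budget is spent on extra LF
    samples.
    """
    rho2 = float(rho) ** 2
    if rho2 >= 1.0:
        raise ValueError("|rho| = 1 gives an unbounded LF-to-HF ratio")
    if not 0.0 < cost_ratio < 1.0:
        raise ValueError("cost ratio w must be in (0, 1)")
    if budget < 1.0:
        raise ValueError("budget must cover at least one HF sample")
    gamma = np.sqrt(rho2 / (cost_ratio * (1.0 - rho2)))
    n_hf = max(int(np.floor(budget / (1.0 + cost_ratio * gamma) + 1e-9)), 1)
    if gamma == 0.0:
        return AllocationPlan(budget=budget, cost_ratio=cost_ratio, gamma=0.0,
                              n_hf=n_hf, n_lf=0)
    n_lf = max(int(np.floor(gamma * n_hf)), n_hf)
    leftover = budget - n_hf - cost_ratio * n_lf
    if leftover > 0:
        n_lf += int(np.floor(leftover / cost_ratio))
    return AllocationPlan(budget=budget, cost_ratio=cost_ratio, gamma=float(gamma),
                          n_hf=n_hf, n_lf=n_lf)


def mfmc_variance(var_hf: float, n_hf: int, n_lf: int, rho: float) -> float:
    """Analytic MFMC variance for given counts and correlation."""
    if n_lf <= 0:
        return var_hf / n_hf
    delta = n_lf - n_hf
    return var_hf / n_hf * (1.0 - (delta / n_lf) * rho**2)


@dataclass
class TrialStudyReport:
    estimator: str
    n_trials: int
    means: np.ndarray
    empirical_mean: float
    empirical_variance: float
    analytic_variance: float
    true_mean: float | None = None

    @property
    def variance_ratio(self) -> float:
        return self.empirical_variance / self.analytic_variance

    @property
    def bias(self) -> float | None:
        if self.true_mean is None:
            return None
        return self.empirical_mean - self.true_mean

    @property
    def bias_se(self) -> float:
        return float(np.sqrt(self.empirical_variance / self.n_trials))


def estimator_trial_study(draw_inputs: Callable[[np.random.Generator, int], np.ndarray],
                          hf_model: Callable[[np.ndarray], np.ndarray],
                          lf_model: Callable[[np.ndarray], np.ndarray] | None,
                          n_hf: int, n_lf: int, n_trials: int,
                          seed: int | None = None,
                          true_mean: float | None = None,
                          estimator: str = "MFMC") -> TrialStudyReport:
    """Empirical bias/variance of an estimator over independent trials.

    ``draw_inputs(rng, n)`` returns an (n, d) input matrix; ``hf_model`` /
    ``lf_model`` map it to value vectors.  The analytic variance reported is
    the mean of the per-trial analytic variances.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    means = np.empty(n_trials)
    analytic = np.empty(n_trials)
    for t in range(n_trials):
        theta = draw_inputs(rng, n_lf if estimator != "MC" else n_hf)
        hf = hf_model(theta[:n_hf])
        if estimator == "MC":
            res = mc_estimate(hf)
        else:
            lf_all = lf_model(theta)
            pairs = SamplePairSet(hf_values=hf,
                                  lf_values_at_hf_inputs=lf_all[:n_hf],
                                  lf_values_extra=lf_all[n_hf:])
            res = mfmc_estimate(pairs, label=estimator)
        means[t] = res.mean
        analytic[t] = res.variance
    return TrialStudyReport(
        estimator=estimator, n_trials=n_trials, means=means,
        empirical_mean=float(means.mean()),
        empirical_variance=float(means.var(ddof=1)),
        analytic_variance=float(analytic.mean()),
        true_mean=true_mean)
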