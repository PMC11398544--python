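# corouq

Personalized, uncertainty-aware coronary hemodynamics in Python:

- **0D circulation models** (`corouq.zerod`): a closed-loop lumped-parameter
  simulator (time-varying elastance chambers, smoothed valves, an aortic
  Windkessel, coronary outlet beds with intramyocardial pressure, quadratic
  stenosis losses `dP = S|Q|Q`), built from a coronary-tree description with
  Poiseuille-scaled segment parameters, plus a fast steady flow-split solver
  used as the inner model for parameter estimation. Hyperemia is modeled by
  scaling the distal coronary resistances by 0.24.
- **Synthetic cohort** (`corouq.cohort`): seeded generators for coronary
  trees (three mains, tapering binary branching, one stenosis per main) and
  LV point clouds with smooth myocardial-blood-flow fields.
- **Perfusion flow targets** (`corouq.targets`): nearest-outlet territory
  tessellation of the LV, MBF integration into branch flow targets, and a
  Monte Carlo noise model (Gaussian distance noise, sd = 10% of distance;
  multiplicative MBF noise, sd = 20%) yielding a mean vector and a
  non-diagonal covariance over realizations.
- **Bayesian personalization** (`corouq.personalize`): DREAM-style
  differential-evolution adaptive Metropolis sampling of LV-outlet
  resistances under a Gaussian flow-target likelihood, with per-generation
  rescaling that preserves the total (parallel) coronary resistance,
  uniform priors on `[0.5 r_hat, 2.0 r_hat]`, split Gelman-Rubin
  diagnostics, and a reduced Nelder-Mead cardiac-function tuner.
- **Quantities of interest** (`corouq.qoi`): TAWSS, OSI, FFR, mean flow,
  a configurable high-fidelity surrogate (stand-in for 3D CFD; real
  evaluations can be supplied as delimited sample tables), and posterior
  input sampling with the total-resistance scale `s ~ U(0.7, 1.25)`.
- **Multi-fidelity estimators** (`corouq.estimators`): MC and two-model
  control-variate MFMC estimation with analytic variance, distribution-free
  Chebyshev intervals, optimal budget allocation, and trial-study harnesses.
- **Shared-space resampling** (`corouq.sharedspace`): supervised
  autoencoders (1D latent) per fidelity linked by analytic empirical-CDF
  normalizing flows; two-stage training with a correlation bonus produces a
  re-parameterized low-fidelity model whose outputs correlate strongly with
  the high-fidelity response (MFMC-AE). Networks are trained with a small
  built-in reverse-mode autodiff engine (no external DL framework needed).
- **Pipeline + CLI** (`corouq.pipeline`, `corouq.cli`): end-to-end
  orchestration with YAML config, JSON/CSV artifacts, and provenance.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (MCMC convergence, OSI bounds, analytic-variance consistency,
allocation optimality, correlation improvement, estimator unbiasedness,
parameter recovery, physics oracles). Full runtime is a few minutes; the
14-outlet DREAM recovery problem dominates.

## CLI

```sh
corouq fixtures --n-outlets 14 --seed 1 --out fixtures/
corouq targets --tree fixtures/tree.csv --lv fixtures/lv.csv \
       --n-realizations 2500 --seed 1 --out targets.json
corouq personalize --chains 16 --generations 4000 --seed 1 --out runs/demo
corouq estimate --n-hf 100 --n-lf 1000 --seed 1 --out runs/demo
corouq run --seed 1 --out runs/demo       # full pipeline
corouq report runs/demo
corouq shared-space train --hf-table hf.csv --lf-table lf.csv
```

All stages are also scriptable; see `corouq.pipeline.run_pipeline` and the
YAML schema in `corouq.pipeline.DEFAULT_CONFIG`.

## Units

CGS internally (dyn, cm, s); mmHg and mL/min only at I/O boundaries
(`corouq.units`).
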