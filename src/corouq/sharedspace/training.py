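"""Supervised autoencoders, two-stage training, and shared-space resampling.

Stage 1 learns, per fidelity, a 1D latent manifold capturing the QoI
variation: encoder E, decoder D and a latent-space surrogate head Q_NN are
trained jointly on a four-term reconstruction/surrogate consistency loss.
Stage 2 links the two latent spaces through analytic normalizing flows
(empirical-CDF Gaussianization) and fine-tunes both autoencoders with a
correlation bonus between the high-fidelity outputs and the resampled
low-fidelity surrogate.  The resulting map re-parameterizes the low-fidelity
model so its outputs correlate strongly with the high-fidelity response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..estimators import EstimatorResult, SamplePairSet, mfmc_estimate
from .autodiff import Adam, Tensor, mse, pearson
from .flow import NormalizingFlow1D, composed_transfer_knots
from .nets import MLP, Standardizer


@dataclass
class ArchConfig:
    latent_dim: int = 1
    hidden: tuple[int, ...] = (32, 32)
    surrogate_hidden: tuple[int, ...] = (32, 32)
    lr: float = 1e-3
    max_epochs: int = 2000
    val_fraction: float = 0.2
    patience: int = 25              # validation checks (every `check_every`)
    check_every: int = 10
    correlation_weight: float = 1.0
    stage2_max_epochs: int = 600
    flow_refit_every: int = 10
    use_true_lf_in_corr: bool = False   # config switch: true Q0D vs surrogate

    def __post_init__(self) -> None:
        if self.latent_dim != 1:
            raise ValueError(
                "only a 1D latent space is supported (analytic flows); "
                f"got latent_dim={self.latent_dim}")


@dataclass
class AEModel:
    encoder: MLP
    decoder: MLP
    qnn: MLP
    x_std: Standardizer
    q_std: Standardizer
    arch: ArchConfig
    history: dict = field(default_factory=dict)

    def encode(self, theta: np.ndarray) -> np.ndarray:
        """Latent coordinates for raw inputs (returns shape (n,))."""
        x = self.x_std.transform(np.atleast_2d(theta))
        return self.encoder.forward_np(x).ravel()

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Raw-input-space reconstruction from latent coordinates."""
        z = np.asarray(z, float).reshape(-1, 1)
        return self.x_std.inverse(self.decoder.forward_np(z))

    def surrogate(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float).reshape(-1, 1)
        return self.q_std.inverse(self.qnn.forward_np(z).ravel())

    def parameters(self):
        return (self.encoder.parameters() + self.decoder.parameters()
                + self.qnn.parameters())


def _stage1_loss(enc: MLP, dec: MLP, qnn: MLP, x: Tensor, q: Tensor) -> Tensor:
    z = enc(x)
    q1 = qnn(z)
    xr = dec(z)
    z2 = enc(xr)
    q2 = qnn(z2)
    xrr = dec(z2)
    return mse(q, q1) + mse(q, q2) + mse(q1, q2) + mse(xr, xrr)


def train_stage1(inputs: np.ndarray, qoi_values: np.ndarray,
                 arch: ArchConfig | None = None, seed: int | None = None) -> AEModel:
    """Train one supervised autoencoder on (theta, Q) samples."""
    arch = arch or ArchConfig()
    inputs = np.atleast_2d(np.asarray(inputs, float))
    qoi_values = np.asarray(qoi_values, float).ravel()
    n, d = inputs.shape
    if n < 25:
        raise ValueError("need at least 25 training samples")
    if not (np.all(np.isfinite(inputs)) and np.all(np.isfinite(qoi_values))):
        raise ValueError("non-finite training data")
    rng = np.random.default_rng(seed)
    x_std = Standardizer(inputs)
    q_std = Standardizer(qoi_values.reshape(-1, 1))
    x = x_std.transform(inputs)
    q = q_std.transform(qoi_values.reshape(-1, 1))
    perm = rng.permutation(n)
    n_val = max(int(arch.val_fraction * n), 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr, q_tr = Tensor(x[tr_idx]), Tensor(q[tr_idx])
    x_val, q_val = Tensor(x[val_idx]), Tensor(q[val_idx])

    enc = MLP([d, *arch.hidden, arch.latent_dim], rng)
    dec = MLP([arch.latent_dim, *arch.hidden, d], rng)
    qnn = MLP([arch.latent_dim, *arch.surrogate_hidden, 1], rng)
    params = enc.parameters() + dec.parameters() + qnn.parameters()
    opt = Adam(params, lr=arch.lr)

    best_val = np.inf
    best_state = [p.value.copy() for p in params]
    strikes = 0
    history = {"train": [], "val": []}
    for epoch in range(arch.max_epochs):
        opt.zero_grad()
        loss = _stage1_loss(enc, dec, qnn, x_tr, q_tr)
        if not np.isfinite(loss.value):
            raise RuntimeError(f"non-finite stage-1 loss at epoch {epoch}")
        loss.backward()
        opt.step()
        if (epoch + 1) % arch.check_every == 0:
            vl = float(_stage1_loss(enc, dec, qnn, x_val, q_val).value)
            history["train"].append(float(loss.value))
            history["val"].append(vl)
            if vl < best_val - 1e-8:
                best_val = vl
                best_state = [p.value.copy() for p in params]
                strikes = 0
            else:
                strikes += 1
                if strikes >= arch.patience:
                    break
    for p, v in zip(params, best_state):
        p.value = v
    return AEModel(encoder=enc, decoder=dec, qnn=qnn, x_std=x_std, q_std=q_std,
                   arch=arch, history=history)


def fit_flow(latent_samples: np.ndarray, eps: float = 1e-4) -> NormalizingFlow1D:
    """Empirical-CDF Gaussianization of a 1D latent sample."""
    return NormalizingFlow1D.fit(latent_samples, eps=eps)


@dataclass
class SharedSpaceMap:
    """Trained shared-space link between a high- and a low-fidelity model."""

    hf_ae: AEModel
    lf_ae: AEModel
    hf_flow: NormalizingFlow1D
    lf_flow: NormalizingFlow1D
    lf_model: Callable[[np.ndarray], np.ndarray] | None = None
    rho_original: float = np.nan
    rho_ae: float = np.nan
    orientation: int = 1     # -1 reverses the LF quantile (sign convention)
    meta: dict = field(default_factory=dict)

    def transfer_latent(self, z_hf: np.ndarray) -> np.ndarray:
        """Map HF latent values to LF latent values through the shared
        (uniform/Gaussian) space; piecewise linear and monotone."""
        u = self.hf_flow.cdf(np.asarray(z_hf, float))
        if self.orientation < 0:
            u = 1.0 - u
        return np.interp(u, self.lf_flow.positions, self.lf_flow.knots)

    def resample_inputs(self, hf_inputs: np.ndarray) -> np.ndarray:
        """Eq.-of-motion of the method: HF input -> shared space -> LF input."""
        z_hf = self.hf_ae.encode(hf_inputs)
        z_lf = self.transfer_latent(z_hf)
        return self.lf_ae.decode(z_lf)

    def resample_lf(self, hf_inputs: np.ndarray,
                    lf_model: Callable[[np.ndarray], np.ndarray] | None = None) -> np.ndarray:
        """Resampled low-fidelity QoI values, index-aligned with hf_inputs.

        Uses the true LF model on reconstructed LF inputs when available,
        otherwise the latent surrogate head."""
        model = lf_model or self.lf_model
        theta_lf = self.resample_inputs(hf_inputs)
        if model is not None:
            return np.asarray(model(theta_lf), float)
        z_lf = self.lf_ae.encode(theta_lf)
        return self.lf_ae.surrogate(z_lf)


def train_stage2(hf_ae: AEModel, lf_ae: AEModel,
                 hf_inputs: np.ndarray, hf_qoi: np.ndarray,
                 lf_inputs: np.ndarray, lf_qoi: np.ndarray,
                 lf_model: Callable[[np.ndarray], np.ndarray] | None = None,
                 lf_values_at_hf_inputs: np.ndarray | None = None,
                 arch: ArchConfig | None = None,
                 seed: int | None = None) -> SharedSpaceMap:
    """Joint fine-tuning with the correlation bonus term.

    Weights start from the stage-1 optima.  The flow transforms are refit
    from the current latent samples every ``flow_refit_every`` epochs and
    held fixed (piecewise-linear, differentiable) in between.
    """
    arch = arch or hf_ae.arch
    hf_inputs = np.atleast_2d(np.asarray(hf_inputs, float))
    lf_inputs = np.atleast_2d(np.asarray(lf_inputs, float))
    hf_qoi = np.asarray(hf_qoi, float).ravel()
    lf_qoi = np.asarray(lf_qoi, float).ravel()
    if hf_qoi.std() == 0:
        raise ValueError("zero-variance high-fidelity QoI: correlation undefined")

    x3 = Tensor(hf_ae.x_std.transform(hf_inputs))
    q3 = Tensor(hf_ae.q_std.transform(hf_qoi.reshape(-1, 1)))
    x0 = Tensor(lf_ae.x_std.transform(lf_inputs))
    q0 = Tensor(lf_ae.q_std.transform(lf_qoi.reshape(-1, 1)))
    params = hf_ae.parameters() + lf_ae.parameters()
    opt = Adam(params, lr=arch.lr)

    def refit_flows():
        z3 = hf_ae.encoder.forward_np(x3.value).ravel()
        z0 = lf_ae.encoder.forward_np(x0.value).ravel()
        return NormalizingFlow1D.fit(z3), NormalizingFlow1D.fit(z0)

    hf_flow, lf_flow = refit_flows()
    best = {"rho": -np.inf, "state": [p.value.copy() for p in params],
            "flows": (hf_flow, lf_flow)}
    history = {"loss": [], "rho": []}
    for epoch in range(arch.stage2_max_epochs):
        if epoch % arch.flow_refit_every == 0 and epoch > 0:
            hf_flow, lf_flow = refit_flows()
        xs, ys = composed_transfer_knots(hf_flow, lf_flow)
        opt.zero_grad()
        l3 = _stage1_loss(hf_ae.encoder, hf_ae.decoder, hf_ae.qnn, x3, q3)
        l0 = _stage1_loss(lf_ae.encoder, lf_ae.decoder, lf_ae.qnn, x0, q0)
        z3 = hf_ae.encoder(x3)
        z0_re = z3.piecewise_linear(xs, ys)
        q0_re = lf_ae.qnn(z0_re)
        rho_t = pearson(q3.value, q0_re).abs()
        loss = l3 + l0 - arch.correlation_weight * rho_t
        if not np.isfinite(loss.value):
            raise RuntimeError(f"non-finite stage-2 loss at epoch {epoch}")
        loss.backward()
        opt.step()
        history["loss"].append(float(loss.value))
        history["rho"].append(float(rho_t.value))
        if rho_t.value > best["rho"]:
            best = {"rho": float(rho_t.value),
                    "state": [p.value.copy() for p in params],
                    "flows": (hf_flow, lf_flow)}
    for p, v in zip(params, best["state"]):
        p.value = v
    hf_flow, lf_flow = best["flows"]

    smap = SharedSpaceMap(hf_ae=hf_ae, lf_ae=lf_ae, hf_flow=hf_flow,
                          lf_flow=lf_flow, lf_model=lf_model,
                          meta={"seed": seed, "history": history})
    if lf_values_at_hf_inputs is not None:
        lv = np.asarray(lf_values_at_hf_inputs, float).ravel()
        smap.rho_original = float(np.corrcoef(hf_qoi, lv)[0, 1])
    # pick the latent orientation giving the larger positive correlation
    # (the |rho| bonus is sign-blind; reversing the shared-space quantile is
    # an exact monotone relabeling of the LF latent)
    rho_by_orientation = {}
    for orient in (1, -1):
        smap.orientation = orient
        q_ae = smap.resample_lf(hf_inputs)
        rho_by_orientation[orient] = (float(np.corrcoef(hf_qoi, q_ae)[0, 1])
                                      if np.std(q_ae) > 0 else 0.0)
    smap.orientation = max(rho_by_orientation, key=rho_by_orientation.get)
    smap.rho_ae = rho_by_orientation[smap.orientation]
    return smap


def train_shared_space(hf_inputs: np.ndarray, hf_qoi: np.ndarray,
                       lf_inputs: np.ndarray, lf_qoi: np.ndarray,
                       lf_model: Callable[[np.ndarray], np.ndarray] | None = None,
                       lf_values_at_hf_inputs: np.ndarray | None = None,
                       arch: ArchConfig | None = None,
                       seed: int | None = None) -> SharedSpaceMap:
    """Convenience wrapper: stage-1 training per fidelity, then stage 2."""
    arch = arch or ArchConfig()
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2**31, size=3)
    hf_ae = train_stage1(hf_inputs, hf_qoi, arch=arch, seed=int(s1))
    lf_ae = train_stage1(lf_inputs, lf_qoi, arch=arch, seed=int(s2))
    return train_stage2(hf_ae, lf_ae, hf_inputs, hf_qoi, lf_inputs, lf_qoi,
                        lf_model=lf_model,
                        lf_values_at_hf_inputs=lf_values_at_hf_inputs,
                        arch=arch, seed=int(s3))


def mfmc_ae_estimate(smap: SharedSpaceMap, hf_inputs_pilot: np.ndarray,
                     hf_values: np.ndarray, extra_hf_inputs: np.ndarray,
                     lf_model: Callable[[np.ndarray], np.ndarray] | None = None
                     ) -> EstimatorResult:
    """Control-variate estimator with the resampled LF model as control.

    ``extra_hf_inputs`` are additional draws from the HF input distribution
    evaluated only through the (cheap) resampled LF chain.
    """
    hf_inputs_pilot = np.atleast_2d(hf_inputs_pilot)
    extra_hf_inputs = np.atleast_2d(extra_hf_inputs) if len(extra_hf_inputs) else \
        np.empty((0, hf_inputs_pilot.shape[1]))
    lf_pilot = smap.resample_lf(hf_inputs_pilot, lf_model=lf_model)
    lf_extra = (smap.resample_lf(extra_hf_inputs, lf_model=lf_model)
                if len(extra_hf_inputs) else np.empty(0))
    pairs = SamplePairSet(hf_values=hf_values, lf_values_at_hf_inputs=lf_pilot,
                          lf_values_extra=lf_extra)
    return mfmc_estimate(pairs, label="MFMC-AE")


def convergence_study(draw_inputs: Callable[[np.random.Generator, int], np.ndarray],
                      hf_model: Callable[[np.ndarray], np.ndarray],
                      lf_model: Callable[[np.ndarray], np.ndarray],
                      pilot_sizes: list[int], n_trials: int,
                      seed: int | None = None,
                      arch: ArchConfig | None = None):
    """Repeatability of rho, rho_AE and the MC mean versus pilot size.

    Returns a pandas DataFrame with one row per (pilot size, trial).
    """
    import pandas as pd

    if min(pilot_sizes) < 25:
        raise ValueError("pilot sizes must be >= 25")
    rng = np.random.default_rng(seed)
    rows = []
    for n_pilot in pilot_sizes:
        for trial in range(n_trials):
            theta = draw_inputs(rng, n_pilot)
            hf = hf_model(theta)
            lf = lf_model(theta)
            smap = train_shared_space(theta, hf, theta, lf, lf_model=lf_model,
                                      lf_values_at_hf_inputs=lf, arch=arch,
                                      seed=int(rng.integers(0, 2**31)))
            rows.append({"n_pilot": n_pilot, "trial": trial,
                         "rho": smap.rho_original, "rho_ae": smap.rho_ae,
                         "mc_mean": float(np.mean(hf))})
    return pd.DataFrame(rows)
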