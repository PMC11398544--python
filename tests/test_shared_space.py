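"""Tests for the autodiff engine, normalizing flows, and shared-space
autoencoder training."""

import numpy as np
import pytest
from scipy import stats

from corouq.modelpairs import correlation_battery, identical_pair
from corouq.sharedspace import (
    AEModel,
    ArchConfig,
    MLP,
    NormalizingFlow1D,
    Tensor,
    composed_transfer_knots,
    fit_flow,
    mfmc_ae_estimate,
    pearson,
    train_shared_space,
    train_stage1,
    train_stage2,
)
from corouq.sharedspace.autodiff import mse

FAST = ArchConfig(hidden=(16, 16), surrogate_hidden=(16, 16),
                  max_epochs=600, stage2_max_epochs=200, lr=3e-3)


class TestAutodiff:
    def numeric_grad(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        for i in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            g[i] = (f(xp) - f(xm)) / (2 * eps)
        return g

    @pytest.mark.parametrize("expr", [
        lambda t: (t * t).sum(),
        lambda t: (t @ Tensor(np.arange(12.0).reshape(4, 3))).square().mean(),
        lambda t: t.tanh().sum(),
        lambda t: (t.abs() + t).mean(),
        lambda t: ((t + 2.0) / (t.square() + 1.0)).sum(),
        lambda t: (t.square().sum() + Tensor(1e-3)).sqrt(),
    ])
    def test_gradients_match_finite_differences(self, expr, rng):
        x = rng.normal(size=(5, 4))

        def f(v):
            return float(expr(Tensor(v)).value)

        t = Tensor(x.copy(), requires_grad=True)
        out = expr(t)
        out.backward()
        assert np.allclose(t.grad, self.numeric_grad(f, x), atol=1e-5)

    def test_broadcast_bias_gradient(self, rng):
        x = rng.normal(size=(7, 3))
        b = rng.normal(size=3)

        def f(bv):
            return float(((Tensor(x) + Tensor(bv)).square()).sum().value)

        t = Tensor(b.copy(), requires_grad=True)
        out = (Tensor(x) + t).square().sum()
        out.backward()
        assert np.allclose(t.grad, self.numeric_grad(f, b), atol=1e-5)

    def test_pearson_gradient(self, rng):
        a = rng.normal(size=10)
        x = rng.normal(size=(10, 1))

        def f(v):
            return float(pearson(a, Tensor(v)).value)

        t = Tensor(x.copy(), requires_grad=True)
        pearson(a, t).backward()
        assert np.allclose(t.grad, self.numeric_grad(f, x), atol=1e-5)

    def test_piecewise_linear_value_and_grad(self):
        xs = np.array([0.0, 1.0, 2.0])
        ys = np.array([0.0, 2.0, 3.0])
        t = Tensor(np.array([0.5, 1.5]), requires_grad=True)
        out = t.piecewise_linear(xs, ys)
        assert np.allclose(out.value, [1.0, 2.5])
        out.sum().backward()
        assert np.allclose(t.grad, [2.0, 1.0])

    def test_mse_zero_on_equal(self, rng):
        x = Tensor(rng.normal(size=(4, 2)))
        assert mse(x, x).value == 0.0


class TestMLP:
    def test_shapes_and_determinism(self):
        rng = np.random.default_rng(0)
        net = MLP([3, 8, 1], rng)
        x = np.random.default_rng(1).normal(size=(5, 3))
        y1 = net.forward_np(x)
        y2 = net.forward_np(x)
        assert y1.shape == (5, 1)
        assert np.array_equal(y1, y2)

    def test_state_round_trip(self, rng):
        net = MLP([2, 4, 1], np.random.default_rng(3))
        state = net.get_state()
        x = rng.normal(size=(3, 2))
        y0 = net.forward_np(x)
        for p in net.parameters():
            p.value += 1.0
        net.set_state(state)
        assert np.allclose(net.forward_np(x), y0)


class TestNormalizingFlow:
    @pytest.fixture
    def samples(self, rng):
        return rng.gamma(2.0, 1.5, size=400)  # skewed, non-Gaussian

    def test_median_maps_near_zero(self, samples):
        flow = fit_flow(samples)
        med = np.median(samples)
        assert abs(flow.forward(np.array([med]))[0]) < 0.05

    def test_transformed_samples_pass_normality(self, samples):
        flow = fit_flow(samples)
        x = flow.forward(samples)
        assert stats.kstest(x, "norm").pvalue > 0.01

    def test_round_trip_identity(self, samples):
        flow = fit_flow(samples)
        z = np.linspace(samples.min(), samples.max(), 200)
        back = flow.inverse(flow.forward(z))
        assert np.max(np.abs(back - z)) < 1e-6

    def test_forward_strictly_monotone(self, samples):
        flow = fit_flow(samples)
        z = np.linspace(samples.min(), samples.max(), 500)
        assert np.all(np.diff(flow.forward(z)) > 0)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_flow(np.full(50, 3.0))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_flow(rng.normal(size=10))

    def test_clip_counting(self, samples):
        flow = fit_flow(samples)
        flow.inverse(np.array([50.0, -50.0]))  # far outside the support image
        assert flow.n_clipped == 2

    def test_composed_transfer_monotone(self, rng):
        f1 = fit_flow(rng.normal(size=300))
        f2 = fit_flow(rng.gamma(3.0, 1.0, size=300))
        xs, ys = composed_transfer_knots(f1, f2)
        assert np.all(np.diff(xs) > 0)
        assert np.all(np.diff(ys) >= 0)


class TestStage1:
    def test_single_coordinate_qoi_r2(self, rng):
        # QoI depends on one coordinate; remaining coordinates are noise
        theta = rng.normal(size=(300, 5))
        q = np.tanh(theta[:, 2]) + 0.2 * theta[:, 2]
        ae = train_stage1(theta, q, arch=FAST, seed=0)
        held = rng.normal(size=(200, 5))
        q_h = np.tanh(held[:, 2]) + 0.2 * held[:, 2]
        pred = ae.surrogate(ae.encode(held))
        r2 = 1.0 - np.sum((pred - q_h) ** 2) / np.sum((q_h - q_h.mean()) ** 2)
        assert r2 > 0.95

    def test_rotated_active_subspace_r2(self, rng):
        w = np.array([0.5, -0.5, 0.5, 0.5])
        theta = rng.normal(size=(300, 4))
        q = np.sinh(0.7 * theta @ w)
        ae = train_stage1(theta, q, arch=FAST, seed=1)
        held = rng.normal(size=(200, 4))
        q_h = np.sinh(0.7 * held @ w)
        pred = ae.surrogate(ae.encode(held))
        r2 = 1.0 - np.sum((pred - q_h) ** 2) / np.sum((q_h - q_h.mean()) ** 2)
        assert r2 > 0.95

    def test_reconstruction_idempotence(self, rng):
        theta = rng.normal(size=(200, 4))
        q = theta @ np.array([1.0, 0.5, 0.0, 0.0])
        ae = train_stage1(theta, q, arch=FAST, seed=2)
        x1 = ae.decode(ae.encode(theta))
        x2 = ae.decode(ae.encode(x1))
        scale = np.std(theta)
        assert np.sqrt(np.mean((x1 - x2) ** 2)) < 0.1 * scale

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            train_stage1(rng.normal(size=(10, 3)), rng.normal(size=10))

    def test_multidim_latent_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(latent_dim=2)


@pytest.fixture(scope="module")
def trained_low_rho_map():
    """Shared-space map trained on the rho ~ 0.1 fixture pair."""
    pair = correlation_battery()[2]
    rng = np.random.default_rng(7)
    theta = pair.draw_inputs(rng, 200)
    hf, lf = pair.hf(theta), pair.lf(theta)
    smap = train_shared_space(theta, hf, theta, lf, lf_model=pair.lf,
                              lf_values_at_hf_inputs=lf, arch=FAST, seed=3)
    return pair, theta, hf, lf, smap


class TestStage2AndResampling:
    def test_correlation_boost_on_low_rho_pair(self, trained_low_rho_map):
        pair, _, _, _, smap = trained_low_rho_map
        assert abs(smap.rho_original) < 0.4
        assert abs(smap.rho_ae) > abs(smap.rho_original) + 0.2

    def test_resample_contract(self, trained_low_rho_map):
        pair, theta, _, _, smap = trained_low_rho_map
        rng = np.random.default_rng(0)
        new = pair.draw_inputs(rng, 57)
        out1 = smap.resample_lf(new)
        out2 = smap.resample_lf(new)
        assert out1.shape == (57,)
        assert np.array_equal(out1, out2)  # deterministic for a fixed map

    def test_resampled_inputs_have_lf_dimension(self, trained_low_rho_map):
        pair, theta, _, _, smap = trained_low_rho_map
        rec = smap.resample_inputs(theta[:10])
        assert rec.shape == (10, pair.dim)

    def test_identical_pair_degenerate_consistency(self, rng):
        # same model, same AE weights on both sides -> resampling is (near)
        # identity and the correlation is ~1
        pair = identical_pair()
        theta = pair.draw_inputs(rng, 200)
        q = pair.hf(theta)
        ae = train_stage1(theta, q, arch=FAST, seed=5)
        z = ae.encode(theta)
        flow = fit_flow(z)
        from corouq.sharedspace import SharedSpaceMap
        smap = SharedSpaceMap(hf_ae=ae, lf_ae=ae, hf_flow=flow, lf_flow=flow,
                              lf_model=pair.lf)
        q_re = smap.resample_lf(theta)
        rho = np.corrcoef(q, q_re)[0, 1]
        assert rho > 0.99
        # latent transfer through identical flows is the identity
        assert np.allclose(smap.transfer_latent(z), z, atol=1e-8)

    def test_anticorrelated_pair_flips_positive(self, rng):
        pair = correlation_battery()[0]  # rho ~ -0.9
        theta = pair.draw_inputs(rng, 200)
        hf, lf = pair.hf(theta), pair.lf(theta)
        smap = train_shared_space(theta, hf, theta, lf, lf_model=pair.lf,
                                  lf_values_at_hf_inputs=lf, arch=FAST, seed=6)
        assert smap.rho_original < -0.8
        # positive and large (capped below 1 by the nonlinear relation
        # between the two QoI shapes, here ~0.94)
        assert smap.rho_ae > 0.8

    def test_monotone_single_coordinate_near_perfect(self, rng):
        # both fidelities monotone in the same coordinate with similar
        # shapes (so the post-resampling Pearson ceiling is ~1): rho_AE >= 0.99
        theta = np.random.default_rng(8).normal(size=(250, 3))
        hf = np.tanh(theta[:, 0]) + 0.3 * theta[:, 0]
        lf = 0.8 * np.tanh(theta[:, 0]) + 0.25 * theta[:, 0] + 0.5

        def lf_model(th):
            th = np.atleast_2d(th)
            return 0.8 * np.tanh(th[:, 0]) + 0.25 * th[:, 0] + 0.5

        smap = train_shared_space(theta, hf, theta, lf, lf_model=lf_model,
                                  lf_values_at_hf_inputs=lf, arch=FAST, seed=9)
        assert smap.rho_ae >= 0.99


class TestMfmcAeEstimate:
    def test_alpha_zero_reduces_to_mc(self, trained_low_rho_map):
        from corouq.estimators import SamplePairSet, mfmc_estimate
        pair, theta, hf, _, smap = trained_low_rho_map
        lf_re = smap.resample_lf(theta)
        pairs = SamplePairSet(hf_values=hf, lf_values_at_hf_inputs=lf_re)
        res = mfmc_estimate(pairs, alpha=0.0, label="MFMC-AE")
        assert res.mean == pytest.approx(hf.mean())

    def test_estimate_runs_and_labels(self, trained_low_rho_map):
        pair, theta, hf, _, smap = trained_low_rho_map
        rng = np.random.default_rng(4)
        extra = pair.draw_inputs(rng, 400)
        res = mfmc_ae_estimate(smap, theta, hf, extra)
        assert res.estimator == "MFMC-AE"
        assert res.n_hf == 200 and res.n_lf == 600
        assert abs(res.rho) > 0.5

    def test_unbiased_over_trials(self, trained_low_rho_map):
        pair, _, _, _, smap = trained_low_rho_map
        rng = np.random.default_rng(5)
        means = []
        for _ in range(200):
            theta = pair.draw_inputs(rng, 200)
            hf = pair.hf(theta[:40])
            res = mfmc_ae_estimate(smap, theta[:40], hf, theta[40:])
            means.append(res.mean)
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - pair.true_hf_mean) < 3 * se


def test_convergence_study_small(rng):
    from corouq.sharedspace import convergence_study
    pair = correlation_battery()[3]
    tiny = ArchConfig(hidden=(8, 8), surrogate_hidden=(8, 8),
                      max_epochs=150, stage2_max_epochs=60, lr=5e-3)
    df = convergence_study(pair.draw_inputs, pair.hf, pair.lf,
                           pilot_sizes=[25, 60], n_trials=2, seed=0, arch=tiny)
    assert len(df) == 4
    assert set(df.columns) >= {"n_pilot", "trial", "rho", "rho_ae", "mc_mean"}
    # reproducibility of the full report
    df2 = convergence_study(pair.draw_inputs, pair.hf, pair.lf,
                            pilot_sizes=[25, 60], n_trials=2, seed=0, arch=tiny)
    assert df.equals(df2)
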