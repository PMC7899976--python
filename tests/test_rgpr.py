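"""Recursive GP regression: kernel algebra, the recursion, and its exactness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from msisim.rgpr import (
    KernelHyperparams,
    OnlineMotionPredictor,
    RecursiveGPRegressor,
    gram,
    harvest_windows,
    kernel,
    select_location_vectors,
)

from oracles import batch_gp_posterior, scalar_rgpr

HYP = KernelHyperparams(sigma_f=1.5, lengthscale=2.0, noise_sd=0.3)

vec3 = arrays(np.float64, 3, elements=st.floats(-5, 5, allow_nan=False))


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        x = np.array([0.3, -1.2, 4.0])
        assert kernel(x, x, HYP) == pytest.approx(HYP.sigma_f**2)

    @given(x=vec3, y=vec3)
    def test_symmetry_and_bound(self, x, y):
        kxy = kernel(x, y, HYP)
        assert kxy == pytest.approx(kernel(y, x, HYP))
        assert 0.0 < kxy <= HYP.sigma_f**2 + 1e-12

    def test_hand_evaluated_value(self):
        # unit lengthscale, unit amplitude, squared distance 2 -> exp(-1)
        hyp = KernelHyperparams(sigma_f=1.0, lengthscale=1.0, noise_sd=0.1)
        val = kernel(np.array([0.0, 0.0]), np.array([1.0, 1.0]), hyp)
        assert val == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel(np.zeros(3), np.zeros(4), HYP)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            KernelHyperparams(sigma_f=-1.0)
        with pytest.raises(ValueError):
            KernelHyperparams(lengthscale=0.0)


class TestGram:
    def test_single_column(self):
        K = gram(np.array([[1.0], [2.0]]), HYP, jitter_rel=0.0)
        np.testing.assert_allclose(K, [[HYP.sigma_f**2]])

    def test_duplicated_columns_psd_after_jitter(self):
        X = np.array([[1.0, 1.0, 2.0], [0.0, 0.0, 1.0]])
        K0 = gram(X, HYP, jitter_rel=0.0)
        assert np.linalg.eigvalsh(K0).min() == pytest.approx(0.0, abs=1e-12)
        K = gram(X, HYP, jitter_rel=1e-8)
        assert np.linalg.eigvalsh(K).min() > 0

    def test_random_gram_nearly_psd_before_jitter(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 12))
        K = gram(X, HYP, jitter_rel=0.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
        assert np.allclose(np.diag(K), HYP.sigma_f**2)


class TestLocationSelection:
    def test_all_candidates_returned_when_m_equals_n(self):
        cand = np.arange(12.0).reshape(4, 3)
        X = select_location_vectors(cand, 4)
        assert np.array_equal(X, cand.T)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        cand = rng.normal(size=(50, 5))
        assert np.array_equal(
            select_location_vectors(cand, 10, seed=3),
            select_location_vectors(cand, 10, seed=3),
        )

    def test_greedy_maxmin_picks_extremes_on_toy_line(self):
        # exhaustive search over all pairs of {0,1,2,10} gives {0,10}
        cand = np.array([[0.0], [1.0], [2.0], [10.0]])
        X = select_location_vectors(cand, 2)
        assert sorted(X.ravel().tolist()) == [0.0, 10.0]

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidates"):
            select_location_vectors(np.zeros((3, 2)), 5)


class TestRecursion:
    def _regressor(self, d=3, m=6, seed=0, jitter=1e-12):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(d, m))
        return RecursiveGPRegressor(X, HYP, jitter_rel=jitter), rng

    def test_initial_state(self):
        reg, _ = self._regressor()
        assert np.all(reg.mean_f == 0.0)
        assert np.array_equal(reg.cov_f, reg.gram_)
        assert np.allclose(reg.cov_f, reg.cov_f.T)

    def test_initial_prediction_mean_zero_variance_prior(self):
        reg, rng = self._regressor()
        # with cov_f = K the predictive variance collapses to k(x,x) for any x
        for _ in range(5):
            _, pred = reg.infer(rng.normal(size=3))
            assert pred.mean == 0.0
            assert pred.variance == pytest.approx(HYP.sigma_f**2, rel=1e-6)

    def test_zero_innovation_leaves_mean_unchanged(self):
        reg, rng = self._regressor()
        x = rng.normal(size=3)
        J, pred = reg.infer(x)
        reg.update(J, pred, y_t=pred.mean)
        assert np.all(reg.mean_f == 0.0)

    def test_trace_contraction_and_psd_on_random_stream(self):
        reg, rng = self._regressor()
        prev = np.trace(reg.cov_f)
        for _ in range(40):
            J, pred = reg.infer(rng.normal(size=3))
            reg.update(J, pred, rng.normal())
            tr = np.trace(reg.cov_f)
            assert tr <= prev + 1e-10
            assert np.allclose(reg.cov_f, reg.cov_f.T, atol=1e-8)
            assert np.linalg.eigvalsh(reg.cov_f).min() >= -1e-8
            prev = tr

    def test_matches_batch_gp_at_location_vectors_and_queries(self):
        reg, rng = self._regressor()
        idx = rng.integers(0, reg.m, size=40)
        ys = rng.normal(size=40)
        for i, y in zip(idx, ys):
            J, pred = reg.infer(reg.X[:, i])
            reg.update(J, pred, y)
        mean_b, cov_b = batch_gp_posterior(
            reg.X[:, idx].T, ys, reg.X.T, HYP.sigma_f, 2.0, HYP.noise_sd
        )
        np.testing.assert_allclose(reg.mean_f, mean_b, atol=1e-6)
        np.testing.assert_allclose(reg.cov_f, cov_b, atol=1e-6)
        # arbitrary query point
        xq = rng.normal(size=3)
        _, pred = reg.infer(xq)
        mean_q, cov_q = batch_gp_posterior(
            reg.X[:, idx].T, ys, xq[None, :], HYP.sigma_f, 2.0, HYP.noise_sd
        )
        assert pred.mean == pytest.approx(mean_q[0], abs=1e-6)
        assert pred.variance == pytest.approx(cov_q[0, 0], abs=1e-6)

    def test_batch_oracle_agrees_with_sklearn(self):
        # certify the test oracle itself against an independent implementation
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(2)
        Xtr, ytr = rng.normal(size=(5, 2)), rng.normal(size=5)
        Xq = rng.normal(size=(3, 2))
        mean, cov = batch_gp_posterior(Xtr, ytr, Xq, 1.5, 2.0, 0.3)
        sk = GaussianProcessRegressor(
            kernel=ConstantKernel(1.5**2, "fixed") * RBF(np.sqrt(2.0), "fixed"),
            alpha=0.3**2,
            optimizer=None,
        ).fit(Xtr, ytr)
        mean_sk, cov_sk = sk.predict(Xq, return_cov=True)
        np.testing.assert_allclose(mean, mean_sk, atol=1e-8)
        np.testing.assert_allclose(cov, cov_sk, atol=1e-8)

    def test_scalar_case_matches_hand_recursion(self):
        hyp = KernelHyperparams(sigma_f=1.2, lengthscale=0.8, noise_sd=0.2)
        reg = RecursiveGPRegressor(np.array([[0.5]]), hyp, jitter_rel=0.0)
        stream = [(0.5, 1.0), (0.2, 0.7), (0.9, -0.3)]
        preds_ref, (mu_ref, c_ref) = scalar_rgpr(0.5, stream, 1.2, 0.8, 0.2)
        for (x_t, y_t), (mu_p_ref, c_p_ref) in zip(stream, preds_ref):
            J, pred = reg.infer(np.array([x_t]))
            assert pred.mean == pytest.approx(mu_p_ref, abs=1e-12)
            assert pred.variance == pytest.approx(c_p_ref, abs=1e-12)
            reg.update(J, pred, y_t)
        assert reg.mean_f[0] == pytest.approx(mu_ref, abs=1e-12)
        assert reg.cov_f[0, 0] == pytest.approx(c_ref, abs=1e-12)

    def test_prediction_invariant_to_location_ordering(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(3, 6))
        perm = rng.permutation(6)
        reg_a = RecursiveGPRegressor(X, HYP, jitter_rel=1e-12)
        reg_b = RecursiveGPRegressor(X[:, perm], HYP, jitter_rel=1e-12)
        for _ in range(10):
            x, y = rng.normal(size=3), rng.normal()
            Ja, pa = reg_a.infer(x)
            Jb, pb = reg_b.infer(x)
            assert pa.mean == pytest.approx(pb.mean, abs=1e-9)
            assert pa.variance == pytest.approx(pb.variance, abs=1e-9)
            reg_a.update(Ja, pa, y)
            reg_b.update(Jb, pb, y)

    def test_infinite_noise_freezes_the_posterior(self):
        hyp = KernelHyperparams(sigma_f=1.5, lengthscale=2.0, noise_sd=1e6)
        rng = np.random.default_rng(4)
        reg = RecursiveGPRegressor(rng.normal(size=(3, 5)), hyp)
        for _ in range(20):
            J, pred = reg.infer(rng.normal(size=3))
            reg.update(J, pred, rng.normal())
        assert np.max(np.abs(reg.mean_f)) < 1e-9

    def test_state_snapshot_round_trip(self, tmp_path):
        reg, rng = self._regressor()
        for _ in range(10):
            J, pred = reg.infer(rng.normal(size=3))
            reg.update(J, pred, rng.normal())
        path = tmp_path / "state.npz"
        reg.save_state(path)
        back = RecursiveGPRegressor.load_state(path)
        np.testing.assert_array_equal(back.mean_f, reg.mean_f)
        np.testing.assert_array_equal(back.cov_f, reg.cov_f)
        x = rng.normal(size=3)
        _, pa = reg.infer(x)
        _, pb = back.infer(x)
        assert pa.mean == pytest.approx(pb.mean, abs=1e-6)  # default jitter on reload

    def test_window_shape_checked(self):
        reg, _ = self._regressor()
        with pytest.raises(ValueError, match="window"):
            reg.infer(np.zeros(5))
        with pytest.raises(ValueError, match="non-finite"):
            J, pred = reg.infer(np.zeros(3))
            reg.update(J, pred, np.nan)


class TestOnlinePredictor:
    def _predictor(self, d=4, m=5, stride=1):
        rng = np.random.default_rng(0)
        reg = RecursiveGPRegressor(rng.normal(size=(d, m)), HYP)
        return OnlineMotionPredictor(reg, learn_stride=stride)

    def test_warmup_emits_prior_and_does_not_update(self):
        pred_obj = self._predictor(d=4)
        for i in range(4):
            p = pred_obj.step(float(i))
            assert p.mean == 0.0 and p.variance == HYP.sigma_f**2
        assert np.all(pred_obj.regressor.mean_f == 0.0)
        assert pred_obj.regressor.n_infer == 0

    def test_window_is_newest_first(self):
        pred_obj = self._predictor(d=4)
        for i in range(6):
            pred_obj.step(float(i))
        np.testing.assert_array_equal(pred_obj.current_window(), [5.0, 4.0, 3.0, 2.0])

    def test_constant_zero_stream_converges_to_zero_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(scale=0.5, size=(4, 5))
        reg = RecursiveGPRegressor(X, HYP)
        pred_obj = OnlineMotionPredictor(reg)
        variances = []
        for _ in range(60):
            p = pred_obj.step(0.0)
            variances.append(p.variance)
        assert abs(p.mean) < 1e-3
        assert variances[-1] < variances[4]

    def test_learn_stride_decimates_updates(self):
        a = self._predictor(d=2, stride=3)
        b = self._predictor(d=2, stride=1)
        for i in range(20):
            a.step(np.sin(i))
            b.step(np.sin(i))
        # strided learner retains more prior uncertainty
        assert np.trace(a.regressor.cov_f) > np.trace(b.regressor.cov_f)

    def test_prediction_error_decays_on_periodic_motion(self, mp_session_60s):
        # learner should predict the periodic profile better in later cycles
        from msisim.rgpr import RGPRConfig
        from msisim.motion import MovementSpec, add_sensor_noise
        from msisim.svc import build_location_vectors

        cfg = RGPRConfig(m=50, learn_stride=2)
        X = build_location_vectors(cfg, MovementSpec(), mp_session_60s.dt)
        reg = RecursiveGPRegressor(X, cfg.hyper, cfg.jitter_rel)
        pred_obj = OnlineMotionPredictor(reg, learn_stride=cfg.learn_stride)
        noisy = add_sensor_noise(mp_session_60s, 1e-4, seed=1)
        errors = np.empty(len(noisy))
        for t, y in enumerate(noisy):
            p = pred_obj.step(y)
            errors[t] = p.mean - mp_session_60s.accel[t]
        n_cycle = round(16.0 / mp_session_60s.dt)
        # first cycle: prior predictions (mean 0), so the error is the motion itself
        first_cycle = np.sqrt(np.mean(errors[:n_cycle] ** 2))
        late_cycle = np.sqrt(np.mean(errors[-n_cycle:] ** 2))
        assert late_cycle < 0.5 * first_cycle


def test_harvest_windows_shape_and_ordering():
    accel = np.arange(10.0)
    W = harvest_windows(accel, d=3, stride=2)
    np.testing.assert_array_equal(W[0], [2.0, 1.0, 0.0])  # newest first
    np.testing.assert_array_equal(W[1], [4.0, 3.0, 2.0])
    assert W.shape == (4, 3)
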