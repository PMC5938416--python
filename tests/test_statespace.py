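"""Tests for the Log-Normal observation model and the fixed-lag smoother."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from aadkit.markers import MarkerSeries
from aadkit.statespace import (AttentionTrajectory, FixedLagConfig,
                               GammaNormalPrior, LogNormalParams,
                               StateSpaceParams, batch_estimate,
                               built_in_delay_s, classify_instances,
                               compute_mse, estimate_window,
                               fit_lognormal_supervised, inverse_gamma_mean,
                               inverse_gamma_var, lognormal_logpdf,
                               realtime_estimate, responsibilities)
from aadkit.statespace import _eta_mstep, _laplace_z
from _oracles import grid_map_z


def _params(rho_a=4.0, mu_a=0.0, rho_u=4.0, mu_u=-1.0, **kw):
    return StateSpaceParams(attended=LogNormalParams(rho_a, mu_a),
                            unattended=LogNormalParams(rho_u, mu_u), **kw)


class TestLogNormalLogpdf:
    def test_zero_quadratic_term(self):
        rho, mu = 3.0, 0.7
        expected = -mu + 0.5 * math.log(rho) - 0.5 * math.log(2 * math.pi)
        assert lognormal_logpdf(math.exp(mu), rho, mu) == pytest.approx(expected)

    def test_standard_closed_form(self):
        assert lognormal_logpdf(1.0, 1.0, 0.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_density_integrates_to_one(self):
        for rho, mu in ((2.0, 0.3), (0.5, -1.0)):
            total, _ = quad(lambda m: math.exp(lognormal_logpdf(m, rho, mu)),
                            1e-12, np.inf, limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_marker_rejected(self):
        with pytest.raises(ValueError):
            lognormal_logpdf(0.0, 1.0, 0.0)


class TestSupervisedFit:
    def test_two_point_ml(self):
        mk = MarkerSeries(np.array([1.0, np.e ** 2]), np.array([1.0, 1.0]), "l1")
        params = fit_lognormal_supervised(mk, [1, 1])
        assert params.attended.mu == pytest.approx(1.0)
        assert params.attended.rho == pytest.approx(1.0)

    def test_degenerate_pool_caps_precision(self):
        mk = MarkerSeries(np.full(4, 2.0), np.full(4, 0.5), "l1")
        params = fit_lognormal_supervised(mk, [1, 1, 1, 1])
        assert params.attended.rho == params.rho_max

    def test_parameter_recovery_at_n2000(self):
        rng = np.random.default_rng(42)
        rho, mu = 4.0, -1.0
        n = 2000
        att = np.exp(rng.normal(mu, 1 / math.sqrt(rho), n))
        unatt = np.exp(rng.normal(-2.0, 0.5, n))
        mk = MarkerSeries(att, unatt, "l1")
        params = fit_lognormal_supervised(mk, np.ones(n, dtype=int))
        assert abs(params.attended.rho - rho) / rho < 0.10
        assert abs(params.attended.mu - mu) < 0.05

    def test_insufficient_data_rejected(self):
        mk = MarkerSeries(np.array([1.0]), np.array([1.0]), "l1")
        with pytest.raises(ValueError):
            fit_lognormal_supervised(mk, [1])


class TestResponsibilities:
    def test_full_symmetry_is_half(self):
        p = _params()
        assert responsibilities(2.0, 2.0, 0.0, p) == pytest.approx(0.5)

    def test_uninformative_observations_reduce_to_logistic(self):
        p = _params(rho_a=3.0, mu_a=0.5, rho_u=3.0, mu_u=0.5)
        for z in (-2.0, 0.0, 1.5):
            expected = 1 / (1 + math.exp(-z))
            assert responsibilities(0.7, 4.0, z, p) == pytest.approx(expected)

    def test_matches_density_ratio_oracle(self):
        p = _params(rho_a=2.0, mu_a=0.2, rho_u=5.0, mu_u=-1.3)
        m1, m2, z = 0.8, 0.3, 0.4
        pz = 1 / (1 + math.exp(-z))
        fa = lambda m: math.exp(lognormal_logpdf(m, 2.0, 0.2))
        fu = lambda m: math.exp(lognormal_logpdf(m, 5.0, -1.3))
        expected = pz * fa(m1) * fu(m2) / (pz * fa(m1) * fu(m2)
                                           + (1 - pz) * fu(m1) * fa(m2))
        assert responsibilities(m1, m2, z, p) == pytest.approx(expected, rel=1e-10)


class TestPriorHelpers:
    def test_inverse_gamma_moments_of_configured_prior(self):
        assert inverse_gamma_mean(2.008, 0.2016) == pytest.approx(0.2)
        assert inverse_gamma_var(2.008, 0.2016) == pytest.approx(5.0, rel=1e-3)

    def test_eta_posterior_mode_at_zero_innovation(self):
        z = np.array([0.0])
        cov = np.zeros((1, 1))
        eta = _eta_mstep(z, cov, z0=0.0, c0=1.0, a0=2.008, b0=0.2016)
        assert eta[0] == pytest.approx(0.2016 / 3.508, abs=1e-5)  # 0.05747


class TestEstimateWindow:
    def test_uninformative_observations_give_flat_half(self):
        p = _params(rho_a=3.0, mu_a=0.0, rho_u=3.0, mu_u=0.0)
        m = np.full(8, 0.7)
        z, z_var, eta, r, _ = estimate_window(m, m, p, outer_iters=5,
                                              inner_iters=2)
        assert np.allclose(z, 0.0, atol=1e-9)
        assert np.allclose(r, 0.5)

    def test_strong_separation_gives_confident_growing_posterior(self):
        """With constant, unambiguous evidence for speaker 1 the posterior
        rises monotonically from the z0 = 0 anchor toward a confident
        plateau; the ramp rate is capped by the Inverse-Gamma state-variance
        prior, which deliberately suppresses per-instance jumps. The mode is
        cross-checked against the independent grid search."""
        p = _params(rho_a=25.0, mu_a=0.0, rho_u=25.0, mu_u=-2.0)
        m1 = np.full(5, 1.0)      # clearly attended law
        m2 = np.full(5, math.exp(-2.0))
        z, z_var, eta, r, _ = estimate_window(m1, m2, p, outer_iters=10,
                                              inner_iters=5,
                                              update_obs_params=False)
        traj = AttentionTrajectory(z, z_var, eta, r, "batch")
        assert np.all(np.diff(traj.p) > 0)
        assert traj.p[-1] > 0.6
        assert np.allclose(r, 1.0, atol=1e-6)
        z_grid = grid_map_z(r, eta, z0=0.0, c0=1.0)
        assert np.max(np.abs(z - z_grid)) <= 0.02

    def test_map_trajectory_matches_grid_search(self):
        """The Laplace E-step's Newton mode agrees with an independent
        grid-restricted coordinate-ascent search of the same posterior."""
        rng = np.random.default_rng(10)
        for trial in range(3):
            K = int(rng.integers(2, 6))
            r = rng.uniform(0.05, 0.95, K)
            eta = rng.uniform(0.05, 0.5, K)
            z0 = float(rng.uniform(-1, 1))
            z, _ = _laplace_z(r, eta, z0=z0, c0=1.0, z_init=np.zeros(K))
            z_grid = grid_map_z(r, eta, z0=z0, c0=1.0)
            assert np.max(np.abs(z - z_grid)) <= 0.02


class TestRealtimeEstimate:
    def _markers(self, K=30, seed=0, sep=1.0):
        rng = np.random.default_rng(seed)
        half = K // 2
        mu1 = np.r_[np.zeros(half), -sep * np.ones(K - half)]
        m1 = np.exp(rng.normal(mu1, 0.4))
        m2 = np.exp(rng.normal(-sep - mu1 - sep * 0, 0.4))[::-1]
        return MarkerSeries(m1, m2, "l1")

    def test_zero_forward_lag_is_fully_realtime(self):
        mk = self._markers()
        p = _params()
        cfg = FixedLagConfig(K_B=5, K_F=0, outer_iters=3, inner_iters=1)
        traj = realtime_estimate(mk, p, cfg)
        assert traj.K == mk.K
        assert cfg.K_A == 6

    def test_builtin_delay_formulas(self):
        assert built_in_delay_s("decoding", 50, 200, 6, L_d=80) == pytest.approx(1.9)
        assert built_in_delay_s("decoding", 16, 64, 6, L_d=16) == pytest.approx(1.75)
        assert built_in_delay_s("encoding", 50, 200, 6) == pytest.approx(1.5)

    def test_marker_swap_mirrors_probabilities(self):
        """Swapping the two marker streams maps p -> 1-p and swaps the CI
        bounds (the model is exactly symmetric in the two speakers)."""
        mk = self._markers(seed=3)
        p = _params(rho_a=6.0, mu_a=0.0, rho_u=6.0, mu_u=-1.0)
        cfg = FixedLagConfig(K_B=7, K_F=2, outer_iters=5, inner_iters=1)
        t1 = realtime_estimate(mk, p, cfg)
        t2 = realtime_estimate(mk.swapped(), p, cfg)
        assert np.allclose(t2.p, 1.0 - t1.p, atol=1e-9)
        assert np.allclose(t2.ci_lo, 1.0 - t1.ci_hi, atol=1e-9)
        assert np.allclose(t2.ci_hi, 1.0 - t1.ci_lo, atol=1e-9)

    def test_probabilities_and_cis_are_proper(self):
        mk = self._markers(seed=4)
        traj = realtime_estimate(mk, _params(),
                                 FixedLagConfig(K_B=5, K_F=2, outer_iters=3))
        assert np.all((traj.p > 0) & (traj.p < 1))
        assert np.all(traj.ci_lo <= traj.p) and np.all(traj.p <= traj.ci_hi)
        assert np.all((traj.ci_lo > 0) & (traj.ci_hi < 1))
        assert np.all((traj.responsibilities > 0) & (traj.responsibilities < 1))

    def test_smoothing_suppresses_marker_fluctuations(self):
        """The p-trajectory is less variable than the raw normalized
        marker-difference trajectory."""
        mk = self._markers(K=40, seed=5)
        traj = realtime_estimate(mk, _params(),
                                 FixedLagConfig(K_B=9, K_F=2, outer_iters=5))
        raw = mk.m1 / (mk.m1 + mk.m2)
        half = slice(0, 20)
        assert np.var(traj.p[half]) <= np.var(raw[half])


class TestBatchEstimate:
    def test_symmetric_markers_stay_at_half(self):
        m = np.full(12, 0.5)
        p = _params(rho_a=3.0, mu_a=0.0, rho_u=3.0, mu_u=0.0)
        traj = batch_estimate(MarkerSeries(m, m, "l1"), p, outer_iters=5,
                              inner_iters=5)
        assert np.allclose(traj.p, 0.5, atol=1e-9)

    def test_stronger_evidence_gives_larger_probabilities(self):
        rng = np.random.default_rng(11)
        K = 24
        base = rng.normal(0.0, 0.3, K)
        p = _params(rho_a=8.0, mu_a=0.0, rho_u=8.0, mu_u=-1.0)
        trajs = []
        for sep in (0.4, 1.0):
            m1 = np.exp(base)
            m2 = np.exp(base - sep)
            trajs.append(batch_estimate(MarkerSeries(m1, m2, "l1"), p,
                                        outer_iters=5, inner_iters=5,))
        assert np.all(trajs[1].p >= trajs[0].p - 1e-9)

    def test_batch_equals_full_window_realtime_at_final_instance(self):
        mk = MarkerSeries(np.exp(np.random.default_rng(12).normal(0, 0.3, 10)),
                          np.exp(np.random.default_rng(13).normal(-1, 0.3, 10)),
                          "l1")
        p = _params()
        K = mk.K
        batch = batch_estimate(mk, p, outer_iters=4, inner_iters=1)
        cfg = FixedLagConfig(K_B=0, K_F=K - 1, outer_iters=4, inner_iters=1)
        rt = realtime_estimate(mk, p, cfg)
        # the whole realtime trajectory comes from the final (full) window;
        # it matches batch up to the EM initialization path
        assert np.allclose(rt.p, batch.p, atol=0.01)


class TestMseAndClassification:
    def _traj(self, z, var=None):
        z = np.asarray(z, float)
        v = np.zeros_like(z) if var is None else np.asarray(var, float)
        return AttentionTrajectory(z, v, np.zeros_like(z),
                                   np.full(z.size, 0.5), "realtime")

    def test_identical_trajectories_have_zero_mse(self):
        t = self._traj([0.3, -0.2, 1.0])
        assert compute_mse(t, t) == 0.0

    def test_hand_mse_value(self):
        tb = self._traj([0.0])
        tr = self._traj([math.log(3.0)])
        assert compute_mse(tr, tb) == pytest.approx(0.0625)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(14)
        zb, zr = rng.standard_normal(9), rng.standard_normal(9)
        expected = np.mean([(1 / (1 + math.exp(-a)) - 1 / (1 + math.exp(-b))) ** 2
                            for a, b in zip(zb, zr)])
        assert compute_mse(self._traj(zr), self._traj(zb)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_mse(self._traj([0.0]), self._traj([0.0, 1.0]))

    def test_ci_classification_convention(self):
        # p=0.9 CI [0.8, 0.95] truth 1 -> correct; p=0.55 CI [0.45,0.65] -> unclassified;
        # p=0.2 CI [0.1,0.3] truth 1 -> incorrect
        def traj_from_ci(lo, hi):
            # invert the logistic-CI mapping: choose z and var reproducing lo/hi
            zl, zh = math.log(lo / (1 - lo)), math.log(hi / (1 - hi))
            z = (zl + zh) / 2
            sd = (zh - zl) / (2 * 1.645)
            return AttentionTrajectory(np.array([z]), np.array([sd ** 2]),
                                       np.zeros(1), np.array([0.5]), "realtime")

        res = classify_instances(traj_from_ci(0.8, 0.95), [1])
        assert res.labels[0] == 1
        res = classify_instances(traj_from_ci(0.45, 0.65), [1])
        assert res.labels[0] == 0
        res = classify_instances(traj_from_ci(0.1, 0.3), [1])
        assert res.labels[0] == -1
        # orientation flip for truth = 2
        res = classify_instances(traj_from_ci(0.1, 0.3), [2])
        assert res.labels[0] == 1

    def test_excluded_instances_are_skipped(self):
        traj = AttentionTrajectory(np.array([3.0, 3.0]), np.array([0.01, 0.01]),
                                   np.zeros(2), np.full(2, 0.5), "realtime")
        res = classify_instances(traj, [1, 2], excluded=[False, True])
        assert res.hit_rate == 1.0 and res.false_alarm_rate == 0.0
        assert res.labels[1] == 0
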