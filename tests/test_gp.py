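"""GP regression: kernel algebra, dense-oracle equivalence, derived stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from axontune import gp
from axontune.gp import KernelHyperparams, StimulusPoint


H = KernelHyperparams(sigma_k2=2.0, sigma_eps2=0.5, l_sf=1.0, l_tf=1.0,
                      l_theta=40.0, l_s=1.0, l_L=1.0)


def dense_gp_posterior(F_train, y, F_test, h, include_noise=True):
    """Textbook GP posterior via full dense linear algebra (test oracle).

    Uses the same covariance model as the implementation, including the
    stabilizing diagonal jitter, but none of its collapsed/Cholesky code.
    """
    K = gp.signal_kernel(F_train, F_train, h) \
        + (h.sigma_eps2 + gp.JITTER * h.sigma_k2) * np.eye(len(y))
    Ks = gp.signal_kernel(F_test, F_train, h)
    Kinv_y = np.linalg.solve(K, y)
    mean = Ks @ Kinv_y
    var = h.sigma_k2 - np.einsum("ij,ji->i", Ks, np.linalg.solve(K, Ks.T))
    if include_noise:
        var = var + h.sigma_eps2
    return mean, var


def random_features(rng, n):
    return gp.transform_features(
        rng.uniform(0.02, 0.32, n), rng.uniform(0.5, 8.0, n),
        rng.uniform(0, 360, n), rng.uniform(0, 20, n),
        rng.integers(0, 2, n))


class TestKernel:
    def test_same_point_same_index_gives_full_variance(self):
        x = StimulusPoint(sf=0.08, tf=2.0, direction=45.0, run_speed=5.0)
        assert gp.kernel_eval(x, x, H, same_index=True) == pytest.approx(2.5)
        assert gp.kernel_eval(x, x, H, same_index=False) == pytest.approx(2.0)

    def test_direction_wraps_at_360(self):
        a = StimulusPoint(sf=0.08, tf=2.0, direction=10.0)
        b = StimulusPoint(sf=0.08, tf=2.0, direction=370.0)
        assert gp.kernel_eval(a, b, H) == pytest.approx(H.sigma_k2)

    def test_distant_points_decay_to_zero(self):
        a = StimulusPoint(sf=0.02, tf=0.5, direction=0.0, run_speed=0.0)
        b = StimulusPoint(sf=0.32, tf=8.0, direction=180.0, run_speed=400.0)
        assert gp.kernel_eval(a, b, H) < 1e-6

    def test_non_finite_inputs_raise(self):
        a = StimulusPoint(sf=0.08, tf=np.nan, direction=0.0)
        b = StimulusPoint(sf=0.08, tf=2.0, direction=0.0)
        with pytest.raises(ValueError):
            gp.kernel_eval(a, b, H)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_kernel_matrices_are_symmetric_psd(self, seed):
        rng = np.random.default_rng(seed)
        F = random_features(rng, 25)
        K = gp.signal_kernel(F, F, H) + H.sigma_eps2 * np.eye(25)
        assert np.allclose(K, K.T)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() >= -1e-8

    def test_invalid_hyperparams_raise(self):
        with pytest.raises(ValueError):
            KernelHyperparams(sigma_k2=1.0, sigma_eps2=1.0, l_sf=0.0,
                              l_tf=1.0, l_theta=1.0, l_s=1.0, l_L=1.0)


class TestPosteriorOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_collapsed_posterior_matches_dense_oracle(self, seed):
        """Posterior from the collapsed fit equals textbook dense GP."""
        rng = np.random.default_rng(seed)
        # duplicated rows exercise the collapse; 3 repeats x 12 conditions
        base = random_features(rng, 12)
        F = np.repeat(base, 3, axis=0)
        y = rng.normal(0.0, 1.0, len(F))
        U, m, ybar, rss, _ = gp._collapse(F, y)
        fit = gp.TuningFit(
            hyperparams=H, features=U, group_counts=m, group_means=ybar,
            trial_features=F, trial_responses=y, s_ref=0.0, objective=0.0,
            converged=True)
        F_test = random_features(rng, 7)
        mean, var = fit.predict_features(F_test)
        mean_o, var_o = dense_gp_posterior(F, y, F_test, H)
        assert mean == pytest.approx(mean_o, abs=1e-7)
        assert var == pytest.approx(var_o, abs=1e-7)

    def test_posterior_variance_bounded_by_prior(self):
        rng = np.random.default_rng(3)
        F = random_features(rng, 20)
        y = rng.normal(0.0, 1.0, 20)
        U, m, ybar, rss, _ = gp._collapse(F, y)
        fit = gp.TuningFit(hyperparams=H, features=U, group_counts=m,
                           group_means=ybar, trial_features=F,
                           trial_responses=y, s_ref=0.0, objective=0.0,
                           converged=True)
        _, var = fit.predict_features(random_features(rng, 50))
        assert np.all(var <= H.sigma_k2 + H.sigma_eps2 + 1e-8)

    def test_interpolation_limit_at_vanishing_noise(self):
        h = KernelHyperparams(sigma_k2=2.0, sigma_eps2=1e-10, l_sf=1.0,
                              l_tf=1.0, l_theta=40.0, l_s=1.0, l_L=1.0)
        rng = np.random.default_rng(4)
        F = random_features(rng, 10)
        y = rng.normal(0.0, 1.0, 10)
        U, m, ybar, rss, _ = gp._collapse(F, y)
        fit = gp.TuningFit(hyperparams=h, features=U, group_counts=m,
                           group_means=ybar, trial_features=F,
                           trial_responses=y, s_ref=0.0, objective=0.0,
                           converged=True)
        mean, _ = fit.predict_features(F)
        assert mean == pytest.approx(y, abs=1e-3)

    def test_collapsed_likelihood_matches_dense(self):
        """Exact grouped marginal likelihood equals the dense evaluation."""
        rng = np.random.default_rng(5)
        base = random_features(rng, 9)
        F = np.repeat(base, 4, axis=0)
        y = rng.normal(0.0, 1.0, len(F))
        U, m, ybar, rss, _ = gp._collapse(F, y)
        Q = gp._sq_dist_components(U, U)
        z = gp._pack(H)
        nll, _ = gp._neg_log_posterior(z, Q, m, ybar, rss, len(y))
        # add back the length-scale priors to isolate the likelihood
        ls = H.lengthscales()
        nll_lik = nll + np.sum(np.log(ls) - ls)
        K = gp.signal_kernel(F, F, H) + H.sigma_eps2 * np.eye(len(y)) \
            + gp.JITTER * H.sigma_k2 * np.eye(len(y))
        sign, logdet = np.linalg.slogdet(K)
        dense = 0.5 * (logdet + y @ np.linalg.solve(K, y)
                       + len(y) * np.log(2 * np.pi))
        assert nll_lik == pytest.approx(dense, rel=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        F = random_features(rng, 15)
        y = rng.normal(0.0, 1.0, 15)
        U, m, ybar, rss, _ = gp._collapse(F, y)
        Q = gp._sq_dist_components(U, U)
        z0 = gp._pack(H)
        _, grad = gp._neg_log_posterior(z0, Q, m, ybar, rss, len(y))
        eps = 1e-6
        for i in range(len(z0)):
            zp, zm = z0.copy(), z0.copy()
            zp[i] += eps
            zm[i] -= eps
            fp, _ = gp._neg_log_posterior(zp, Q, m, ybar, rss, len(y))
            fm, _ = gp._neg_log_posterior(zm, Q, m, ybar, rss, len(y))
            assert grad[i] == pytest.approx((fp - fm) / (2 * eps), abs=1e-4)


class TestFit:
    def test_constant_responses_give_subthreshold_snr(self):
        rows = []
        for sf in (0.02, 0.08, 0.32):
            for tf in (0.5, 2.0, 8.0):
                for rep in range(3):
                    rows.append((sf, tf, 0.0, 0, 5.0, 1.0))
        table = pd.DataFrame(rows, columns=["sf", "tf", "direction", "laser",
                                            "run_speed", "response"])
        fit = gp.fit_gp(table, seed=0)
        assert not fit.responsive

    def test_objective_beats_random_hyperparameters(self, tuned_roi):
        _, _, table, fit = tuned_roi
        F = gp.transform_features(table["sf"], table["tf"],
                                  table["direction"], table["run_speed"],
                                  table["laser"])
        r = np.asarray(table["response"])
        U, m, ybar, rss, _ = gp._collapse(F, r)
        Q = gp._sq_dist_components(U, U)
        rng = np.random.default_rng(0)
        for _ in range(10):
            ls = np.maximum(rng.gamma(2.0, 1.0, 5), 0.25)
            h = KernelHyperparams(float(rng.uniform(0.01, 2.0)),
                                  float(rng.uniform(0.01, 2.0)), *ls)
            nll, _ = gp._neg_log_posterior(gp._pack(h), Q, m, ybar, rss,
                                           len(r))
            assert fit.objective >= -nll - 1e-6

    def test_fit_constraints_honored(self, tuned_roi):
        _, _, _, fit = tuned_roi
        h = fit.hyperparams
        assert h.l_sf >= 0.25 and h.l_tf >= 0.25 and h.l_s >= 0.25

    def test_fit_reproducible_given_seed(self, small_protocol):
        from axontune import synthetic as syn
        tuning = syn.GroundTruthTuning(sf_pref=-3.0, tf_pref=1.0,
                                       noise_sd=0.15)
        _, table = syn.simulate_tuned_responses(small_protocol, [tuning],
                                                seed=31)
        f1 = gp.fit_gp(table, seed=5)
        f2 = gp.fit_gp(table, seed=5)
        assert f1.hyperparams == f2.hyperparams

    def test_too_few_trials_raise(self):
        table = pd.DataFrame([(0.02, 1.0, 0.0, 0, 5.0, 1.0)],
                             columns=["sf", "tf", "direction", "laser",
                                      "run_speed", "response"])
        with pytest.raises(ValueError):
            gp.fit_gp(table, seed=0)


class TestDerivedQuantities:
    @pytest.mark.parametrize("r_best,var_best,expected",
                             [(4.0, 4.0, 2.0), (0.0, 1.0, 0.0), (3.0, 1.0, 3.0)])
    def test_snr_arithmetic(self, r_best, var_best, expected, tuned_roi):
        _, _, _, fit = tuned_roi
        probe = gp.TuningFit(
            hyperparams=fit.hyperparams, features=fit.features,
            group_counts=fit.group_counts, group_means=fit.group_means,
            trial_features=fit.trial_features,
            trial_responses=fit.trial_responses, s_ref=fit.s_ref,
            objective=0.0, converged=True, r_best=r_best, var_best=var_best)
        assert gp.compute_snr(probe) == pytest.approx(expected)

    def test_r2_hand_example(self):
        # r = (1,2,3), p = (1,2,4): 1 - 1/2 = 0.5
        r = np.array([1.0, 2.0, 3.0])
        p = np.array([1.0, 2.0, 4.0])
        r2 = 1.0 - np.sum((r - p) ** 2) / np.sum((r - r.mean()) ** 2)
        assert r2 == pytest.approx(0.5)

    def test_r2_of_good_fit_is_high(self, tuned_roi):
        _, _, _, fit = tuned_roi
        assert fit.r2 > 0.5
        # predicting the mean everywhere gives r2 = 0 by definition
        r = fit.trial_responses
        assert 1.0 - np.sum((r - r.mean()) ** 2) / np.sum(
            (r - r.mean()) ** 2) == pytest.approx(0.0)

    @pytest.mark.parametrize("snr,r2,expected", [
        (2.5, 0.3, True), (1.9, 0.5, False), (3.0, 0.05, False)])
    def test_responsiveness_gate(self, snr, r2, expected, tuned_roi):
        _, _, _, fit = tuned_roi
        probe = gp.TuningFit(
            hyperparams=fit.hyperparams, features=fit.features,
            group_counts=fit.group_counts, group_means=fit.group_means,
            trial_features=fit.trial_features,
            trial_responses=fit.trial_responses, s_ref=fit.s_ref,
            objective=0.0, converged=True, snr=snr, r2=r2)
        assert gp.is_responsive(probe) is expected

    def test_preferred_stimulus_matches_fine_grid_argmax(self, tuned_roi):
        _, _, _, fit = tuned_roi
        best = fit.best_stimulus
        g_sf = np.linspace(np.log2(0.02), np.log2(0.32), 101)
        g_tf = np.linspace(np.log2(0.5), np.log2(8.0), 101)
        SF, TF = np.meshgrid(g_sf, g_tf, indexing="ij")
        F = np.column_stack([
            SF.ravel(), TF.ravel(),
            np.full(SF.size, best.direction),
            np.full(SF.size, fit.s_ref), np.zeros(SF.size)])
        mean, _ = fit.predict_features(F)
        i = np.argmax(mean)
        assert abs(np.log2(best.sf) - SF.ravel()[i]) < 0.25
        assert abs(np.log2(best.tf) - TF.ravel()[i]) < 0.25

    def test_out_of_range_peak_clips_to_boundary(self, small_protocol):
        from axontune import synthetic as syn
        tuning = syn.GroundTruthTuning(sf_pref=np.log2(0.01),
                                       tf_pref=np.log2(2.0), dir_pref=0.0,
                                       noise_sd=0.05)
        _, table = syn.simulate_tuned_responses(small_protocol, [tuning],
                                                seed=41)
        fit = gp.fit_gp(table, seed=0)
        assert fit.best_stimulus.sf == pytest.approx(0.02)

    @pytest.mark.parametrize("tf,sf,expected", [
        (8.0, 0.02, 400.0), (0.5, 0.32, 1.5625), (2.0, 0.08, 25.0)])
    def test_preferred_speed_ratio(self, tf, sf, expected, tuned_roi):
        _, _, _, fit = tuned_roi
        probe = gp.TuningFit(
            hyperparams=fit.hyperparams, features=fit.features,
            group_counts=fit.group_counts, group_means=fit.group_means,
            trial_features=fit.trial_features,
            trial_responses=fit.trial_responses, s_ref=fit.s_ref,
            objective=0.0, converged=True,
            best_stimulus=StimulusPoint(sf=sf, tf=tf, direction=0.0))
        assert gp.preferred_speed(probe) == pytest.approx(expected)

    def test_modulation_criterion_arithmetic(self):
        # the gate is r_best - 0.66*sd_best > r_worst + 0.66*sd_worst
        def gate(rb, vb, rw, vw):
            return rb - 0.66 * np.sqrt(vb) > rw + 0.66 * np.sqrt(vw)

        assert gate(1.0, 0.01, 0.8, 0.01)          # 0.934 > 0.866
        assert not gate(1.0, 0.09, 1.0, 0.09)      # equal responses
        assert not gate(1.0, 0.09, 0.9, 0.09)      # 0.802 < 1.098

    def test_tuned_roi_is_modulated_along_each_dimension(self, tuned_roi):
        _, _, _, fit = tuned_roi
        for dim in ("sf", "tf", "direction", "speed"):
            assert gp.is_modulated(fit, dim)


class TestTuningWidth:
    def test_fwhm_close_to_analytic_gaussian_width(self, tuned_roi):
        # generative sigma = 1 octave -> FWHM = 2 sqrt(2 ln 2) = 2.355
        _, _, _, fit = tuned_roi
        width = gp.tuning_width(fit, "sf")
        assert not width.censored
        assert width.fwhm_octaves == pytest.approx(2.355, rel=0.15)

    def test_fwhm_monotone_in_generative_sigma(self, small_protocol):
        from axontune import synthetic as syn
        widths = []
        for sigma in (0.5, 1.0, 2.0):
            tuning = syn.GroundTruthTuning(
                sf_pref=np.log2(0.08), tf_pref=np.log2(2.0),
                sf_sigma=sigma, noise_sd=0.05)
            _, table = syn.simulate_tuned_responses(small_protocol, [tuning],
                                                    seed=51)
            fit = gp.fit_gp(table, seed=0)
            widths.append(gp.tuning_width(fit, "sf").fwhm_octaves)
        assert widths[0] < widths[1] < widths[2]

    def test_monotonic_curve_is_censored(self, small_protocol):
        from axontune import synthetic as syn
        tuning = syn.GroundTruthTuning(sf_pref=np.log2(0.005),
                                       tf_pref=np.log2(2.0), sf_sigma=3.0,
                                       noise_sd=0.05)
        _, table = syn.simulate_tuned_responses(small_protocol, [tuning],
                                                seed=61)
        fit = gp.fit_gp(table, seed=0)
        assert gp.tuning_width(fit, "sf").censored


class TestExtraction:
    def _recording(self, rate, fr=10.0):
        from axontune.synthetic import RoiRecording
        return RoiRecording(dff=rate, rate=rate, frame_rate=fr)

    def _protocol_one(self):
        from axontune.synthetic import StimulusTrial
        return [StimulusTrial(sf=0.08, tf=2.0, direction=0.0, laser=0,
                              static_onset=0.0, drift_onset=1.0,
                              drift_offset=3.0)]

    def test_constant_rate_returns_constant(self):
        rec = self._recording(np.full(50, 2.0))
        out = gp.extract_trial_responses(rec, self._protocol_one())
        assert out["response"].iloc[0] == pytest.approx(2.0)

    def test_zero_rate_returns_zero(self):
        rec = self._recording(np.zeros(50))
        out = gp.extract_trial_responses(rec, self._protocol_one())
        assert out["response"].iloc[0] == pytest.approx(0.0)

    def test_linear_ramp_returns_midpoint(self):
        # rate ramps 0 -> 1 across the window; symmetric sampling -> 0.5
        fr = 10.0
        times = np.arange(50) / fr
        a, b = 1.25, 3.0
        rate = np.clip((times - a) / (b - a), 0.0, 1.0)
        rate[times >= b] = 1.0
        rec = self._recording(rate, fr)
        out = gp.extract_trial_responses(rec, self._protocol_one())
        assert out["response"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_invalid_frames_drop_trial(self):
        rec = self._recording(np.full(50, 2.0))
        rec.valid[:] = False
        out = gp.extract_trial_responses(rec, self._protocol_one())
        assert len(out) == 0
        assert out.attrs["dropped"] == [0]

    def test_window_outside_trace_raises(self):
        rec = self._recording(np.full(5, 2.0))
        with pytest.raises(ValueError):
            gp.extract_trial_responses(rec, self._protocol_one())

    def test_opto_mode_extends_window_to_laser_offset(self):
        from axontune.synthetic import StimulusTrial
        fr = 10.0
        rate = np.zeros(60)
        # drift 1.0-3.0 s carries 1.0; laser tail 3.0-3.5 s carries 3.0
        rate[int(1.0 * fr):int(3.0 * fr)] = 1.0
        rate[int(3.0 * fr):int(3.5 * fr)] = 3.0
        rec = self._recording(rate, fr)
        trial = StimulusTrial(sf=0.08, tf=2.0, direction=0.0, laser=1,
                              static_onset=0.0, drift_onset=1.0,
                              drift_offset=3.0, laser_onset=1.5,
                              laser_offset=3.5)
        std = gp.extract_trial_responses(rec, [trial], mode="standard")
        opto = gp.extract_trial_responses(rec, [trial], mode="opto")
        assert std["response"].iloc[0] == pytest.approx(1.0)
        assert opto["response"].iloc[0] > std["response"].iloc[0]
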