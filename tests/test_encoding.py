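"""Nested encoding GLM: design construction, ridge machinery, coefficient
uncertainty and ramping-interval PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

import ramptime as rt
from ramptime import encoding as enc
from ramptime import preprocess as pp
from ramptime.config import ParameterError

from conftest import FS, fast_task


class TestNuisanceDiscretization:
    def test_silent_channel(self):
        assert len(enc.discretize_nuisance_events(np.zeros(1000), FS)) == 0

    def test_three_planted_bursts(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.05, 6000)
        onsets = [1000, 3000, 5000]
        for i in onsets:
            x[i : i + 20] += 5.0
        ev = enc.discretize_nuisance_events(x, FS)
        assert len(ev) == 3
        for t, i in zip(ev, onsets):
            assert abs(t * FS - i) <= 1

    def test_unreachable_threshold(self):
        x = np.random.default_rng(1).normal(0, 0.05, 2000)
        assert len(enc.discretize_nuisance_events(x, FS, k=1000)) == 0


def _two_trial_session(T1=2.0, T2=4.0, fs=FS):
    """Minimal session with two licked trials of movement times T1, T2."""
    cfg = fast_task(sampling_rate=fs)
    trials = rt.build_trial_timeline(np.array([T1, T2]), cfg, seed=0)
    gp = rt.GenerativeParams(n_trials=2, noise_sd=0.01, artifact_rate=0.0,
                             spontaneous_lick_rate=0.0)
    return rt.synthesize_session(trials, gp, cfg, seed=0)


class TestDesignMatrix:
    def test_stretch_rows_tile_the_interval(self):
        s = _two_trial_session()
        dff = pp.compute_dff(s.channels["gcamp"], FS, "moving_average", s.trials)
        ctrl = pp.compute_dff(s.channels["control"], FS, "moving_average", s.trials)
        spec = enc.EncodingSpec()
        g = spec.group_slices()
        blocks = list(enc.iter_trial_blocks(s, dff, ctrl, spec))
        assert len(blocks) == 2
        for (i, X, y), T in zip(blocks, (2.0, 4.0)):
            stretch = X[g["stretch"]]
            n_cue_to_lick = int(stretch.sum())
            expected = int(round(T * FS))
            assert abs(n_cue_to_lick - expected) <= 1
            row_sums = stretch.sum(axis=1)
            assert np.all(np.abs(row_sums - n_cue_to_lick / spec.n_stretch) <= 1)

    def test_stretch_windows_scale_with_interval(self):
        s = _two_trial_session(T1=2.0, T2=4.0)
        dff = pp.compute_dff(s.channels["gcamp"], FS, "moving_average", s.trials)
        ctrl = pp.compute_dff(s.channels["control"], FS, "moving_average", s.trials)
        g = enc.EncodingSpec().group_slices()
        blocks = list(enc.iter_trial_blocks(s, dff, ctrl))
        w1 = blocks[0][1][g["stretch"]][250].sum()
        w2 = blocks[1][1][g["stretch"]][250].sum()
        assert w2 == pytest.approx(2 * w1, abs=1.0)

    def test_baseline_offset_proportional_to_interval(self):
        s = _two_trial_session(T1=2.0, T2=4.0)
        dff = pp.compute_dff(s.channels["gcamp"], FS, "moving_average", s.trials)
        ctrl = pp.compute_dff(s.channels["control"], FS, "moving_average", s.trials)
        g = enc.EncodingSpec().group_slices()
        blocks = list(enc.iter_trial_blocks(s, dff, ctrl))
        a1 = blocks[0][1][g["baseline_offset"]].max()
        a2 = blocks[1][1][g["baseline_offset"]].max()
        assert a2 / a1 == pytest.approx(2.0, rel=1e-9)


class TestRidge:
    def test_matches_closed_form_and_sklearn(self):
        """The Gram-based solver agrees with the explicit normal-equations
        formula and with sklearn Ridge on a random 5 x 50 system."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 50))
        y = rng.normal(size=50)
        lam = 0.37
        ours = enc._solve_ridge(X @ X.T, X @ y, lam, 50)
        explicit = np.linalg.inv(X @ X.T + 50 * lam * np.eye(5)) @ (X @ y)
        skl = Ridge(alpha=50 * lam, fit_intercept=False).fit(X.T, y).coef_
        assert np.allclose(ours, explicit, atol=1e-8)
        assert np.allclose(ours, skl, atol=1e-8)

    def test_noiseless_identifiability(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 400))
        theta = rng.normal(size=8)
        y = theta @ X
        rec = enc._solve_ridge(X @ X.T, X @ y, 1e-12, 400)
        assert np.allclose(rec, theta, atol=1e-6)

    def test_timing_nests_improve_gcamp_not_control(self, ramp_session, ramp_dff,
                                                    ramp_control_dff):
        fit_g = enc.fit_nested_ridge(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        fit_c = enc.fit_nested_ridge(ramp_session, ramp_control_dff, ramp_dff, seed=0)
        imp_g = fit_g.improvements.set_index("input")["rel_improvement"]
        imp_c = fit_c.improvements.set_index("input")["rel_improvement"]
        assert imp_g["stretch"] > 0.05
        assert imp_g["baseline_offset"] + imp_g["stretch"] > 0.05
        assert imp_c["stretch"] < 0.01
        assert imp_c["baseline_offset"] < 0.01

    def test_cv_mse_non_increasing_on_full_generator(self, ramp_session, ramp_dff,
                                                     ramp_control_dff):
        fit = enc.fit_nested_ridge(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        mse = np.array(fit.cv_mse)
        assert np.all(mse[2:] <= mse[1:-1] * 1.02)  # small CV noise tolerated

    def test_predictor_rescaling_is_absorbed(self, ramp_session, ramp_dff,
                                             ramp_control_dff):
        scaled = pp.DffTrace(10.0 * ramp_control_dff.values, "moving_average", FS)
        a = enc.fit_nested_ridge(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        b = enc.fit_nested_ridge(ramp_session, ramp_dff, scaled, seed=0)
        assert np.allclose(a.cv_mse, b.cv_mse, rtol=1e-9)

    def test_stretch_coefficients_ramp_monotonically(self, ramp_session, ramp_dff,
                                                     ramp_control_dff):
        """On ramp-mode data the fitted stretch profile rises across the
        interval (Spearman rho > 0.9)."""
        from scipy import stats

        fit = enc.fit_nested_ridge(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        sl = fit.spec.group_slices()["stretch"]
        coefs = fit.coefficients[5][sl]
        # the first/last ~15% of the interval share support with the cue and
        # lick kernels, which absorb part of the ramp there; the monotone
        # rise is the stretch group's own signature in between
        core = coefs[75:425]
        rho = stats.spearmanr(np.arange(len(core)), core).statistic
        assert rho > 0.9


class TestUncertainty:
    def test_toy_covariance_matches_analytic(self):
        rng = np.random.default_rng(4)
        d, n = 4, 5000
        X = rng.normal(size=(d, n))
        theta_true = np.array([1.0, -0.5, 0.25, 2.0])
        sigma = 0.5
        y = theta_true @ X + rng.normal(0, sigma, n)
        lam = 1e-3
        spec = enc.EncodingSpec(n_cue=1, n_lick=1, n_nuisance=0, n_stretch=0)
        XX, XY = X @ X.T, X @ y
        theta = enc._solve_ridge(XX, XY, lam, n)
        fit = enc.NestedFit(
            spec=spec, lambdas=[lam] * 5, coefficients=[theta] * 5,
            scale=np.ones(d), cv_objective=[0] * 5, cv_mse=[0] * 5,
            train_loss=[0] * 5, r2=[0] * 5, aic=[0] * 5, bic=[0] * 5,
            n_timepoints=n, trial_folds={}, gram=(XX, XY, y @ y),
        )
        draws = enc.simulate_fit_uncertainty(fit, level=3, n_draws=2000, seed=0)
        A = XX + n * lam * np.eye(d)
        Ainv = np.linalg.inv(A)
        cov_analytic = sigma**2 * Ainv @ XX @ Ainv
        cov_emp = np.cov(draws.T)
        assert np.allclose(cov_emp, cov_analytic, rtol=0.25, atol=0.1 * cov_analytic.max())

    def test_bands_contain_point_prediction(self, ramp_session, ramp_dff,
                                            ramp_control_dff):
        fit = enc.fit_nested_ridge(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        blocks = enc.iter_trial_blocks(ramp_session, ramp_dff, ramp_control_dff, fit.spec)
        _, X, _ = next(iter(blocks))
        bands = enc.prediction_bands(fit, X, n_sim=200, seed=1)
        assert np.all(bands["lo"] <= bands["point"] + 1e-12)
        assert np.all(bands["hi"] >= bands["point"] - 1e-12)

    def test_noise_free_draw_spread_vanishes(self):
        rng = np.random.default_rng(5)
        d, n = 3, 1000
        X = rng.normal(size=(d, n))
        theta_true = np.ones(d)
        y = theta_true @ X  # exact, no noise
        lam = 1e-10
        spec = enc.EncodingSpec(n_cue=1, n_lick=0, n_nuisance=0, n_stretch=0)
        XX, XY = X @ X.T, X @ y
        theta = enc._solve_ridge(XX, XY, lam, n)
        fit = enc.NestedFit(
            spec=spec, lambdas=[lam] * 4, coefficients=[theta] * 4,
            scale=np.ones(d), cv_objective=[0] * 4, cv_mse=[0] * 4,
            train_loss=[0] * 4, r2=[0] * 4, aic=[0] * 4, bic=[0] * 4,
            n_timepoints=n, trial_folds={}, gram=(XX, XY, y @ y),
        )
        draws = enc.simulate_fit_uncertainty(fit, level=2, n_draws=500, seed=0)
        assert draws.std(axis=0).max() < 1e-3


class TestPCA:
    def test_max_interpolation_length_from_task_structure(self):
        assert enc.max_interpolation_length(rt.TaskConfig()) == 5700

    def test_rank_one_input(self):
        base = np.linspace(0, 1, 300)
        segs = [a * base[: 200 + 20 * k] for k, a in enumerate((1.0, 2.0, 0.5, 3.0))]
        out = enc.pca_ramping_intervals(segs, target_length=300)
        assert out["variance_explained"][0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_matches_svd_oracle(self):
        rng = np.random.default_rng(6)
        segs = [rng.normal(size=120) for _ in range(15)]
        out = enc.pca_ramping_intervals(segs, target_length=120)
        M = np.vstack(segs)
        sv = np.linalg.svd(M - M.mean(axis=0), compute_uv=False)
        oracle = sv**2 / (sv**2).sum()
        assert np.allclose(out["variance_explained"], oracle, atol=1e-8)

    def test_ramp_plus_offset_two_components(self):
        """Low-noise ramps with baseline offsets concentrate in two
        components (ramp-like and offset-like)."""
        s = rt.make_session(
            rt.GenerativeParams(n_trials=100, noise_sd=0.03, artifact_rate=0.0),
            fast_task(), seed=22,
        )
        dff = pp.compute_dff(s.channels["gcamp"], FS, "moving_average", s.trials)
        segs, _ = enc.extract_ramping_intervals(s, dff)
        L = enc.max_interpolation_length(s.meta["task"])
        out = enc.pca_ramping_intervals(segs, target_length=L)
        assert out["variance_explained"][:2].sum() >= 0.90

    def test_reconstruction_lengths_match_input(self, ramp_session, ramp_dff):
        segs, _ = enc.extract_ramping_intervals(ramp_session, ramp_dff)
        out = enc.pca_ramping_intervals(segs, target_length=500)
        assert [len(r) for r in out["reconstructions"]] == [len(s) for s in segs]

    def test_too_few_trials_refused(self):
        with pytest.raises(ParameterError):
            enc.pca_ramping_intervals([np.ones(50)], target_length=100)
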