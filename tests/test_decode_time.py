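"""Debounced threshold crossings, threshold selection, slope analysis and
the nested first-lick-time decoder."""

import numpy as np
import pytest
from scipy import stats

import ramptime as rt
from ramptime import decode_time as dt
from ramptime import encoding as enc
from ramptime.config import ParameterError

from conftest import FS, fast_task


def oracle_crossing(seg, level):
    """Exhaustive suffix scan: first i > 0 with seg[i-1] < level and
    min(seg[i:]) >= level."""
    n = len(seg)
    for i in range(1, n):
        if seg[i - 1] < level and seg[i:].min() >= level:
            return i / n
    if seg.min() >= level:
        return 0.0  # started (and stayed) above: no low-to-high crossing
    return 0.0


class TestDebouncedCrossing:
    def test_linear_ramp_crosses_at_level(self):
        seg = np.linspace(0, 1, 1000)
        out = dt.debounced_crossing_times([seg], 0.5)
        assert out[0] == pytest.approx(0.5, abs=2 / 1000)

    def test_start_and_end_above_is_no_crossing(self):
        seg = np.full(100, 0.8)
        assert dt.debounced_crossing_times([seg], 0.5)[0] == 0.0

    def test_dip_then_final_crossing(self):
        seg = np.concatenate([np.full(50, 0.9), np.full(50, 0.1), np.full(100, 0.9)])
        out = dt.debounced_crossing_times([seg], 0.5)
        assert out[0] == pytest.approx(100 / 200)

    def test_matches_brute_force_oracle_on_noisy_ramps(self):
        rng = np.random.default_rng(0)
        segs = [
            np.cumsum(rng.normal(0.005, 0.02, rng.integers(50, 400))) for _ in range(100)
        ]
        for level in (-0.1, 0.05, 0.3, 0.8):
            ours = dt.debounced_crossing_times(segs, level)
            oracle = np.array([oracle_crossing(s, level) for s in segs])
            assert np.array_equal(ours, oracle)

    def test_invariant_under_joint_monotone_rescale(self):
        rng = np.random.default_rng(1)
        segs = [np.cumsum(rng.normal(0.01, 0.05, 200)) for _ in range(20)]
        a = dt.debounced_crossing_times(segs, 0.4)
        b = dt.debounced_crossing_times([3 * s + 2 for s in segs], 3 * 0.4 + 2)
        assert np.allclose(a, b)


class TestThresholdSelection:
    def test_identical_ramps_mid_is_lowest_level(self):
        segs = [np.linspace(0, 1, 200) for _ in range(30)]
        ts = dt.select_thresholds(segs, mode="single")
        assert ts.selected["mid"][1] == 30
        assert ts.selected["mid"][0] == ts.levels[np.argmax(ts.counts == ts.counts.max())]

    def test_mixed_ramps_and_flat_trials(self):
        """60 ramps + 40 flat-low trials: every eligible level is crossed by
        the same 60 trials, so min is the lowest candidate with >= 50."""
        segs = [np.linspace(0.0, 1.0, 200) for _ in range(60)]
        segs += [np.full(200, 0.0) for _ in range(40)]
        ts = dt.select_thresholds(segs, mode="multi")
        assert ts.selected["min"][1] == 60
        assert ts.selected["mid"][1] == 60
        assert ts.selected["max"][1] >= 50
        eligible = np.flatnonzero(ts.counts >= 50)
        assert ts.selected["min"][0] == ts.levels[eligible[0]]

    def test_relaxed_selection_on_noise(self):
        rng = np.random.default_rng(2)
        segs = [rng.normal(0, 1, 150) for _ in range(40)]
        ts = dt.select_thresholds(segs, relaxed=True)
        assert ts.relaxed
        assert "relaxed" in ts.selected
        assert ts.selected["relaxed"][1] < 50

    def test_no_crossing_flag(self):
        segs = [np.linspace(1, 0, 100) for _ in range(10)]  # falling only
        ts = dt.select_thresholds(segs)
        assert ts.no_crossings


class TestSlopeAnalysis:
    def _ideal_ramp_segments(self, n=120, seed=3):
        """Common-endpoint ramps: segment value at fraction f of interval is
        A * (0.7 + f*(T-1.3)) / T, evaluated on the cue+0.7 -> lick-0.6 span."""
        rng = np.random.default_rng(seed)
        T = rng.uniform(2.0, 6.0, n)
        segs = []
        for t in T:
            dur = t - 1.3
            tt = 0.7 + np.linspace(0, dur, max(20, int(dur * FS)))
            segs.append(5.0 * tt / t)  # slope A/T, endpoint A at lick
        return segs, T

    def test_ideal_steps_have_equal_slopes(self):
        rng = np.random.default_rng(4)
        T = rng.uniform(2.0, 6.0, 150)
        segs = []
        for t in T:
            dur = t - 1.3
            n = max(20, int(dur * FS))
            step_at = int(0.5 * n)  # step at a fixed fraction of the interval
            seg = np.zeros(n)
            seg[step_at:] = 1.0
            segs.append(seg)
        ts = dt.ThresholdSet(
            levels=np.linspace(0, 1, 100), counts=np.zeros(100),
            selected={"min": (0.2, 150), "mid": (0.5, 150), "max": (0.8, 150)},
        )
        res = dt.threshold_slope_analysis(segs, T, ts)
        slopes = res.set_index("level_name")["slope"]
        assert abs(slopes["min"] - slopes["mid"]) < 0.02
        assert abs(slopes["mid"] - slopes["max"]) < 0.02

    def test_ideal_ramps_slopes_increase_toward_one(self):
        segs, T = self._ideal_ramp_segments()
        ts = dt.select_thresholds(segs, mode="multi")
        res = dt.threshold_slope_analysis(segs, T, ts).set_index("level_name")
        assert res.loc["min", "slope"] < res.loc["mid", "slope"] < res.loc["max", "slope"]
        # closed form: crossing time at level theta is theta*T/A, so the
        # regression slope equals theta/A and reaches 1 at the endpoint level
        for name in ("min", "mid", "max"):
            assert res.loc[name, "slope"] == pytest.approx(res.loc[name, "level"] / 5.0,
                                                           abs=0.05)

    def test_ramp_vs_step_session_contrast(self, ramp_session, ramp_dff, step_session,
                                           step_dff):
        """Generator round trip: the slope profile rises with threshold level
        on ramp-mode sessions, CI-separated; not on step-mode sessions."""
        fl_r = ramp_session.trials["first_lick_time"].to_numpy()
        segs_r, ids_r = dt.ramping_intervals(ramp_session, ramp_dff)
        res_r = dt.threshold_slope_analysis(segs_r, fl_r[ids_r]).set_index("level_name")
        assert (
            res_r.loc["min", "slope"]
            < res_r.loc["mid", "slope"]
            < res_r.loc["max", "slope"]
        )
        assert res_r.loc["min", "slope_ci_high"] < res_r.loc["max", "slope_ci_low"]

        fl_s = step_session.trials["first_lick_time"].to_numpy()
        segs_s, ids_s = dt.ramping_intervals(step_session, step_dff)
        res_s = dt.threshold_slope_analysis(segs_s, fl_s[ids_s]).set_index("level_name")
        spread_s = res_s["slope"].max() - res_s["slope"].min()
        spread_r = res_r["slope"].max() - res_r["slope"].min()
        assert spread_s < 0.5 * spread_r


class TestTimelickDecoder:
    def test_constructed_identity_reaches_unit_r2(self, ramp_session, ramp_dff,
                                                  ramp_control_dff):
        """If log(T) is an exact affine function of crossing time, the final
        nest fits perfectly and earlier nests do not."""
        res = dt.fit_timelick_decoder(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        X, keep = res["design"], res["trials"]
        cross = X[:, 9]
        y = 0.3 + 1.7 * cross  # exact construction on the real crossing predictor
        out = dt.nested_ridge_cv(X, y, list(range(1, 11)), seed=0,
                                 lambda_grid=np.array([1e-8]))
        assert out["r2_cv"][-1] > 0.999
        assert out["r2_cv"][0] < 0.5

    def test_decoder_explains_variance_on_ramp_session(self, ramp_session, ramp_dff,
                                                       ramp_control_dff):
        res = dt.fit_timelick_decoder(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        assert res["r2_cv"][-1] > 0.3

    def test_crossing_absorbs_baseline_variance(self, ramp_session, ramp_dff,
                                                ramp_control_dff):
        """Marginal gain of the baseline nests shrinks once the crossing-time
        nest is available (fit order swapped)."""
        res = dt.fit_timelick_decoder(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        X, y = res["design"], res["log_first_lick"]
        # baseline (ITI+LOI) marginal gain without the crossing predictor
        base_first = dt.nested_ridge_cv(X[:, :8], y, [6, 8], seed=0)
        gain_without = base_first["r2_cv"][1] - base_first["r2_cv"][0]
        # same marginal gain when crossing time is already in the model
        Xsw = X[:, [0, 1, 2, 3, 4, 5, 9, 6, 7]]
        cross_first = dt.nested_ridge_cv(Xsw, y, [7, 9], seed=0)
        gain_with = cross_first["r2_cv"][1] - cross_first["r2_cv"][0]
        assert gain_with < gain_without

    def test_shuffled_targets_have_no_explained_variance(self, ramp_session, ramp_dff,
                                                         ramp_control_dff):
        res = dt.fit_timelick_decoder(ramp_session, ramp_dff, ramp_control_dff, seed=0)
        X, y = res["design"], res["log_first_lick"]
        rng = np.random.default_rng(0)
        null_r2 = []
        for _ in range(100):
            ys = rng.permutation(y)
            out = dt.nested_ridge_cv(X, ys, [10], seed=1)
            null_r2.append(out["r2_cv"][0])
        assert np.quantile(null_r2, 0.975) < 0.1
        assert res["r2_cv"][-1] > np.quantile(null_r2, 0.975)

    def test_pca_smoothed_variant_changes_little(self, ramp_session, ramp_dff):
        """Feeding 3-PC reconstructions into the crossing analysis moves the
        crossing-time R^2 by < 0.1 on clean synthetic data."""
        fl = ramp_session.trials["first_lick_time"].to_numpy()
        segs, ids = dt.ramping_intervals(ramp_session, ramp_dff)
        L = enc.max_interpolation_length(ramp_session.meta["task"])
        pca = enc.pca_ramping_intervals(segs, target_length=L)
        segs_pca = pca["reconstructions"]

        def crossing_r2(sgs):
            ts = dt.select_thresholds(sgs, mode="single")
            c = dt.debounced_crossing_times(sgs, ts.selected["mid"][0])
            ok = c > 0
            return stats.linregress(c[ok], np.log(fl[ids][ok])).rvalue ** 2

        assert abs(crossing_r2(segs) - crossing_r2(segs_pca)) < 0.1

    def test_too_few_trials_rejected(self):
        s = rt.make_session(rt.GenerativeParams(n_trials=8), fast_task(), seed=30)
        from ramptime import preprocess as pp

        dff = pp.compute_dff(s.channels["gcamp"], FS, "moving_average", s.trials)
        ctrl = pp.compute_dff(s.channels["control"], FS, "moving_average", s.trials)
        with pytest.raises(ParameterError):
            dt.fit_timelick_decoder(s, dff, ctrl)
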