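"""dF/F conditioning: singularity removal, the four F0 methods, the
Distortion Index, transient kinetics and normalized dF/F."""

import numpy as np
import pytest
from scipy import signal as sps

import ramptime as rt
from ramptime import preprocess as pp
from ramptime.config import ParameterError

from conftest import FS, fast_task


def oracle_remove_singularities(x, k=15.0, max_run=3):
    """Independent scan-and-interpolate reference implementation."""
    x = np.asarray(x, dtype=float)
    mean, sd = x.mean(), x.std()
    out = x.copy()
    if sd == 0:
        return out
    bad = np.abs(x - mean) > k * sd
    i = 0
    while i < len(x):
        if bad[i]:
            j = i
            while j < len(x) and bad[j]:
                j += 1
            if j - i <= max_run:
                for m in range(i, j):
                    lo = i - 1
                    hi = j
                    if lo < 0:
                        out[m] = x[hi]
                    elif hi >= len(x):
                        out[m] = x[lo]
                    else:
                        w = (m - lo) / (hi - lo)
                        out[m] = (1 - w) * x[lo] + w * x[hi]
            i = j
        else:
            i += 1
    return out


class TestRemoveSingularities:
    def test_single_spike_interpolated(self):
        # a lone spike among n points tops out at ~sqrt(n) SDs, so the trace
        # must be long enough for the 15 SD rule to catch it
        x = np.sin(np.arange(1000) * 0.01) * 0.001
        x[500] = 1e6
        y = pp.remove_singularities(x)
        assert y[500] == pytest.approx((x[499] + x[501]) / 2)

    def test_clean_trace_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        assert np.array_equal(pp.remove_singularities(x), x)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.01, 2000)
        spikes = rng.choice(2000, 12, replace=False)
        x[spikes] += rng.choice([-5, 5], 12)
        assert np.allclose(pp.remove_singularities(x), oracle_remove_singularities(x))

    def test_long_runs_left_untouched(self):
        x = np.random.default_rng(2).normal(0, 0.01, 500)
        x[100:110] = 50.0  # 10-sample excursion: signal, not a glitch
        y = pp.remove_singularities(x)
        assert np.array_equal(y[100:110], x[100:110])

    def test_all_flagged_refused(self):
        # two-level trace where every point sits far from the mean in SD units
        with pytest.raises(pp.DegenerateTraceError):
            pp.remove_singularities(np.array([0.0, 1e9, 0.0, 1e9] * 10), k=0.5)


def _toy_trials(n=6, start=30.0, spacing=12.0):
    import pandas as pd

    lamp = start + spacing * np.arange(n)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "lampoff_time": lamp,
            "cue_time": lamp + 1.0,
            "first_lick_time": np.full(n, 3.0),
            "outcome": ["early"] * n,
            "opto_on": [False] * n,
        }
    )


class TestComputeDff:
    @pytest.mark.parametrize("method", pp.DFF_METHODS)
    def test_constant_input_gives_zero(self, method):
        x = np.full(20_000, 7.5)
        d = pp.compute_dff(x, FS, method, _toy_trials())
        assert np.nanmax(np.abs(d.values)) < 1e-12

    def test_moving_average_matches_sliding_mean_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(100, 5, 4000)
        f0 = pp.moving_average_f0(x, fs=10.0, window=20.0)
        half = int(20.0 * 10.0 / 2)
        oracle = np.empty_like(x)
        for i in range(len(x)):
            h = min(half, i, len(x) - 1 - i)
            oracle[i] = x[i - h : i + h + 1].mean()
        assert np.allclose(f0, oracle, atol=1e-10)

    def test_slow_exponential_bound(self):
        """For F = c*exp(-t/tau) with tau >> window, the moving-average dF/F
        is bounded by the second-order window-mean error h^2/(4 tau^2)."""
        fs, window, tau = 10.0, 100.0, 5000.0
        t = np.arange(40_000) / fs
        x = 100.0 * np.exp(-t / tau)
        d = pp.compute_dff(x, fs, "moving_average", window=window, clean=False)
        h = window / 2.0
        interior = slice(int(window * fs), -int(window * fs))
        assert np.nanmax(np.abs(d.values[interior])) < h**2 / (4 * tau**2)

    def test_pretrial_methods_flag_trials_without_baseline(self):
        tr = _toy_trials()
        tr.loc[0, "lampoff_time"] = 2.0  # only 2 s of pre-trial data
        tr.loc[0, "cue_time"] = 3.0
        x = np.random.default_rng(4).normal(100, 1, int(110 * FS))
        d = pp.compute_dff(x, FS, "normalized_baseline", tr)
        assert d.excluded_trials == [0]

    def test_lowpass_attenuates_above_corner(self):
        """A sinusoid at 10x the corner frequency is strongly attenuated in
        F0 (the zero-phase low-pass keeps only bleaching-scale trends)."""
        fs, fc = 100.0, 5e-4  # scaled corner so the session stays small
        t = np.arange(int(4000 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * fc * t)
        f0 = pp.lowpass_f0(x, fs, fc=fc)
        assert f0.std() < 0.1 * x.std()

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            pp.compute_dff(np.ones(100), FS, "bandstop")


class TestDistortionIndex:
    def test_pure_rescale_gives_zero(self, ramp_session):
        raw = ramp_session.channels["gcamp"]
        dff = pp.DffTrace((raw - raw.mean()) / raw.mean(), "moving_average", FS)
        pairs = pp.find_trial_pairs(ramp_session.trials, FS, len(raw))
        assert len(pairs) > 0
        di = pp.distortion_index(raw, dff, pairs, smooth=0)
        assert np.nanmax(di) < 1e-10

    def test_hand_computed_window(self):
        raw = np.arange(100, dtype=float)
        vals = raw.copy()
        vals[:50] *= 2.0  # distorted first half
        dff = pp.DffTrace(vals, "normalized_baseline", 1.0)
        pair = pp.TrialPair("ER", 0, 1, (0, 100))
        di = pp.distortion_index(raw, dff, [pair], smooth=0)
        f_hat = (raw - raw.min()) / (raw.max() - raw.min())
        d_hat = (vals - vals.min()) / (vals.max() - vals.min())
        assert np.allclose(di, np.abs(f_hat - d_hat))

    def test_normalized_baseline_distorts_more_than_moving_average(self, ramp_session):
        """Baseline normalization erases the movement-time-coupled baseline
        and so distorts the timing-interval signal more than the 200 s
        moving average does."""
        raw = ramp_session.channels["gcamp"]
        tr = ramp_session.trials
        d_nb = pp.compute_dff(raw, FS, "normalized_baseline", tr)
        d_ma = pp.compute_dff(raw, FS, "moving_average", tr)
        pairs = pp.find_trial_pairs(tr, FS, len(raw))
        assert len(pairs) >= 3
        mid = len(raw) and int(20.0 * FS)  # cue of trial n sits 20 s into the window
        timing = slice(mid, mid + int(3.3 * FS))
        di_nb = pp.distortion_index(raw, d_nb, pairs, smooth=0)[timing]
        di_ma = pp.distortion_index(raw, d_ma, pairs, smooth=0)[timing]
        assert np.nanmean(di_nb) > np.nanmean(di_ma)

    def test_flat_window_skipped_with_warning(self):
        raw = np.ones(100)
        dff = pp.DffTrace(np.zeros(100), "moving_average", 1.0)
        with pytest.warns(UserWarning):
            with pytest.raises(pp.DegenerateTraceError):
                pp.distortion_index(raw, dff, [pp.TrialPair("ER", 0, 1, (0, 100))])


class TestTransientKinetics:
    def test_exponential_decay_closed_form(self):
        fs, tau = 1000.0, 0.1
        x = np.zeros(int(fs * 200))
        events = 5.0 + 10.0 * np.arange(15)
        t = np.arange(int(fs)) / fs
        kern = np.exp(-t / tau)
        for e in events:
            i = int(e * fs)
            x[i : i + len(kern)] += kern
        t_half = pp.transient_half_decay(x, fs, events)
        assert t_half == pytest.approx(tau * np.log(2), abs=2 / fs)

    def test_monotone_rise_returns_absent(self):
        fs = 100.0
        x = np.tile(np.linspace(0, 1, int(10 * fs)), 30)
        events = 10.0 * np.arange(1, 25) + 5.0
        assert pp.transient_half_decay(x, fs, events, window=(-0.5, 1.0)) is None

    def test_generator_round_trip_75ms(self):
        """A lick kernel built to decay with t1/2 = 75 ms is recovered from
        the lick-aligned average within 5 ms."""
        cfg = fast_task(sampling_rate=1000.0)
        gp = rt.GenerativeParams(
            n_trials=40,
            noise_sd=0.02,
            artifact_rate=0.0,
            spontaneous_lick_rate=0.0,
            ramp_peak_amplitude=0.0,
            baseline_gain=0.0,
            lick_kernel=rt.KernelParams(6.0, 0.002, 0.075 / np.log(2)),
            reward_kernel=rt.KernelParams(0.0, 0.03, 0.25),
        )
        s = rt.make_session(gp, cfg, seed=12)
        early = s.trials[(s.trials["outcome"] == "early")]
        licks = (early["cue_time"] + early["first_lick_time"]).to_numpy()
        t_half = pp.transient_half_decay(s.channels["gcamp"], 1000.0, licks)
        assert t_half == pytest.approx(0.075, abs=0.005)

    def test_too_few_events_rejected(self):
        with pytest.raises(ParameterError):
            pp.transient_half_decay(np.zeros(1000), 100.0, np.array([1.0, 2.0]))


class TestNormalizedDff:
    def test_scale_invariance(self, ramp_session, ramp_dff):
        doubled = pp.DffTrace(2 * ramp_dff.values, ramp_dff.method, FS)
        a = pp.normalized_dff(ramp_dff, ramp_session.trials)
        b = pp.normalized_dff(doubled, ramp_session.trials)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_lick_transient_near_100_percent(self, ramp_session, ramp_dff):
        nd = pp.normalized_dff(ramp_dff, ramp_session.trials)
        tr = ramp_session.trials
        ok = tr["first_lick_time"].between(2.0, 3.0)
        licks = (tr["cue_time"] + tr["first_lick_time"])[ok].to_numpy()
        base = pp.event_triggered_matrix(nd.values, FS, licks, (-0.5, -0.2)).mean(axis=1)
        peak = pp.event_triggered_matrix(nd.values, FS, licks, (-0.05, 0.3)).max(axis=1)
        assert np.mean(peak - base) == pytest.approx(100.0, rel=1e-6)

    def test_sensor_gains_overlay(self):
        """Two sensors with different gains but the same latent produce
        overlapping normalized ramps."""
        cfg = fast_task()
        outputs = []
        for gain in (1.0, 2.5):
            gp = rt.GenerativeParams(
                n_trials=80,
                noise_sd=0.02,
                artifact_rate=0.0,
                ramp_peak_amplitude=5.0 * gain,
                baseline_gain=3.0 * gain,
                cue_kernel=rt.KernelParams(3.0 * gain, 0.02, 0.10),
                lick_kernel=rt.KernelParams(6.0 * gain, 0.02, 0.15),
                reward_kernel=rt.KernelParams(8.0 * gain, 0.03, 0.25),
            )
            s = rt.make_session(gp, cfg, seed=13)
            dff = pp.compute_dff(s.channels["gcamp"], FS, "moving_average", s.trials)
            nd = pp.normalized_dff(dff, s.trials)
            tr = s.trials
            ok = tr["first_lick_time"].between(2.5, 3.5)
            cues = tr["cue_time"][ok].to_numpy()
            outputs.append(
                pp.event_triggered_matrix(nd.values, FS, cues, (0.3, 2.0)).mean(axis=0)
            )
        a, b = outputs
        assert np.max(np.abs(a - b)) < 0.15 * max(np.ptp(a), 1e-9) + 5.0
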