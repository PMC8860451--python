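"""Probabilistic movement-state decoding.

Each 10 ms timepoint of each trial is labeled non-movement (0) from the cue
until 160 ms before the first-lick, or movement (1) at the single timepoint
150 ms before the first-lick; later points never enter the design.  A
logistic GLM p(s_t = 1) = logistic(b X_t) is fit on predictors built from the
smoothed, 100 Hz-downsampled signal: nine 200 ms-mean history bins reaching
2 s into the past (most distant first) and the current value.  Nesting the
history from distant to recent shows recent signal absorbing the variance
explained by older history - the signature of a diffusion-like ramp.

Because s = 0 points vastly outnumber s = 1 points, each fit is repeated on
100 balanced subsets (all s = 1 plus an equal count of random s = 0 points)
and the coefficients averaged.  The averaged model's mean predicted
probability across trials, as a function of time since the cue, is the
fitted hazard; it is compared (after min-max normalization of both) with the
empirical hazard from the behavioral distribution by R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .behavior import hazard_function, timing_histogram
from .config import ParameterError
from .decode_time import smooth_trace
from .preprocess import DffTrace
from .synth import SessionTimeline

HISTORY_BINS = [(1.8, 2.0), (1.6, 1.8), (1.4, 1.6), (1.2, 1.4), (1.0, 1.2),
                (0.8, 1.0), (0.6, 0.8), (0.4, 0.6), (0.2, 0.4)]
STATE_POINT = 0.150  # s = 1 sits 150 ms before the first-lick
STATE_CUTOFF = 0.160  # s = 0 points end 160 ms before the first-lick


@dataclass
class StateSeries:
    X: np.ndarray  # (n_points, 10): 9 history bins (distant first) + current
    s: np.ndarray  # binary labels
    trial: np.ndarray
    t_since_cue: np.ndarray
    fs: float
    predictor_names: list = field(default_factory=lambda: (
        [f"hist_{a:.1f}-{b:.1f}s" for a, b in HISTORY_BINS] + ["current"]
    ))


def _downsample(values: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    step = int(round(fs_in / fs_out))
    if step <= 1:
        return np.asarray(values, dtype=float)
    return np.asarray(values, dtype=float)[::step]


def build_state_series(
    session: SessionTimeline,
    dff: DffTrace,
    fs: float = 100.0,
    smooth_sigma: float = 0.1,
    history: str = "continuous",
) -> StateSeries:
    """Per-timepoint design and movement-state labels.

    ``history='continuous'`` reads history bins from the continuous recording
    (so every post-cue timepoint has a full 2 s of history, reaching into the
    lamp-off interval); ``history='trial'`` zeroes any part of a bin that
    precedes the cue.
    """
    sm = smooth_trace(dff, smooth_sigma) if smooth_sigma > 0 else dff
    x = _downsample(sm.values, dff.sampling_rate, fs)
    dt = 1.0 / fs
    c = np.concatenate([[0.0], np.cumsum(x)])

    def window_mean(i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
        i0c = np.clip(i0, 0, len(x))
        i1c = np.clip(i1, 0, len(x))
        width = np.maximum(i1c - i0c, 1)
        return (c[i1c] - c[i0c]) / width

    rows_X, rows_s, rows_tr, rows_t = [], [], [], []
    tr = session.trials
    for i in range(len(tr)):
        T = tr["first_lick_time"].iloc[i]
        if not np.isfinite(T):
            continue
        t_cue = tr["cue_time"].iloc[i]
        t_state = t_cue + T - STATE_POINT
        t_cut = t_cue + T - STATE_CUTOFF
        if t_state <= t_cue:
            continue
        times = np.arange(t_cue, t_cut, dt)
        times = np.append(times, t_state)
        labels = np.zeros(len(times))
        labels[-1] = 1.0
        idx = np.round(times * fs).astype(int)
        ok = idx < len(x)
        times, labels, idx = times[ok], labels[ok], idx[ok]
        cols = []
        for a, b in HISTORY_BINS:
            lo = np.round((times - b) * fs).astype(int)
            hi = np.round((times - a) * fs).astype(int)
            if history == "trial":
                cue_i = int(round(t_cue * fs))
                lo = np.maximum(lo, cue_i)
                hi = np.maximum(hi, cue_i)
            cols.append(np.where(hi > lo, window_mean(lo, hi), 0.0))
        cols.append(x[idx])
        rows_X.append(np.column_stack(cols))
        rows_s.append(labels)
        rows_tr.append(np.full(len(times), i))
        rows_t.append(times - t_cue)
    if not rows_X:
        raise ParameterError("no licked trials: cannot build the state series")
    return StateSeries(
        X=np.vstack(rows_X),
        s=np.concatenate(rows_s),
        trial=np.concatenate(rows_tr),
        t_since_cue=np.concatenate(rows_t),
        fs=fs,
    )


@dataclass
class StateFit:
    coef: list  # per nest: averaged (d_j + 1,) vector, intercept first
    coef_sd: list
    nests: list
    n_boot: int
    log_imbalance: float = 0.0  # log(n_s0 / n_s1) of the full design


def _fit_logistic(X: np.ndarray, s: np.ndarray, ridge: float = 1e-4) -> np.ndarray:
    """One logistic fit; the tiny ridge stabilizes separated data."""
    clf = LogisticRegression(C=1.0 / ridge, max_iter=2000, tol=1e-8)
    clf.fit(X, s)
    return np.concatenate([clf.intercept_, clf.coef_.ravel()])


def fit_state_model(
    series: StateSeries,
    n_boot: int = 100,
    seed: int = 0,
    min_states: int = 50,
    nests: list[int] | None = None,
) -> StateFit:
    """Nested logistic fits averaged over class-balanced resamples.

    Nest j uses the j most distant predictors (nest 1: only the 1.8-2.0 s
    history bin; nest 10: all nine bins plus the current value).  Each of the
    ``n_boot`` refits uses every s = 1 point and an equal count of randomly
    drawn s = 0 points.
    """
    s1 = np.flatnonzero(series.s == 1)
    s0 = np.flatnonzero(series.s == 0)
    if len(s1) < min_states:
        raise ParameterError(f"need >= {min_states} movement-state points, got {len(s1)}")
    if nests is None:
        nests = list(range(1, series.X.shape[1] + 1))
    rng = np.random.default_rng(seed)
    coefs, sds = [], []
    for d in nests:
        draws = np.empty((n_boot, d + 1))
        for b in range(n_boot):
            pick = rng.choice(s0, size=len(s1), replace=len(s0) < len(s1))
            idx = np.concatenate([s1, pick])
            draws[b] = _fit_logistic(series.X[idx, :d], series.s[idx])
        coefs.append(draws.mean(axis=0))
        sds.append(draws.std(axis=0))
    return StateFit(
        coef=coefs, coef_sd=sds, nests=nests, n_boot=n_boot,
        log_imbalance=float(np.log(len(s0) / len(s1))),
    )


def _predict_p(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    z = coef[0] + X[:, : len(coef) - 1] @ coef[1:]
    return 1.0 / (1.0 + np.exp(-z))


def fitted_hazard(
    fit: StateFit,
    series: StateSeries,
    first_lick_times: np.ndarray,
    bin_width: float = 0.25,
    nest: int = -1,
    correct_imbalance: bool = True,
    min_opportunities: int = 10,
) -> dict:
    """Fitted vs empirical hazard, both min-max normalized, with their R^2.

    The fitted hazard is the mean predicted movement probability across the
    trials still unlicked in each time bin; the empirical hazard comes from
    the behavioral first-lick distribution.  ``correct_imbalance`` removes
    the case-control intercept shift log(n0/n1) induced by the balanced
    resampling, putting predictions back on the true probability scale
    before averaging.  R^2 = 1 - SSE/SST over bins where both curves are
    defined and the empirical hazard rests on at least ``min_opportunities``
    remaining trials.
    """
    coef = fit.coef[nest].copy()
    if correct_imbalance:
        coef[0] -= fit.log_imbalance
    p = _predict_p(coef, series.X)
    t_max = float(np.nanmax(first_lick_times))
    hist = timing_histogram(first_lick_times, bin_width, t_max)
    emp = hazard_function(hist)
    nb = len(emp.bin_centers)
    bins = np.minimum((series.t_since_cue / bin_width).astype(int), nb - 1)
    steps_per_bin = bin_width * series.fs
    fit_hz = np.full(nb, np.nan)
    for b in range(nb):
        m = bins == b
        if m.any():
            # per-timestep p -> per-bin hazard (prob of >=1 transition in the bin)
            fit_hz[b] = 1.0 - (1.0 - p[m].mean()) ** steps_per_bin
    ok = np.isfinite(fit_hz) & (emp.opportunities >= min_opportunities)
    if ok.sum() < 3:
        return {"r2": np.nan, "fitted": fit_hz, "empirical": emp, "bins_used": int(ok.sum())}

    def norm01(v):
        lo, hi = np.nanmin(v[ok]), np.nanmax(v[ok])
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    f_n = norm01(fit_hz)
    e_n = norm01(emp.hazard)
    sse = float(np.sum((f_n[ok] - e_n[ok]) ** 2))
    sst = float(np.sum((e_n[ok] - e_n[ok].mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return {
        "r2": float(r2),
        "fitted": f_n,
        "empirical": e_n,
        "bin_centers": emp.bin_centers,
        "bins_used": int(ok.sum()),
    }


def shuffled_fit(
    series: StateSeries, n_boot: int = 100, seed: int = 0, **kw
) -> tuple[StateFit, StateSeries]:
    """Refit after shuffling the state labels (overfitting guard: the
    shuffled model's hazard R^2 should collapse)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(series.s))
    shuffled = StateSeries(
        X=series.X,
        s=series.s[perm],
        trial=series.trial,
        t_since_cue=series.t_since_cue,
        fs=series.fs,
    )
    return fit_state_model(shuffled, n_boot=n_boot, seed=seed, **kw), shuffled


# ---------------------------------------------------------------------------
# logistic ground-truth generator (for parameter- and hazard-recovery checks)


def simulate_logistic_trials(
    n_trials: int = 500,
    b0: float = -12.0,
    b1: float = 6.5,
    fs: float = 100.0,
    slope_mean: float = 0.6,
    slope_cv: float = 0.15,
    noise_sd: float = 0.02,
    t_max: float = 17.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Trials whose movement hazard is exactly logistic in the signal.

    Each trial's signal is a noisy ramp with a trial-specific slope; at every
    10 ms step the movement state fires with p = logistic(b0 + b1 * x(t)).
    The reported first-lick is 150 ms after the state transition, mirroring
    how the state labels are placed.  Returns (per-trial signals from the
    cue, first-lick times); trials that never fire are dropped.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(slope_cv**2))
    signals, licks = [], []
    n_steps = int(round(t_max * fs))
    t = np.arange(n_steps) / fs
    for _ in range(n_trials):
        a = rng.lognormal(np.log(slope_mean) - sigma**2 / 2, sigma)
        x = a * t + rng.normal(0, noise_sd, n_steps)
        p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
        fired = np.flatnonzero(rng.random(n_steps) < p)
        if len(fired) == 0:
            continue
        k = fired[0]
        lick = k / fs + STATE_POINT
        signals.append(x[: min(n_steps, int(round(lick * fs)) + 1)])
        licks.append(lick)
    return signals, np.array(licks)


def state_series_from_trials(
    signals: list[np.ndarray], first_lick_times: np.ndarray, fs: float = 100.0
) -> StateSeries:
    """StateSeries built from bare per-trial cue-aligned signals (history
    bins read zeros before the cue)."""
    rows_X, rows_s, rows_tr, rows_t = [], [], [], []
    dt = 1.0 / fs
    for i, (x, T) in enumerate(zip(signals, first_lick_times)):
        t_state = T - STATE_POINT
        t_cut = T - STATE_CUTOFF
        if t_state <= 0:
            continue
        times = np.append(np.arange(0.0, t_cut, dt), t_state)
        idx = np.round(times * fs).astype(int)
        ok = idx < len(x)
        times, idx = times[ok], idx[ok]
        labels = np.zeros(len(times))
        if len(labels):
            labels[-1] = 1.0
        c = np.concatenate([[0.0], np.cumsum(x)])
        cols = []
        for a, b in HISTORY_BINS:
            lo = np.clip(np.round((times - b) * fs).astype(int), 0, len(x))
            hi = np.clip(np.round((times - a) * fs).astype(int), 0, len(x))
            width = np.maximum(hi - lo, 1)
            cols.append(np.where(hi > lo, (c[hi] - c[lo]) / width, 0.0))
        cols.append(x[idx])
        rows_X.append(np.column_stack(cols))
        rows_s.append(labels)
        rows_tr.append(np.full(len(times), i))
        rows_t.append(times)
    return StateSeries(
        X=np.vstack(rows_X),
        s=np.concatenate(rows_s),
        trial=np.concatenate(rows_tr),
        t_since_cue=np.concatenate(rows_t),
        fs=fs,
    )


# ---------------------------------------------------------------------------
# time-slice model selection


def time_slice_selection(
    session: SessionTimeline,
    dff: DffTrace,
    window: float = 0.5,
    fs: float = 100.0,
    smooth_sigma: float = 0.1,
) -> dict:
    """BIC comparison of candidate predictor sets on 500 ms time slices.

    Each trial contributes at most one point per slice (its mean signal in
    the slice window, labeled 1 only if its movement state occurred within
    the slice); trials stop contributing after their lick.  Candidate sets
    combine the slice signal with previous-trial history (n-1 / n-2 lick
    times and outcomes); the winner is the lowest summed BIC over slices
    where every candidate converged.
    """
    import statsmodels.api as sm_api

    sm = smooth_trace(dff, smooth_sigma) if smooth_sigma > 0 else dff
    x = _downsample(sm.values, dff.sampling_rate, fs)
    tr = session.trials
    fl = tr["first_lick_time"].to_numpy()
    cue = tr["cue_time"].to_numpy()
    outc = (tr["outcome"].astype(str) == "reward").astype(float).to_numpy()
    licked = np.flatnonzero(np.isfinite(fl))
    if len(licked) < 3:
        raise ParameterError("too few licked trials for time-slice selection")
    t_max = np.nanmax(fl)
    slices = np.arange(0.0, t_max, window)

    candidates = {
        "signal": ["sig"],
        "signal+n1": ["sig", "prev1_lick", "prev1_outcome"],
        "signal+n1+n2": ["sig", "prev1_lick", "prev1_outcome", "prev2_lick", "prev2_outcome"],
        "history_only": ["prev1_lick", "prev1_outcome"],
    }
    bic = {k: 0.0 for k in candidates}
    converged = 0
    failed = 0
    for t0 in slices:
        rows = []
        for i in licked:
            if i < 2:
                continue
            T = fl[i]
            if T - STATE_POINT < t0:  # already moved before this slice
                continue
            a = int(round((cue[i] + t0) * fs))
            b = int(round((cue[i] + min(t0 + window, T - STATE_CUTOFF)) * fs))
            if b <= a or b > len(x):
                continue
            state = float(t0 <= T - STATE_POINT < t0 + window)
            rows.append(
                {
                    "sig": x[a:b].mean(),
                    "prev1_lick": fl[i - 1] if np.isfinite(fl[i - 1]) else 0.0,
                    "prev1_outcome": outc[i - 1],
                    "prev2_lick": fl[i - 2] if np.isfinite(fl[i - 2]) else 0.0,
                    "prev2_outcome": outc[i - 2],
                    "state": state,
                }
            )
        df = pd.DataFrame(rows)
        if len(df) < 10 or df["state"].nunique() < 2:
            continue
        slice_bic = {}
        ok = True
        for name, cols in candidates.items():
            X = sm_api.add_constant(df[cols].to_numpy())
            try:
                import warnings as _w

                with np.errstate(all="ignore"), _w.catch_warnings():
                    _w.simplefilter("ignore")
                    res = sm_api.Logit(df["state"].to_numpy(), X).fit(disp=0, maxiter=200)
                if not np.all(np.isfinite(res.params)) or not np.isfinite(res.bic):
                    raise ValueError("diverged")
                slice_bic[name] = float(res.bic)
            except Exception:
                ok = False
                break
        if ok:
            for name, v in slice_bic.items():
                bic[name] += v
            converged += 1
        else:
            failed += 1
    if converged == 0:
        raise ParameterError("no time slice converged for all candidate models")
    winner = min(bic, key=bic.get)
    return {"bic": bic, "winner": winner, "slices_converged": converged, "slices_failed": failed}
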