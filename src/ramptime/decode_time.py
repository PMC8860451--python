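"""Threshold-crossing analysis and the nested first-lick-time decoder.

A threshold-crossing event on a trial is the first time the smoothed signal
passes a level from low to high *and stays above it* through the end of the
ramping interval (cue + 0.7 s to first-lick - 0.6 s); the debouncing rejects
chance crossings of a noisy trace.  For linear single-trial ramps rising to a
common endpoint, the regression slope of crossing time on first-lick time
grows with the threshold level and approaches 1 at the endpoint level; for a
single discrete step the crossing time is the step time at every level, so
the slope profile is flat.  That contrast is the discriminative signature the
module tests for.

The nested decoder predicts log first-lick time from trial history, baseline
signal summaries and the threshold-crossing times, adding predictors in a
fixed order so each one's marginal explained variance is measured against
everything already known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .config import ParameterError, TaskConfig
from .encoding import extract_ramping_intervals
from .preprocess import DffTrace
from .synth import SessionTimeline

DECODER_NESTS = [
    "null",
    "prev_lick_time",
    "prev_reaction",
    "prev_early",
    "prev_reward",
    "prev_iti_lick",
    "iti_median",
    "loi_median",
    "control_crossing",
    "signal_crossing",
]


def smooth_trace(dff: DffTrace, sigma: float = 0.1) -> DffTrace:
    """100 ms Gaussian smoothing (truncated at 3 sigma), method-preserving."""
    sm = gaussian_filter1d(
        np.asarray(dff.values, dtype=float), sigma * dff.sampling_rate, truncate=3.0
    )
    return DffTrace(sm, dff.method, dff.sampling_rate, {**dff.params, "smooth_sigma": sigma},
                    list(dff.excluded_trials))


def ramping_intervals(
    session: SessionTimeline, dff: DffTrace, smooth_sigma: float = 0.1, **kw
) -> tuple[list[np.ndarray], np.ndarray]:
    """Smoothed per-trial ramping-interval segments and their trial ids."""
    sm = smooth_trace(dff, smooth_sigma) if smooth_sigma > 0 else dff
    return extract_ramping_intervals(session, sm, **kw)


def debounced_crossing_times(segments: list[np.ndarray], level: float) -> np.ndarray:
    """Normalized crossing time in (0, 1] per segment, or 0 for no crossing.

    A crossing is the first sample from which the signal stays at or above
    the level through the interval end, reached from below (a trace that
    starts and ends above the level never crosses).
    """
    out = np.zeros(len(segments))
    for k, seg in enumerate(segments):
        n = len(seg)
        suffix_min = np.minimum.accumulate(seg[::-1])[::-1]
        ok = suffix_min >= level
        if not ok.any():
            continue
        i = int(np.argmax(ok))
        if i == 0:
            continue  # started above the level: not a low-to-high crossing
        out[k] = i / n
    return out


@dataclass
class ThresholdSet:
    levels: np.ndarray  # all candidate levels
    counts: np.ndarray  # crossing trials per level
    selected: dict  # name -> (level, count); names 'min','mid','max' (or 'relaxed')
    relaxed: bool = False
    no_crossings: bool = False


def select_thresholds(
    segments: list[np.ndarray],
    n_levels: int = 100,
    mode: str = "multi",
    relaxed: bool = False,
    min_crossings: int = 50,
) -> ThresholdSet:
    """Unbiased threshold levels from the session's own signal range.

    100 evenly spaced candidates span the pooled min-to-max of the ramping
    intervals.  'mid' is the lowest level with the maximum number of crossing
    trials; 'min'/'max' are the lowest/highest levels with at least
    ``min_crossings`` crossings.  Relaxed selection (used for control
    channels, which rarely satisfy the debounce) drops the floor and takes
    the most-crossed level.
    """
    if not segments:
        raise ParameterError("need at least one valid ramping interval")
    pooled_min = min(s.min() for s in segments)
    pooled_max = max(s.max() for s in segments)
    levels = np.linspace(pooled_min, pooled_max, n_levels)
    counts = np.array(
        [int(np.count_nonzero(debounced_crossing_times(segments, lv))) for lv in levels]
    )
    sel: dict = {}
    no_cross = counts.max() == 0
    if no_cross:
        return ThresholdSet(levels, counts, {}, relaxed, True)
    mid_idx = int(np.argmax(counts == counts.max()))
    if relaxed:
        sel["relaxed"] = (float(levels[mid_idx]), int(counts[mid_idx]))
        return ThresholdSet(levels, counts, sel, True, False)
    sel["mid"] = (float(levels[mid_idx]), int(counts[mid_idx]))
    if mode == "multi":
        eligible = np.flatnonzero(counts >= min_crossings)
        if len(eligible):
            sel["min"] = (float(levels[eligible[0]]), int(counts[eligible[0]]))
            sel["max"] = (float(levels[eligible[-1]]), int(counts[eligible[-1]]))
    return ThresholdSet(levels, counts, sel, False, False)


# ---------------------------------------------------------------------------
# nested ridge decoder (dense, trial-level)


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def nested_ridge_cv(
    X: np.ndarray,
    y: np.ndarray,
    nest_ends: list[int],
    folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Generic dense nested ridge with per-nest CV-selected penalties.

    X is (n, d) with column 0 an intercept; nest_ends[j] is the number of
    columns used by nest j.  Returns per-nest held-out R^2 (1 - SSE/SST on
    the held-out trials), coefficients, and penalties.
    """
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 3, 13)
    n = len(y)
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(folds, size=n)
    sst = float(np.sum((y - y.mean()) ** 2))
    out = {"r2_cv": [], "lambda": [], "coef": [], "mse_cv": []}
    for d in nest_ends:
        Xd = X[:, :d]
        best = None
        for lam in lambda_grid:
            sse = 0.0
            for f in range(folds):
                tr = fold_of != f
                te = ~tr
                if te.sum() == 0 or tr.sum() <= 1:
                    continue
                Xt, yt = Xd[tr], y[tr]
                theta = np.linalg.solve(
                    Xt.T @ Xt + len(yt) * lam * np.eye(d), Xt.T @ yt
                )
                resid = y[te] - Xd[te] @ theta
                sse += float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, lam)
        sse, lam = best
        theta = np.linalg.solve(Xd.T @ Xd + n * lam * np.eye(d), Xd.T @ y)
        out["r2_cv"].append(1.0 - sse / sst if sst > 0 else np.nan)
        out["mse_cv"].append(sse / n)
        out["lambda"].append(float(lam))
        out["coef"].append(theta)
    return out


def fit_timelick_decoder(
    session: SessionTimeline,
    dff: DffTrace,
    control_dff: DffTrace,
    folds: int = 5,
    seed: int = 0,
    smooth_sigma: float = 0.1,
) -> dict:
    """Nested decoder of log(first-lick time) per trial.

    Nest order: intercept; previous-trial first-lick time; four previous-
    outcome indicators (reaction, early, reward, ITI lick; no-lick is the
    all-zero level); median signal in the 10 s pre-lamp-off window (ITI);
    median signal lamp-off-to-cue (LOI); control-channel crossing time;
    signal crossing time.  All predictors min-max normalized to (0, 1).
    """
    segs, ids = ramping_intervals(session, dff, smooth_sigma)
    if len(ids) < 20:
        raise ParameterError(f"need >= 20 usable trials, got {len(ids)}")
    csegs_all, cids = ramping_intervals(session, control_dff, smooth_sigma)
    cmap = {i: s for i, s in zip(cids, csegs_all)}

    ts = select_thresholds(segs, mode="single")
    if ts.no_crossings:
        sig_cross = np.ones(len(ids))
    else:
        sig_cross = debounced_crossing_times(segs, ts.selected["mid"][0])
    csegs = [cmap.get(i, np.zeros(2)) for i in ids]
    cts = select_thresholds(csegs, relaxed=True)
    if cts.no_crossings:
        ctrl_cross = np.ones(len(ids))
    else:
        ctrl_cross = debounced_crossing_times(csegs, cts.selected["relaxed"][0])

    tr = session.trials
    fs = dff.sampling_rate
    fl = tr["first_lick_time"].to_numpy()
    lamp = tr["lampoff_time"].to_numpy()
    cue = tr["cue_time"].to_numpy()
    outc = tr["outcome"].astype(str).to_numpy()

    rows = []
    keep = []
    for k, i in enumerate(ids):
        if i == 0:
            continue  # no previous trial
        a = int(round((lamp[i] - 10.0) * fs))
        b = int(round(lamp[i] * fs))
        c = int(round(cue[i] * fs))
        if a < 0 or c > len(dff.values):
            continue
        prev_t = fl[i - 1] if np.isfinite(fl[i - 1]) else 0.0
        rows.append(
            [
                1.0,
                prev_t,
                float(outc[i - 1] == "reaction"),
                float(outc[i - 1] == "early"),
                float(outc[i - 1] == "reward"),
                float(outc[i - 1] == "iti_lick"),
                float(np.median(dff.values[a:b])),
                float(np.median(dff.values[b:c])),
                ctrl_cross[k],
                sig_cross[k],
            ]
        )
        keep.append(i)
    X = np.array(rows)
    y = np.log(fl[np.array(keep)])
    for j in range(1, X.shape[1]):
        X[:, j] = _minmax01(X[:, j])

    nest_ends = list(range(1, len(DECODER_NESTS) + 1))
    res = nested_ridge_cv(X, y, nest_ends, folds=folds, seed=seed)
    res["nests"] = DECODER_NESTS
    res["trials"] = np.array(keep)
    res["design"] = X
    res["log_first_lick"] = y
    res["thresholds"] = ts
    return res


def threshold_slope_analysis(
    segments: list[np.ndarray],
    first_lick_times: np.ndarray,
    threshold_set: ThresholdSet | None = None,
    cue_buffer: float = 0.7,
    lick_buffer: float = 0.6,
    min_crossing_trials: int = 10,
) -> pd.DataFrame:
    """Regression of absolute crossing time on first-lick time per level.

    Absolute crossing time = cue_buffer + normalized crossing * interval
    duration (s post-cue).  Returns slope, 95% CI, R^2 and n per selected
    level; levels with too few crossing trials are omitted.
    """
    if threshold_set is None:
        threshold_set = select_thresholds(segments, mode="multi")
    first_lick_times = np.asarray(first_lick_times, dtype=float)
    durations = first_lick_times - cue_buffer - lick_buffer
    rows = []
    for name in ("min", "mid", "max"):
        if name not in threshold_set.selected:
            continue
        level, _ = threshold_set.selected[name]
        norm = debounced_crossing_times(segments, level)
        crossed = norm > 0
        if crossed.sum() < min_crossing_trials:
            continue
        t_cross = cue_buffer + norm[crossed] * durations[crossed]
        res = stats.linregress(first_lick_times[crossed], t_cross)
        ci = 1.96 * res.stderr
        rows.append(
            {
                "level_name": name,
                "level": level,
                "slope": res.slope,
                "slope_ci_low": res.slope - ci,
                "slope_ci_high": res.slope + ci,
                "r2": res.rvalue**2,
                "n": int(crossed.sum()),
            }
        )
    if not rows:
        raise ParameterError("fewer than 2 usable threshold levels")
    return pd.DataFrame(rows)
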