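"""Behavioral timing analysis.

The raw first-lick timing histogram is survival-biased: a response at time t
can only be observed if no earlier response occurred.  The hazard function
(IRT/Op analysis) corrects this by dividing the count in each 250 ms bin by
the number of remaining opportunities - the total count of first-licks at
that bin time or later - yielding the conditional probability of moving in a
bin given no earlier movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ParameterError, TaskConfig
from .preprocess import DffTrace, event_triggered_matrix
from .synth import SessionTimeline, classify_outcome  # re-exported

__all__ = [
    "TimingHistogram",
    "HazardCurve",
    "classify_outcome",
    "timing_histogram",
    "hazard_function",
    "reconstruct_histogram",
    "event_aligned_average",
    "baseline_timing_correlation",
    "weber_summary",
]


@dataclass
class TimingHistogram:
    bin_edges: np.ndarray  # length n_bins + 1, half-open [lo, hi) bins
    counts: np.ndarray
    n_trials: int


@dataclass
class HazardCurve:
    bin_centers: np.ndarray
    hazard: np.ndarray  # NaN where opportunities == 0
    opportunities: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.opportunities > 0


def timing_histogram(
    times: np.ndarray,
    bin_width: float = 0.25,
    t_max: float | None = None,
) -> TimingHistogram:
    """First-lick timing histogram with half-open 250 ms bins from zero."""
    t = np.asarray(times, dtype=float)
    t = t[np.isfinite(t)]
    if t_max is None:
        t_max = float(t.max()) if len(t) else bin_width
    n_bins = max(1, int(np.ceil(t_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(t / bin_width).astype(int)
    counts = np.bincount(idx[(idx >= 0) & (idx < n_bins)], minlength=n_bins)
    return TimingHistogram(bin_edges=edges, counts=counts.astype(float), n_trials=len(t))


def hazard_function(hist: TimingHistogram) -> HazardCurve:
    """Per-bin conditional movement probability.

    hazard(b) = counts(b) / opportunities(b), with opportunities(b) the total
    count at bin b or later.  Bins with zero remaining opportunities are
    undefined (NaN), not zero.
    """
    if hist.n_trials < 1 or hist.counts.sum() == 0:
        raise ParameterError("empty histogram")
    opp = np.cumsum(hist.counts[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        hz = np.where(opp > 0, hist.counts / np.where(opp > 0, opp, 1), np.nan)
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0
    return HazardCurve(bin_centers=centers, hazard=hz, opportunities=opp.astype(float))


def reconstruct_histogram(curve: HazardCurve) -> np.ndarray:
    """Invert the hazard back to bin counts via the survival recursion.

    With N0 = opportunities in the first bin: counts(b) = hazard(b) *
    survivors(b), survivors(b+1) = survivors(b) - counts(b).  Exact inverse
    of :func:`hazard_function`.
    """
    survivors = float(curve.opportunities[0]) if len(curve.opportunities) else 0.0
    counts = np.zeros_like(curve.hazard)
    for b in range(len(counts)):
        h = curve.hazard[b]
        if not np.isfinite(h):
            break
        counts[b] = h * survivors
        survivors -= counts[b]
    return counts


def hazard_by_session(times_per_session: list[np.ndarray], bin_width: float = 0.25,
                      t_max: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-session hazards on a common grid and their nan-mean (the default
    averaging style; pooled-trial hazard is ``hazard_function`` on the
    concatenated sample)."""
    if t_max is None:
        t_max = max(float(np.nanmax(t)) for t in times_per_session)
    curves = [hazard_function(timing_histogram(t, bin_width, t_max)) for t in times_per_session]
    grid = curves[0].bin_centers
    mat = np.vstack([c.hazard for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(mat, axis=0)
    return grid, avg


# ---------------------------------------------------------------------------
# event-aligned averages


def event_aligned_average(
    dff: DffTrace,
    events: np.ndarray,
    window: tuple[float, float],
    group_values: np.ndarray | None = None,
    group_edges: np.ndarray | None = None,
    truncate_at: np.ndarray | None = None,
    truncate_buffer: float = 0.15,
) -> dict:
    """Per-group event-aligned mean traces with a bootstrap-free normal CI.

    ``group_values`` (one per event) are binned by ``group_edges``; when
    ``truncate_at`` (absolute times, e.g. first-licks) is given, each trial's
    samples from ``truncate_buffer`` seconds before its truncation time are
    masked, so peri-movement transients do not contaminate the average.
    """
    events = np.asarray(events, dtype=float)
    fs = dff.sampling_rate
    a = int(round(window[0] * fs))
    b = int(round(window[1] * fs))
    tgrid = np.arange(a, b) / fs
    if group_values is None:
        groups = {None: np.arange(len(events))}
    else:
        group_values = np.asarray(group_values, dtype=float)
        if group_edges is None:
            raise ParameterError("group_edges required with group_values")
        idx = np.digitize(group_values, group_edges) - 1
        groups = {
            g: np.flatnonzero(idx == g) for g in range(len(group_edges) - 1)
            if np.any(idx == g)
        }
    out = {}
    for g, sel in groups.items():
        rows = []
        dropped = 0
        for j in sel:
            i = int(round(events[j] * fs))
            if i + a < 0 or i + b > len(dff.values):
                dropped += 1
                continue
            row = dff.values[i + a : i + b].astype(float).copy()
            if truncate_at is not None and np.isfinite(truncate_at[j]):
                cut = truncate_at[j] - truncate_buffer - events[j]
                row[tgrid >= cut] = np.nan
            rows.append(row)
        if not rows:
            continue
        m = np.vstack(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(m, axis=0)
            sd = np.nanstd(m, axis=0)
        cnt = np.sum(np.isfinite(m), axis=0)
        sem = np.where(cnt > 0, sd / np.sqrt(np.maximum(cnt, 1)), np.nan)
        out[g] = {
            "time": tgrid,
            "mean": mean,
            "ci_low": mean - 1.96 * sem,
            "ci_high": mean + 1.96 * sem,
            "n": len(rows),
            "dropped": dropped,
        }
    return out


# ---------------------------------------------------------------------------
# baseline-signal / movement-time correlation


def baseline_timing_correlation(
    dff: DffTrace,
    trials: pd.DataFrame,
    window: str = "baseline",
    lick_range: tuple[float, float] = (0.75, 4.0),
    min_trials: int = 700,
) -> dict:
    """Pearson r between a pre-trial signal window and first-lick time.

    window='baseline' averages the 2 s before lamp-off; window='loi' the
    0.4 s before the cue.  The 95% CI uses the Fisher z transform.  Fewer
    than ``min_trials`` pooled trials triggers a warning, not an error.
    """
    if window == "baseline":
        ref = trials["lampoff_time"].to_numpy()
        span = (-2.0, 0.0)
    elif window == "loi":
        ref = trials["cue_time"].to_numpy()
        span = (-0.4, 0.0)
    else:
        raise ParameterError("window must be 'baseline' or 'loi'")
    fl = trials["first_lick_time"].to_numpy()
    ok = np.isfinite(fl) & (fl >= lick_range[0]) & (fl <= lick_range[1])
    if ok.sum() < 3:
        raise ParameterError("too few qualifying trials")
    if ok.sum() < min_trials:
        warnings.warn(f"only {int(ok.sum())} pooled trials (< {min_trials})")
    fs = dff.sampling_rate
    ref_ok, fl_ok = ref[ok], fl[ok]
    fits = np.array(
        [
            int(round(t * fs)) + int(round(span[0] * fs)) >= 0
            and int(round(t * fs)) + int(round(span[1] * fs)) <= len(dff.values)
            for t in ref_ok
        ]
    )
    m = event_triggered_matrix(dff.values, fs, ref_ok[fits], span)
    x = m.mean(axis=1)
    y = fl_ok[fits]
    if np.std(x) == 0:
        raise ParameterError("zero-variance predictor window")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if n > 3:
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
    else:
        lo, hi = -1.0, 1.0  # Fisher z undefined at n <= 3
    return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)), "n": n}


def weber_summary(times_by_target: dict) -> dict:
    """Per-target mean/SD/CV and the max pairwise CV ratio (scalar property:
    the ratio should be ~1 across target intervals)."""
    stats_out = {}
    for target, times in times_by_target.items():
        t = np.asarray(times, dtype=float)
        t = t[np.isfinite(t)]
        m, s = float(t.mean()), float(t.std())
        stats_out[target] = {"mean": m, "sd": s, "cv": s / m if m else np.nan, "n": len(t)}
    cvs = [v["cv"] for v in stats_out.values() if np.isfinite(v["cv"])]
    ratio = max(cvs) / min(cvs) if len(cvs) >= 2 else None
    return {"targets": stats_out, "max_cv_ratio": ratio}
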