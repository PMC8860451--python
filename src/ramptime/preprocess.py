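"""Fluorescence conditioning.

Raw photometry traces are cleaned of single-point singularities and corrected
for slow bleaching by one of four dF/F = (F - F0)/F0 conventions:

1. ``normalized_baseline`` - F0 is the mean of the 5 s preceding each trial.
2. ``lowpass``             - F0 is a zero-phase low-pass (f_c = 5e-5 Hz) of the
                             whole session.
3. ``multiple_baseline``   - F0 is the mean over the 5 s pre-trial windows of
                             the current trial and its five neighbors on each side.
4. ``moving_average``      - F0 is the centered 200 s moving average, window
                             shrunk symmetrically at the session edges.

Method 1 assumes the pre-trial baseline carries no signal; when baseline
activity covaries with the upcoming movement time that assumption fails and
the correction distorts the trace.  The Distortion Index quantifies this by
comparing min-max-normalized raw and corrected traces over paired-trial
windows in which consecutive trials had very different movement times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import ParameterError, TaskConfig
from .synth import SessionTimeline

DFF_METHODS = ("normalized_baseline", "lowpass", "multiple_baseline", "moving_average")


class DegenerateTraceError(ValueError):
    """Raised when a trace cannot be conditioned (e.g. every point flagged)."""


@dataclass
class DffTrace:
    """A bleach-corrected trace tagged with the method that produced it."""

    values: np.ndarray
    method: str
    sampling_rate: float
    params: dict = field(default_factory=dict)
    excluded_trials: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)


def remove_singularities(values: np.ndarray, k: float = 15.0, max_run: int = 3) -> np.ndarray:
    """Replace isolated points beyond k SD of the mean by linear interpolation.

    Only runs of at most ``max_run`` consecutive flagged samples are treated
    as singularities; longer excursions are left untouched (they are signal,
    not glitches).  Refuses degenerate traces in which everything is flagged.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ParameterError("trace too short")
    sd = x.std()
    if sd == 0:
        return x.copy()
    flagged = np.abs(x - x.mean()) > k * sd
    if flagged.all():
        raise DegenerateTraceError("all samples flagged as singularities")
    out = x.copy()
    # walk flagged runs; interpolate the short ones from their neighbors
    i = 0
    n = len(x)
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j < n and flagged[j]:
            j += 1
        if j - i <= max_run:
            lo = i - 1
            hi = j
            if lo < 0 and hi < n:
                out[i:j] = x[hi]
            elif hi >= n and lo >= 0:
                out[i:j] = x[lo]
            else:
                out[i:j] = np.interp(np.arange(i, j), [lo, hi], [x[lo], x[hi]])
        i = j
    return out


def moving_average_f0(x: np.ndarray, fs: float, window: float = 200.0) -> np.ndarray:
    """Centered sliding mean with the half-window shrunk symmetrically at the
    edges, computed with cumulative sums."""
    n = len(x)
    half = int(round(window * fs / 2.0))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    c = np.concatenate([[0.0], np.cumsum(x)])
    lo = idx - h
    hi = idx + h
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def lowpass_f0(x: np.ndarray, fs: float, fc: float = 5e-5, steepness: float = 0.95) -> np.ndarray:
    """Zero-phase low-pass baseline with a corner at ``fc`` Hz.

    The corner is orders of magnitude below a practical direct design at the
    acquisition rate, so the trace is block-averaged to ~1 Hz, filtered
    forward-backward with a Butterworth whose transition band follows the
    steepness convention (stop edge at fc / (1 - steepness) scaled), and
    interpolated back to the full rate.
    """
    n = len(x)
    dec_fs = min(1.0, fs)
    step = max(1, int(round(fs / dec_fs)))
    m = n // step
    if m < 12:
        # session too short to decimate; fall back to the session mean
        return np.full(n, x.mean())
    xd = x[: m * step].reshape(m, step).mean(axis=1)
    wn = min(0.99, max(2.0 * fc / dec_fs, 1e-6))
    # steeper transition band -> higher order, capped for numerical stability
    order = int(np.clip(round(8 * steepness), 2, 4))
    sos = sps.butter(order, wn, output="sos")
    pad = min(m - 1, 30)
    # filter the demeaned series so DC passes exactly (constant in -> constant out)
    mu = xd.mean()
    f0d = mu + sps.sosfiltfilt(sos, xd - mu, padlen=pad)
    centers = (np.arange(m) + 0.5) * step
    return np.interp(np.arange(n), centers, f0d)


def _pretrial_means(
    x: np.ndarray, fs: float, trials: pd.DataFrame, span: float = 5.0
) -> np.ndarray:
    """Mean fluorescence over the ``span`` seconds preceding each lamp-off;
    NaN where the window falls off the front of the record."""
    out = np.full(len(trials), np.nan)
    for i, t in enumerate(trials["lampoff_time"].to_numpy()):
        a = int(round((t - span) * fs))
        b = int(round(t * fs))
        if a < 0 or b > len(x):
            continue
        out[i] = x[a:b].mean()
    return out


def _trial_spans(trials: pd.DataFrame, fs: float, n: int) -> list[tuple[int, int]]:
    """Per-trial sample spans: lamp-off to the next lamp-off (or record end)."""
    starts = trials["lampoff_time"].to_numpy()
    spans = []
    for i, t in enumerate(starts):
        a = int(round(t * fs))
        b = int(round(starts[i + 1] * fs)) if i + 1 < len(starts) else n
        spans.append((max(a, 0), min(b, n)))
    return spans


def compute_dff(
    values: np.ndarray,
    fs: float,
    method: str = "moving_average",
    trials: pd.DataFrame | None = None,
    window: float = 200.0,
    fc: float = 5e-5,
    steepness: float = 0.95,
    n_neighbor_trials: int = 5,
    clean: bool = True,
) -> DffTrace:
    """(F - F0) / F0 with F0 given by the selected method.

    Methods 1 and 3 need the trial table; trials lacking 5 s of pre-trial
    data are excluded (their samples set to NaN) and listed in
    ``excluded_trials``.
    """
    if method not in DFF_METHODS:
        raise ParameterError(f"unknown dF/F method {method!r}")
    x = np.asarray(values, dtype=float)
    if clean:
        x = remove_singularities(x)
    n = len(x)
    excluded: list[int] = []

    if method == "moving_average":
        f0 = moving_average_f0(x, fs, window)
    elif method == "lowpass":
        f0 = lowpass_f0(x, fs, fc, steepness)
    else:
        if trials is None:
            raise ParameterError(f"method {method!r} requires the trial table")
        pt = _pretrial_means(x, fs, trials)
        f0 = np.full(n, np.nan)
        spans = _trial_spans(trials, fs, n)
        for i, (a, b) in enumerate(spans):
            if method == "normalized_baseline":
                base = pt[i]
            else:  # multiple_baseline: this trial and 5 neighbors each side
                lo = max(0, i - n_neighbor_trials)
                hi = min(len(pt), i + n_neighbor_trials + 1)
                neigh = pt[lo:hi]
                base = np.nanmean(neigh) if np.any(np.isfinite(neigh)) else np.nan
            if not np.isfinite(base):
                excluded.append(i)
                continue
            f0[a:b] = base
        # pre-first-trial and post-last-trial samples keep their nearest F0
        first_valid = np.flatnonzero(np.isfinite(f0))
        if len(first_valid) == 0:
            raise DegenerateTraceError("no trial had usable pre-trial data")
        f0[: first_valid[0]] = f0[first_valid[0]]
        f0[first_valid[-1] + 1 :] = f0[first_valid[-1]]

    with np.errstate(invalid="ignore", divide="ignore"):
        dff = (x - f0) / f0
    return DffTrace(
        values=dff,
        method=method,
        sampling_rate=fs,
        params={"window": window, "fc": fc, "steepness": steepness},
        excluded_trials=excluded,
    )


# ---------------------------------------------------------------------------
# paired-trial Distortion Index


@dataclass
class TrialPair:
    kind: str  # "ER" or "RE"
    first: int
    second: int
    window: tuple[int, int]  # sample span, cue of trial n +/- 20 s


def find_trial_pairs(
    trials: pd.DataFrame,
    fs: float,
    n_samples: int,
    early_window: tuple[float, float] = (0.7, 2.9),
    reward_window: tuple[float, float] = (3.4, 7.0),
    pad: float = 20.0,
) -> list[TrialPair]:
    """Consecutive-trial pairs of kinds ER and RE.

    E trials have an unrewarded first-lick in ``early_window``; R trials a
    first-lick in ``reward_window``.  The analysis window runs from 20 s
    before to 20 s after the cue of the second trial; pairs crossing the
    session edges are dropped.
    """
    fl = trials["first_lick_time"].to_numpy()
    cue = trials["cue_time"].to_numpy()
    is_e = np.isfinite(fl) & (fl >= early_window[0]) & (fl <= early_window[1])
    is_r = np.isfinite(fl) & (fl >= reward_window[0]) & (fl <= reward_window[1])
    pairs = []
    for i in range(len(trials) - 1):
        kind = None
        if is_e[i] and is_r[i + 1]:
            kind = "ER"
        elif is_r[i] and is_e[i + 1]:
            kind = "RE"
        if kind is None:
            continue
        a = int(round((cue[i + 1] - pad) * fs))
        b = int(round((cue[i + 1] + pad) * fs))
        if a < 0 or b > n_samples:
            continue
        pairs.append(TrialPair(kind, i, i + 1, (a, b)))
    return pairs


def _minmax(x: np.ndarray) -> np.ndarray | None:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return None
    return (x - lo) / (hi - lo)


def distortion_index(
    raw: np.ndarray,
    dff: DffTrace,
    pairs: list[TrialPair],
    smooth: float = 0.2,
) -> np.ndarray:
    """Mean over pairs of |normalized F - normalized dF/F| per time point.

    Both traces are min-max normalized over each pair window, so the DI is
    invariant to affine rescaling of either input; flat windows are skipped
    with a warning.  Smoothed with a ``smooth``-second moving average for
    display (pass 0 to disable).
    """
    if not pairs:
        raise ParameterError("need at least one trial pair")
    acc = None
    used = 0
    for p in pairs:
        a, b = p.window
        f = _minmax(np.asarray(raw, dtype=float)[a:b])
        d = _minmax(dff.values[a:b])
        if f is None or d is None or np.any(~np.isfinite(f)) or np.any(~np.isfinite(d)):
            warnings.warn(f"skipping flat/invalid pair window {p.first}-{p.second}")
            continue
        di = np.abs(f - d)
        acc = di if acc is None else acc + di
        used += 1
    if used == 0:
        raise DegenerateTraceError("no usable pair windows")
    di = acc / used
    if smooth > 0:
        w = max(1, int(round(smooth * dff.sampling_rate)))
        di = np.convolve(di, np.ones(w) / w, mode="same")
    return di


# ---------------------------------------------------------------------------
# transient kinetics and normalized dF/F


def event_triggered_matrix(
    values: np.ndarray, fs: float, events: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Stack of signal snippets around each event (events off the record are
    dropped).  Rows are events, columns the window samples."""
    a = int(round(window[0] * fs))
    b = int(round(window[1] * fs))
    rows = []
    for t in np.asarray(events, dtype=float):
        i = int(round(t * fs))
        if i + a < 0 or i + b > len(values):
            continue
        rows.append(values[i + a : i + b])
    if not rows:
        return np.empty((0, b - a))
    return np.vstack(rows)


def transient_half_decay(
    values: np.ndarray,
    fs: float,
    events: np.ndarray,
    window: tuple[float, float] = (-0.5, 1.0),
    min_events: int = 10,
) -> float | None:
    """Half-decay time (s) of the event-aligned average transient.

    The aligned average's baseline is its mean over the pre-event quarter of
    the window; the peak is the post-event maximum.  Returns the time from
    the peak to the first sample at or below baseline + (peak - baseline)/2,
    or None when the average never decays that far within the window.
    """
    m = event_triggered_matrix(values, fs, events, window)
    if m.shape[0] < min_events:
        raise ParameterError(f"need >= {min_events} qualifying events, got {m.shape[0]}")
    avg = m.mean(axis=0)
    i0 = int(round(-window[0] * fs))  # sample of the event
    baseline = avg[: max(1, i0 // 2)].mean()
    post = avg[i0:]
    pk = int(np.argmax(post))
    half = baseline + (post[pk] - baseline) / 2.0
    below = np.flatnonzero(post[pk:] <= half)
    if len(below) == 0:
        return None
    return float(below[0] / fs)


def normalized_dff(
    dff: DffTrace,
    trials: pd.DataFrame,
    lick_window: tuple[float, float] = (2.0, 3.0),
    min_trials: int = 5,
    baseline_span: tuple[float, float] = (-0.5, -0.2),
    peak_span: tuple[float, float] = (-0.05, 0.3),
) -> DffTrace:
    """dF/F expressed as a percentage of the mean lick-transient amplitude.

    The scaling amplitude is the mean baseline-to-peak excursion around the
    first-lick, over trials with first-licks in ``lick_window``; dividing by
    it removes sensor gain, so signals from sensors of different brightness
    overlay.
    """
    fl = trials["first_lick_time"].to_numpy()
    cue = trials["cue_time"].to_numpy()
    ok = np.isfinite(fl) & (fl >= lick_window[0]) & (fl <= lick_window[1])
    if ok.sum() < min_trials:
        raise ParameterError(f"need >= {min_trials} trials with first-lick in {lick_window}")
    licks = cue[ok] + fl[ok]
    fs = dff.sampling_rate
    base = event_triggered_matrix(dff.values, fs, licks, baseline_span).mean(axis=1)
    peak = event_triggered_matrix(dff.values, fs, licks, peak_span).max(axis=1)
    amp = float(np.mean(peak - base))
    if amp <= 0:
        raise DegenerateTraceError("non-positive lick-transient amplitude")
    return DffTrace(
        values=dff.values / amp * 100.0,
        method=dff.method,
        sampling_rate=fs,
        params={**dff.params, "normalized_by": amp},
        excluded_trials=list(dff.excluded_trials),
    )
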