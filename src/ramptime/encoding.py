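"""Nested encoding model of single-trial photometry signals.

The session's concatenated lamp-off-to-lick signal Y is modeled as Y = ThetaX
with progressively richer design matrices ("nests"):

  nest 0  null offset x0
  nest 1  + control-channel trace
  nest 2  + cue kernels (24) and first-lick kernels (28)
  nest 3  + nuisance movement kernels (44, around EMG/accelerometer events)
  nest 4  + per-trial constant baseline offset, amplitude proportional to the
            timed interval (lamp-off to lick)
  nest 5  + 500 "stretch" indicators, each tiling one 1/500 fraction of the
            cue-to-lick interval

Nests 0-3 are timing-independent; 4-5 are timing-dependent.  Each nest is fit
by ridge regression, with the penalty chosen by five-fold cross-validation
blocked by trial, and the contribution of each input is the relative
improvement of held-out loss at the nest where it first appears.

The fits are computed from per-trial Gram matrices (X Xt and X Yt accumulated
trial by trial), so sessions of millions of timepoints never materialize a
dense design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .config import ParameterError, TaskConfig
from .preprocess import DffTrace
from .synth import SessionTimeline

NEST_NAMES = ["null", "control", "cue+lick", "nuisance", "baseline_offset", "stretch"]


# ---------------------------------------------------------------------------
# basis kernels


def raised_cosine_basis(
    n_kernels: int, t_start: float, t_end: float, fs: float, log_spaced: bool = False
) -> np.ndarray:
    """(n_kernels, L) raised-cosine bumps tiling [t_start, t_end].

    Bump j is 0.5*(1 + cos(pi*(t - c_j)/w)) on |t - c_j| < w, with centers
    evenly (or log-evenly) spaced and width twice the center spacing, so
    adjacent bumps overlap and the set tiles the support.
    """
    L = max(2, int(round((t_end - t_start) * fs)))
    t = t_start + np.arange(L) / fs
    if log_spaced:
        # log spacing concentrates kernels near the support start
        u = np.log1p(np.linspace(0, 1, n_kernels) * (np.e - 1))
        centers = t_start + u * (t_end - t_start)
    else:
        centers = np.linspace(t_start, t_end, n_kernels)
    w = 2.0 * max(np.diff(centers).min() if n_kernels > 1 else (t_end - t_start), 1.0 / fs)
    basis = np.zeros((n_kernels, L))
    for j, c in enumerate(centers):
        m = np.abs(t - c) < w
        basis[j, m] = 0.5 * (1 + np.cos(np.pi * (t[m] - c) / w))
    return basis


def discretize_nuisance_events(
    channel: np.ndarray,
    fs: float,
    k: float = 3.0,
    baseline_window: float = 1.0,
    refractory: float = 0.2,
) -> np.ndarray:
    """Onset times of threshold crossings: k SD above a rolling baseline,
    with a refractory period so one burst yields one event."""
    x = np.asarray(channel, dtype=float)
    if len(x) == 0 or np.all(x == x[0]):
        return np.array([])
    w = max(1, int(round(baseline_window * fs)))
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(len(x))
    lo = np.maximum(0, idx - w)
    baseline = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    resid = x - baseline
    sd = resid.std()
    if sd == 0:
        return np.array([])
    above = resid > k * sd
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if len(onsets) and above[0]:
        onsets = np.concatenate([[0], onsets[onsets != 0]])
    events = []
    last = -np.inf
    for i in onsets:
        t = i / fs
        if t - last >= refractory:
            events.append(t)
            last = t
    return np.array(events)


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class EncodingSpec:
    """Predictor layout shared by all trials of one session fit."""

    n_cue: int = 24
    n_lick: int = 28
    n_nuisance: int = 44
    n_stretch: int = 500
    cue_support: tuple[float, float] = (0.0, 0.5)
    lick_support: tuple[float, float] = (-0.5, 0.0)
    nuisance_support: tuple[float, float] = (-0.5, 0.5)

    @property
    def nest_sizes(self) -> list[int]:
        return [1, 1, self.n_cue + self.n_lick, self.n_nuisance, 1, self.n_stretch]

    @property
    def n_predictors(self) -> int:
        return sum(self.nest_sizes)

    def nest_slice(self, level: int) -> slice:
        """Columns occupied by nests 0..level (cumulative)."""
        return slice(0, sum(self.nest_sizes[: level + 1]))

    def group_slices(self) -> dict:
        out = {}
        start = 0
        for name, size in zip(NEST_NAMES, self.nest_sizes):
            out[name] = slice(start, start + size)
            start += size
        return out


def _place_kernels(
    row_block: np.ndarray, basis: np.ndarray, event_offsets: np.ndarray, support_start: int
) -> None:
    """Add each basis kernel at each event offset (samples, trial-local)."""
    d, L = basis.shape
    n = row_block.shape[1]
    for off in event_offsets:
        a = off + support_start
        b = a + L
        sa = max(a, 0)
        sb = min(b, n)
        if sb <= sa:
            continue
        row_block[:, sa:sb] += basis[:, sa - a : sb - a]


def iter_trial_blocks(
    session: SessionTimeline,
    dff: DffTrace,
    control_dff: DffTrace,
    spec: EncodingSpec | None = None,
    nuisance_events: np.ndarray | None = None,
) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield (trial index, X_block (d x n_i), y_i) for each usable trial.

    The trial span runs lamp-off to first-lick; trials without a lick, or
    shorter than the cue-kernel support after the cue, are skipped.
    """
    spec = spec or EncodingSpec()
    fs = dff.sampling_rate
    cfg: TaskConfig = session.meta.get("task") or TaskConfig(sampling_rate=fs)
    if nuisance_events is None:
        ev = np.concatenate(
            [
                discretize_nuisance_events(session.channels["emg"], session.sampling_rate),
                discretize_nuisance_events(session.channels["accel"], session.sampling_rate),
            ]
        )
        nuisance_events = np.sort(ev)

    cue_basis = raised_cosine_basis(spec.n_cue, *spec.cue_support, fs, log_spaced=True)
    lick_basis = raised_cosine_basis(spec.n_lick, *spec.lick_support, fs)
    nuis_basis = raised_cosine_basis(spec.n_nuisance, *spec.nuisance_support, fs)
    d = spec.n_predictors
    g = spec.group_slices()

    tr = session.trials
    for i in range(len(tr)):
        T = tr["first_lick_time"].iloc[i]
        if not np.isfinite(T):
            continue
        t_lamp = tr["lampoff_time"].iloc[i]
        t_cue = tr["cue_time"].iloc[i]
        a = int(round(t_lamp * fs))
        b = int(round((t_cue + T) * fs))
        n_i = b - a
        if n_i < 2 or b > len(dff.values) or a < 0:
            continue
        cue_off = int(round(t_cue * fs)) - a
        if n_i - cue_off < 2:
            continue
        y = np.asarray(dff.values[a:b], dtype=float)
        if np.any(~np.isfinite(y)):
            continue
        X = np.zeros((d, n_i))
        X[g["null"], :] = 1.0
        X[g["control"], :] = control_dff.values[a:b]
        _place_kernels(X[g["cue+lick"]][: spec.n_cue], cue_basis, np.array([cue_off]),
                       int(round(spec.cue_support[0] * fs)))
        _place_kernels(X[g["cue+lick"]][spec.n_cue :], lick_basis, np.array([n_i]),
                       int(round(spec.lick_support[0] * fs)))
        local_ev = nuisance_events[(nuisance_events >= t_lamp - 0.5) & (nuisance_events <= t_cue + T + 0.5)]
        if len(local_ev):
            offs = np.round((local_ev - t_lamp) * fs).astype(int)
            _place_kernels(X[g["nuisance"]], nuis_basis, offs,
                           int(round(spec.nuisance_support[0] * fs)))
        # per-trial constant offset, amplitude proportional to the timed interval
        X[g["baseline_offset"], :] = T
        # stretch: indicator rows tiling equal fractions of the cue-to-lick span
        n_cue_to_lick = n_i - cue_off
        frac = np.arange(n_cue_to_lick) / n_cue_to_lick
        rows = np.minimum((frac * spec.n_stretch).astype(int), spec.n_stretch - 1)
        s0 = g["stretch"].start
        X[s0 + rows, cue_off + np.arange(n_cue_to_lick)] = 1.0
        yield i, X, y


# ---------------------------------------------------------------------------
# nested ridge fit from per-fold Gram matrices


@dataclass
class NestedFit:
    spec: EncodingSpec
    lambdas: list[float]
    coefficients: list[np.ndarray]  # per nest, on the scaled design
    scale: np.ndarray  # per-predictor max-abs divisors
    cv_objective: list[float]  # penalized CV objective at lambda*
    cv_mse: list[float]  # unpenalized held-out MSE per nest
    train_loss: list[float]
    r2: list[float]
    aic: list[float]
    bic: list[float]
    n_timepoints: int
    trial_folds: dict
    improvements: pd.DataFrame = field(default=None)
    gram: tuple = field(default=None, repr=False)

    def coefficients_raw(self, level: int) -> np.ndarray:
        """Coefficients mapped back to the unscaled predictor units."""
        sl = self.spec.nest_slice(level)
        return self.coefficients[level] / self.scale[sl]


def _solve_ridge(XX: np.ndarray, XY: np.ndarray, lam: float, n: int) -> np.ndarray:
    d = XX.shape[0]
    return np.linalg.solve(XX + n * lam * np.eye(d), XY)


def fit_nested_ridge(
    session: SessionTimeline,
    dff: DffTrace,
    control_dff: DffTrace,
    spec: EncodingSpec | None = None,
    folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    max_nest: int = 5,
    seed: int = 0,
) -> NestedFit:
    """Fit all nests with per-nest ridge penalties chosen by trial-blocked CV.

    Accumulates per-fold Gram matrices in one pass over the trials; the
    per-predictor max-abs scaling is applied to the Grams afterwards, so
    rescaling any raw predictor leaves the fitted predictions unchanged.
    """
    spec = spec or EncodingSpec()
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 3, 13)
    d = spec.n_predictors
    rng = np.random.default_rng(seed)

    XXf = np.zeros((folds, d, d))
    XYf = np.zeros((folds, d))
    Syyf = np.zeros(folds)
    nf = np.zeros(folds, dtype=int)
    row_max = np.zeros(d)
    trial_folds: dict[int, int] = {}

    for i, X, y in iter_trial_blocks(session, dff, control_dff, spec):
        f = int(rng.integers(folds))  # fold blocked by trial, not timepoint
        trial_folds[i] = f
        XXf[f] += X @ X.T
        XYf[f] += X @ y
        Syyf[f] += y @ y
        nf[f] += len(y)
        row_max = np.maximum(row_max, np.abs(X).max(axis=1))
    n_total = int(nf.sum())
    if n_total == 0:
        raise ParameterError("no usable trials for the encoding fit")

    scale = np.where(row_max > 0, row_max, 1.0)
    D = 1.0 / scale
    XXf *= D[None, :, None] * D[None, None, :]
    XYf *= D[None, :]

    XX = XXf.sum(axis=0)
    XY = XYf.sum(axis=0)
    Syy = Syyf.sum()

    lambdas, coefs, cv_obj, cv_mse = [], [], [], []
    train_loss, r2s, aics, bics = [], [], [], []
    for level in range(max_nest + 1):
        sl = spec.nest_slice(level)
        best = None
        for lam in lambda_grid:
            obj_sum, mse_sum = 0.0, 0.0
            for f in range(folds):
                if nf[f] == 0:
                    continue
                XXtr = XX[sl, sl] - XXf[f][sl, sl]
                XYtr = XY[sl] - XYf[f][sl]
                ntr = n_total - nf[f]
                theta = _solve_ridge(XXtr, XYtr, lam, ntr)
                sse = Syyf[f] - 2 * theta @ XYf[f][sl] + theta @ XXf[f][sl, sl] @ theta
                mse = sse / nf[f]
                obj_sum += mse + lam * theta @ theta
                mse_sum += mse
            k = int(np.sum(nf > 0))
            obj, mse_cv = obj_sum / k, mse_sum / k
            if best is None or obj < best[0]:
                best = (obj, mse_cv, lam)
        obj, mse_cv, lam = best
        theta = _solve_ridge(XX[sl, sl], XY[sl], lam, n_total)
        sse = Syy - 2 * theta @ XY[sl] + theta @ XX[sl, sl] @ theta
        ybar_sse = Syy - (XY[0] ** 2) / max(XX[0, 0], 1e-300)  # x0 row is all ones
        k_par = sl.stop
        lambdas.append(float(lam))
        coefs.append(theta)
        cv_obj.append(float(obj))
        cv_mse.append(float(mse_cv))
        train_loss.append(float(sse / n_total))
        r2s.append(float(1.0 - sse / ybar_sse) if ybar_sse > 0 else np.nan)
        aics.append(float(n_total * np.log(max(sse / n_total, 1e-300)) + 2 * k_par))
        bics.append(float(n_total * np.log(max(sse / n_total, 1e-300)) + k_par * np.log(n_total)))

    # relative held-out loss improvement at the nest where each input appears;
    # nest 0 (x0) is itself the null model, so its improvement is vs var(Y)
    null_mse = float((Syy - (XY[0] ** 2) / max(XX[0, 0], 1e-300)) / n_total)
    rows = []
    prev = None
    for level in range(max_nest + 1):
        ref = null_mse if level == 0 else prev
        rows.append(
            {
                "nest": level,
                "input": NEST_NAMES[level],
                "cv_mse": cv_mse[level],
                "rel_improvement": (ref - cv_mse[level]) / ref if ref else np.nan,
            }
        )
        prev = cv_mse[level]
    improvements = pd.DataFrame(rows)

    return NestedFit(
        spec=spec,
        lambdas=lambdas,
        coefficients=coefs,
        scale=scale,
        cv_objective=cv_obj,
        cv_mse=cv_mse,
        train_loss=train_loss,
        r2=r2s,
        aic=aics,
        bic=bics,
        n_timepoints=n_total,
        trial_folds=trial_folds,
        improvements=improvements,
        gram=(XX, XY, Syy),
    )


def ridge_closed_form(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Reference ridge solution (X X^T + n lam I)^-1 X y for a dense d x n
    design; the nested fitter must agree with this on small systems."""
    d, n = X.shape
    return np.linalg.solve(X @ X.T + n * lam * np.eye(d), X @ y)


def simulate_fit_uncertainty(
    fit: NestedFit,
    level: int = 5,
    n_draws: int = 1000,
    seed: int = 0,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Coefficient draws from the ridge sampling distribution.

    Sigma_theta = sigma^2 A^-1 (X X^T) A^-1 with A = X X^T + n lam I and
    sigma^2 the training residual variance (the ridge "sandwich").  Returns
    an (n_draws, d) array on the scaled design.
    """
    XX, XY, Syy = fit.gram
    sl = fit.spec.nest_slice(level)
    theta = fit.coefficients[level]
    n = fit.n_timepoints
    lam = fit.lambdas[level]
    sse = Syy - 2 * theta @ XY[sl] + theta @ XX[sl, sl] @ theta
    sigma2 = max(sse, 0.0) / n
    A = XX[sl, sl] + n * lam * np.eye(sl.stop)
    Ainv = np.linalg.inv(A)
    cov = sigma2 * Ainv @ XX[sl, sl] @ Ainv
    cov = (cov + cov.T) / 2 + jitter * np.eye(sl.stop)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(theta, cov, size=n_draws, method="eigh")


def prediction_bands(
    fit: NestedFit,
    X: np.ndarray,
    level: int = 5,
    n_sim: int = 300,
    q: tuple[float, float] = (2.5, 97.5),
    seed: int = 0,
) -> dict:
    """Point prediction and simulated coefficient-uncertainty bands for a
    dense (d x n) design block (scaled units are applied internally)."""
    sl = fit.spec.nest_slice(level)
    Xs = X[: sl.stop] / fit.scale[sl][:, None]
    draws = simulate_fit_uncertainty(fit, level, n_draws=n_sim, seed=seed)
    sims = draws @ Xs
    lo, hi = np.percentile(sims, q, axis=0)
    point = fit.coefficients[level] @ Xs
    return {"point": point, "lo": np.minimum(lo, point), "hi": np.maximum(hi, point)}


# ---------------------------------------------------------------------------
# PCA of ramping intervals


def extract_ramping_intervals(
    session: SessionTimeline,
    dff: DffTrace,
    cue_buffer: float = 0.7,
    lick_buffer: float = 0.6,
    min_duration: float = 0.1,
    lick_range: tuple[float, float] = (1.4, 17.0),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-trial cue+0.7 s to lick-0.6 s signal segments and their trial ids.

    Trials with first-lick outside ``lick_range`` or a segment shorter than
    ``min_duration`` are excluded.
    """
    fs = dff.sampling_rate
    tr = session.trials
    segs, ids = [], []
    for i in range(len(tr)):
        T = tr["first_lick_time"].iloc[i]
        if not np.isfinite(T) or not (lick_range[0] <= T <= lick_range[1]):
            continue
        t_cue = tr["cue_time"].iloc[i]
        a = int(round((t_cue + cue_buffer) * fs))
        b = int(round((t_cue + T - lick_buffer) * fs))
        if b - a < max(2, int(round(min_duration * fs))) or a < 0 or b > len(dff.values):
            continue
        seg = np.asarray(dff.values[a:b], dtype=float)
        if np.any(~np.isfinite(seg)):
            continue
        segs.append(seg)
        ids.append(i)
    return segs, np.array(ids, dtype=int)


def max_interpolation_length(cfg: TaskConfig, cue_buffer: float = 0.7,
                             lick_buffer: float = 0.6) -> int:
    """Common sample count all ramping intervals are interpolated to: the
    longest possible interval (trial end minus both buffers) at the
    acquisition rate.  3.3 s task at 1 kHz: (7 - 0.7 - 0.6) s -> 5700."""
    return int(round((cfg.trial_end - cue_buffer - lick_buffer) * cfg.sampling_rate))


def pca_ramping_intervals(
    segments: list[np.ndarray],
    target_length: int,
    n_components: int = 3,
) -> dict:
    """PCA across trials of length-normalized ramping intervals.

    Each segment is linearly interpolated up to ``target_length`` samples,
    PCA is run across trials, and the ``n_components``-PC reconstructions are
    down-sampled back to each trial's original duration.
    """
    if len(segments) < 3:
        raise ParameterError("need >= 3 ramping intervals after exclusion")
    M = np.vstack(
        [
            np.interp(
                np.linspace(0, 1, target_length), np.linspace(0, 1, len(s)), s
            )
            for s in segments
        ]
    )
    mean = M.mean(axis=0)
    Xc = M - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    var_explained = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    recon = mean + scores @ Vt[:k]
    recon_native = [
        np.interp(np.linspace(0, 1, len(s)), np.linspace(0, 1, target_length), r)
        for s, r in zip(segments, recon)
    ]
    return {
        "components": Vt[:k],
        "scores": scores,
        "mean": mean,
        "variance_explained": var_explained,
        "reconstructions": recon_native,
        "interpolated": M,
    }
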