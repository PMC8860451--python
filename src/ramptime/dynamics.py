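"""Ramp-vs-step classification of single-trial dynamics.

Averaged signals that ramp can arise from single trials that truly ramp, or
from single trials that step abruptly at variable times.  Each trial's
(min-max normalized) ramping-interval signal is therefore classified by
comparing two generative hypotheses under data-driven proposals:

* ramp: y = a*t + b + noise, with Gaussian proposals for slope and intercept
  centered on a RANSAC consensus line and spread set by the maximum
  data-supported slope (signal range / duration);
* step: y = left before the step time, right after, with the step time drawn
  uniformly from the indices where the signal derivative is in its top 5%,
  and segment amplitudes proposed around the segment means.

Noise is proposed from a Beta distribution whose mode is the relevant signal
SD (the normalization puts sigma in (0, 1)).  Classification runs 20
independent traces of 50 refinement rounds; each round flips a fair coin for
the hypothesis class, draws a fresh proposal, and keeps the best-scoring
hypothesis so far.  p(ramp) is the fraction of traces whose final best
hypothesis is a ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ParameterError

BETA_CONCENTRATION = 10.0  # nu = alpha + beta; weakly informative, mode-preserving


@dataclass
class RampHypothesis:
    slope: float
    intercept: float
    sigma: float


@dataclass
class StepHypothesis:
    step_index: int
    left: float
    right: float
    sigma: float


@dataclass
class TrialClassification:
    p_ramp: float
    best_class: str
    best_score: float
    best_hypothesis: object
    best_step_index: int | None
    trace_scores: np.ndarray  # (n_traces, n_rounds) running best score


def normalize_signal(y: np.ndarray) -> np.ndarray:
    """Per-trial min-max normalization to [0, 1] (flat signals map to 0.5)."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        return np.full_like(y, 0.5)
    return (y - lo) / (hi - lo)


def _beta_params(mode: float) -> tuple[float, float]:
    m = float(np.clip(mode, 0.01, 0.99))
    nu = BETA_CONCENTRATION
    return m * (nu - 2) + 1, (1 - m) * (nu - 2) + 1


def ransac_line(
    t: np.ndarray, y: np.ndarray, n_iter: int = 50, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Dynamic-noise RANSAC line: two-point samples, inlier band 2x the
    median absolute residual of the current consensus, re-estimated per
    iteration; returns the least-squares fit of the best consensus set."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(y)
    if n < 2:
        raise ParameterError("need >= 2 samples")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0])
    best_count, best = -1, (0.0, float(np.mean(y)))
    for _ in range(n_iter):
        i, j = rng.choice(n, size=2, replace=False)
        if t[i] == t[j]:
            continue
        a = (y[j] - y[i]) / (t[j] - t[i])
        b = y[i] - a * t[i]
        resid = np.abs(y - (a * t + b))
        band = 2.0 * max(np.median(resid), 1e-6)
        inliers = resid <= band
        cnt = int(inliers.sum())
        if cnt > best_count and cnt >= 2:
            A = np.polyfit(t[inliers], y[inliers], 1)
            best_count, best = cnt, (float(A[0]), float(A[1]))
    return best


@dataclass
class RampProposal:
    """Proposal distribution for ramp hypotheses on one (normalized) trial."""

    slope_mean: float
    slope_sd: float  # = maxslope, the maximum data-supported slope
    intercept_mean: float
    intercept_sd: float
    sigma_alpha: float
    sigma_beta: float


@dataclass
class StepProposal:
    candidate_indices: np.ndarray  # top-5%-derivative interior indices
    left_mean: np.ndarray  # per candidate
    left_sd: np.ndarray
    right_mean: np.ndarray
    right_sd: np.ndarray
    sigma_alpha: np.ndarray
    sigma_beta: np.ndarray


def ramp_proposal(t: np.ndarray, y: np.ndarray, seed: int | np.random.Generator = 0) -> RampProposal:
    duration = t[-1] - t[0] if len(t) > 1 else 1.0
    maxslope = (y.max() - y.min()) / max(duration, 1e-9)
    a0, b0 = ransac_line(t, y, seed=seed)
    bmax = float(np.mean(y) - maxslope * np.mean(t))
    alpha, beta = _beta_params(np.std(y))
    return RampProposal(
        slope_mean=a0,
        slope_sd=max(maxslope, 1e-6),
        intercept_mean=b0,
        intercept_sd=max(abs(bmax), 0.05),
        sigma_alpha=alpha,
        sigma_beta=beta,
    )


def step_proposal(t: np.ndarray, y: np.ndarray) -> StepProposal:
    n = len(y)
    dy = np.gradient(y)
    interior = np.arange(1, n - 1)
    d_int = dy[interior]
    if np.allclose(d_int, d_int[0]):
        cand = interior  # flat derivative: any interior step time is as likely
    else:
        # top 5% by rank (robust to ties, e.g. a lone clean step), keeping
        # only saliently rising points
        k = max(1, int(round(0.05 * len(d_int))))
        top = np.argpartition(d_int, -k)[-k:]
        top = top[d_int[top] > np.median(d_int)]
        if len(top) == 0:
            top = np.array([int(np.argmax(d_int))])
        cand = np.sort(interior[top])
    lm = np.empty(len(cand))
    ls = np.empty(len(cand))
    rm = np.empty(len(cand))
    rs = np.empty(len(cand))
    sa = np.empty(len(cand))
    sb = np.empty(len(cand))
    for k, s in enumerate(cand):
        left, right = y[:s], y[s:]
        lm[k], rm[k] = left.mean(), right.mean()
        ls[k] = max(left.std(), 1e-3)
        rs[k] = max(right.std(), 1e-3)
        a, b = _beta_params(left.std())
        sa[k], sb[k] = a, b
    return StepProposal(cand, lm, ls, rm, rs, sa, sb)


def propose_ramp(
    signal: np.ndarray,
    t: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    proposal: RampProposal | None = None,
) -> RampHypothesis:
    """Draw one ramp hypothesis from the data-driven proposal."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(signal, dtype=float)
    if len(y) < 10:
        raise ParameterError("signal too short (need >= 10 samples)")
    if t is None:
        t = np.arange(len(y), dtype=float)
    if proposal is None:
        proposal = ramp_proposal(t, y, seed=rng)
    a = rng.normal(proposal.slope_mean, proposal.slope_sd)
    b = rng.normal(proposal.intercept_mean, proposal.intercept_sd)
    s = rng.beta(proposal.sigma_alpha, proposal.sigma_beta)
    return RampHypothesis(float(a), float(b), float(np.clip(s, 1e-4, 1 - 1e-4)))


def propose_step(
    signal: np.ndarray,
    seed: int | np.random.Generator = 0,
    proposal: StepProposal | None = None,
) -> StepHypothesis:
    """Draw one step hypothesis from the data-driven proposal."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(signal, dtype=float)
    if len(y) < 10:
        raise ParameterError("signal too short (need >= 10 samples)")
    if proposal is None:
        proposal = step_proposal(np.arange(len(y), dtype=float), y)
    k = int(rng.integers(len(proposal.candidate_indices)))
    left = rng.normal(proposal.left_mean[k], proposal.left_sd[k])
    right = rng.normal(proposal.right_mean[k], proposal.right_sd[k])
    s = rng.beta(proposal.sigma_alpha[k], proposal.sigma_beta[k])
    return StepHypothesis(
        int(proposal.candidate_indices[k]), float(left), float(right),
        float(np.clip(s, 1e-4, 1 - 1e-4)),
    )


def _gauss_logpdf(x: float, mu: float, sd: float) -> float:
    return float(stats.norm.logpdf(x, mu, sd))


def score_hypothesis(
    signal: np.ndarray,
    hypothesis: RampHypothesis | StepHypothesis,
    t: np.ndarray | None = None,
    ramp_prop: RampProposal | None = None,
    step_prop: StepProposal | None = None,
) -> float:
    """Log joint: log class prior (1/2) + log parameter prior (the proposal
    densities) + iid Gaussian log likelihood of the residuals with SD sigma."""
    y = np.asarray(signal, dtype=float)
    if t is None:
        t = np.arange(len(y), dtype=float)
    if isinstance(hypothesis, RampHypothesis):
        if hypothesis.sigma <= 0:
            return -np.inf
        resid = y - (hypothesis.slope * t + hypothesis.intercept)
        prior = np.log(0.5)
        if ramp_prop is not None:
            prior += _gauss_logpdf(hypothesis.slope, ramp_prop.slope_mean, ramp_prop.slope_sd)
            prior += _gauss_logpdf(
                hypothesis.intercept, ramp_prop.intercept_mean, ramp_prop.intercept_sd
            )
            prior += float(
                stats.beta.logpdf(hypothesis.sigma, ramp_prop.sigma_alpha, ramp_prop.sigma_beta)
            )
    else:
        if hypothesis.sigma <= 0:
            return -np.inf
        s = hypothesis.step_index
        pred = np.where(np.arange(len(y)) < s, hypothesis.left, hypothesis.right)
        resid = y - pred
        prior = np.log(0.5)
        if step_prop is not None:
            k = np.flatnonzero(step_prop.candidate_indices == s)
            if len(k):
                k = int(k[0])
                prior += -np.log(len(step_prop.candidate_indices))
                prior += _gauss_logpdf(hypothesis.left, step_prop.left_mean[k], step_prop.left_sd[k])
                prior += _gauss_logpdf(
                    hypothesis.right, step_prop.right_mean[k], step_prop.right_sd[k]
                )
                prior += float(
                    stats.beta.logpdf(hypothesis.sigma, step_prop.sigma_alpha[k], step_prop.sigma_beta[k])
                )
            else:
                return -np.inf
    n = len(y)
    sig = hypothesis.sigma
    loglik = -n * np.log(sig * np.sqrt(2 * np.pi)) - float(resid @ resid) / (2 * sig**2)
    return float(prior + loglik)


# ---------------------------------------------------------------------------
# vectorized classification


def _batch_ramp_scores(
    t: np.ndarray, y: np.ndarray, p: RampProposal, rng: np.random.Generator, m: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a = rng.normal(p.slope_mean, p.slope_sd, m)
    b = rng.normal(p.intercept_mean, p.intercept_sd, m)
    s = np.clip(rng.beta(p.sigma_alpha, p.sigma_beta, m), 1e-4, 1 - 1e-4)
    resid2 = np.sum((y[None, :] - (a[:, None] * t[None, :] + b[:, None])) ** 2, axis=1)
    n = len(y)
    loglik = -n * np.log(s * np.sqrt(2 * np.pi)) - resid2 / (2 * s**2)
    prior = (
        np.log(0.5)
        + stats.norm.logpdf(a, p.slope_mean, p.slope_sd)
        + stats.norm.logpdf(b, p.intercept_mean, p.intercept_sd)
        + stats.beta.logpdf(s, p.sigma_alpha, p.sigma_beta)
    )
    return prior + loglik, a, b, s


def _batch_step_scores(
    y: np.ndarray, p: StepProposal, rng: np.random.Generator, m: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    kk = rng.integers(len(p.candidate_indices), size=m)
    s_idx = p.candidate_indices[kk]
    left = rng.normal(p.left_mean[kk], p.left_sd[kk])
    right = rng.normal(p.right_mean[kk], p.right_sd[kk])
    sig = np.clip(rng.beta(p.sigma_alpha[kk], p.sigma_beta[kk]), 1e-4, 1 - 1e-4)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    n = len(y)
    sl = s_idx.astype(int)
    left_sse = c2[sl] - 2 * left * c1[sl] + sl * left**2
    right_sse = (c2[n] - c2[sl]) - 2 * right * (c1[n] - c1[sl]) + (n - sl) * right**2
    resid2 = left_sse + right_sse
    loglik = -n * np.log(sig * np.sqrt(2 * np.pi)) - resid2 / (2 * sig**2)
    prior = (
        np.log(0.5)
        - np.log(len(p.candidate_indices))
        + stats.norm.logpdf(left, p.left_mean[kk], p.left_sd[kk])
        + stats.norm.logpdf(right, p.right_mean[kk], p.right_sd[kk])
        + stats.beta.logpdf(sig, p.sigma_alpha[kk], p.sigma_beta[kk])
    )
    return prior + loglik, s_idx, left, right, sig


def classify_trial(
    signal: np.ndarray,
    fs: float = 100.0,
    n_traces: int = 20,
    n_rounds: int = 50,
    seed: int = 0,
    flip_per_round: bool = True,
    min_duration: float = 0.1,
) -> TrialClassification:
    """p(ramp) for one ramping-interval signal.

    The signal is min-max normalized, proposal distributions are built once
    from the data, and each of ``n_traces`` independent traces runs
    ``n_rounds`` rounds of propose-and-retain-best.  With
    ``flip_per_round=False`` the class is chosen once per trace instead of
    re-flipped each round.
    """
    y0 = np.asarray(signal, dtype=float)
    if len(y0) < max(10, int(round(min_duration * fs))):
        raise ParameterError("ramping interval too short to classify")
    y = normalize_signal(y0)
    t = np.arange(len(y)) / fs
    rng = np.random.default_rng(seed)
    rp = ramp_proposal(t, y, seed=rng)
    sp = step_proposal(t, y)

    m = n_traces * n_rounds
    if flip_per_round:
        is_ramp = rng.random((n_traces, n_rounds)) < 0.5
    else:
        is_ramp = np.repeat(rng.random(n_traces) < 0.5, n_rounds).reshape(n_traces, n_rounds)

    scores = np.empty((n_traces, n_rounds))
    r_scores, ra, rb, rs = _batch_ramp_scores(t, y, rp, rng, m)
    s_scores, si, sl_, sr, ss = _batch_step_scores(y, sp, rng, m)
    flat = is_ramp.ravel()
    scores.ravel()[flat] = r_scores[flat]
    scores.ravel()[~flat] = s_scores[~flat]

    # retain-best within each trace
    running = np.maximum.accumulate(scores, axis=1)
    final_idx = np.argmax(scores, axis=1)
    final_is_ramp = is_ramp[np.arange(n_traces), final_idx]
    p_ramp = float(np.mean(final_is_ramp))

    gi = int(np.argmax(scores))
    g_tr, g_rd = divmod(gi, n_rounds)
    if is_ramp[g_tr, g_rd]:
        best_hyp: object = RampHypothesis(float(ra[gi]), float(rb[gi]), float(rs[gi]))
        best_class = "ramp"
    else:
        best_hyp = StepHypothesis(int(si[gi]), float(sl_[gi]), float(sr[gi]), float(ss[gi]))
        best_class = "step"

    # best step time regardless of winning class, for step-aligned averaging
    best_step_i = int(si[int(np.argmax(s_scores))]) if len(s_scores) else None

    return TrialClassification(
        p_ramp=p_ramp,
        best_class=best_class,
        best_score=float(scores.ravel()[gi]),
        best_hypothesis=best_hyp,
        best_step_index=best_step_i,
        trace_scores=running,
    )


# ---------------------------------------------------------------------------
# step-aligned averaging and the step-variance diagnostic


def step_aligned_average(
    signals: list[np.ndarray],
    step_indices: np.ndarray,
    window: int | None = None,
) -> dict:
    """Average of trials re-aligned at their best-fit step sample.

    ``window`` is the half-width in samples (default: the largest one-sided
    span available).  Samples outside a trial are NaN-masked.  True steps at
    variable times average to a clean step; true ramps average to a transient
    riding on a background ramp, whose positive slope is the diagnostic.
    """
    step_indices = np.asarray(step_indices, dtype=int)
    if window is None:
        window = int(max(max(s, len(x) - s) for x, s in zip(signals, step_indices)))
    L = 2 * window + 1
    acc = np.zeros(L)
    cnt = np.zeros(L)
    for x, s in zip(signals, step_indices):
        a = s - window
        for_lo = max(0, a)
        for_hi = min(len(x), s + window + 1)
        if for_hi <= for_lo:
            continue
        acc[for_lo - a : for_hi - a] += x[for_lo:for_hi]
        cnt[for_lo - a : for_hi - a] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return {"average": avg, "counts": cnt, "offset": np.arange(-window, window + 1)}


def background_slope(aligned: dict, exclude: int = 25) -> float:
    """Slope of the step-aligned average away from the step (samples within
    ``exclude`` of the alignment point are masked)."""
    off = aligned["offset"]
    avg = aligned["average"]
    m = (np.abs(off) > exclude) & np.isfinite(avg) & (aligned["counts"] > 1)
    if m.sum() < 3:
        raise ParameterError("too few samples outside the exclusion zone")
    return float(np.polyfit(off[m].astype(float), avg[m], 1)[0])


def step_variance_profile(
    signals: list[np.ndarray],
    first_lick_times: np.ndarray,
    fs: float,
    pool_width: float = 1.0,
    n_landmarks: int = 10,
    min_pool: int = 20,
) -> dict:
    """Cross-trial signal variance vs fraction of the timed interval.

    Trials are pooled by first-lick second (1-2 s, 2-3 s, ...), each pool
    truncated at its earliest lick, and the across-trial variance evaluated
    at 10% landmarks of the truncated span.  A discrete-step process with
    uniform step times predicts an inverted U (variance maximal mid-interval,
    negative curvature); common-endpoint ramps predict variance decreasing
    toward the lick.  Returns per-pool profiles, the mean profile, the
    quadratic curvature and the Spearman trend.
    """
    first_lick_times = np.asarray(first_lick_times, dtype=float)
    lo = np.floor(first_lick_times.min())
    hi = np.floor(first_lick_times.max()) + 1.0
    landmarks = (np.arange(1, n_landmarks + 1)) / n_landmarks
    profiles = []
    pools = []
    for p0 in np.arange(lo, hi, pool_width):
        sel = np.flatnonzero((first_lick_times >= p0) & (first_lick_times < p0 + pool_width))
        if len(sel) < min_pool:
            continue
        t_trunc = first_lick_times[sel].min()
        samples = np.round(landmarks * t_trunc * fs).astype(int) - 1
        samples = np.clip(samples, 0, None)
        vals = []
        for i in sel:
            x = signals[i]
            if samples[-1] >= len(x):
                continue
            vals.append(x[samples])
        if len(vals) < min_pool:
            continue
        v = np.var(np.vstack(vals), axis=0)
        profiles.append(v)
        pools.append((float(p0), float(p0 + pool_width), len(vals)))
    if not profiles:
        raise ParameterError("no pool had enough trials")
    mat = np.vstack(profiles)
    mean_profile = mat.mean(axis=0)
    quad = np.polyfit(landmarks, mean_profile, 2)
    rho = stats.spearmanr(landmarks, mean_profile).statistic if mean_profile.std() > 0 else 0.0
    return {
        "landmarks": landmarks,
        "profiles": mat,
        "pools": pools,
        "mean_profile": mean_profile,
        "curvature": float(quad[0]),
        "spearman_rho": float(rho),
    }
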