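"""Synthetic session generator with known ground truth.

Every downstream stage (dF/F conditioning, hazard analysis, encoding/decoding
GLMs, ramp-vs-step inference, movement-state decoding, opto statistics) is
testable against sessions produced here, because each trial records the latent
quantities the analyses try to recover: the movement-time-dependent baseline
offset, the ramp slope (ramp mode) or step time (step mode), and the opto flag.

First-lick times follow a log-normal with moments matched to the requested
mean and Weber fraction (SD / mean), reproducing the scalar property of
timing: the coefficient of variation is independent of the target interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import GenerativeParams, KernelParams, OptoParams, ParameterError, TaskConfig

# padding (s) before the first lamp-off and after the last trial so that
# -20 s paired-trial windows and pre-lamp-off baselines stay inside the record
SESSION_PAD = 25.0


@dataclass
class SessionTimeline:
    """One behavioral session: continuous channels, event streams, trial table.

    channels: name -> float array at ``sampling_rate`` (gcamp, control, emg, accel)
    events:   name -> sorted times in seconds on the session clock
    trials:   per-trial table (lampoff_time, cue_time, first_lick_time, outcome,
              opto_on, ground truth columns)
    """

    channels: dict
    events: dict
    trials: pd.DataFrame
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def _lognorm_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_first_lick_times(
    n: int,
    mean: float,
    weber_fraction: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n first-lick times (s post-cue) with SD = weber_fraction * mean.

    Log-normal with matched first two moments, truncated below at 0.05 s.
    Deterministic given the seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if mean <= 0 or weber_fraction <= 0:
        raise ParameterError("mean and weber_fraction must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu, sigma = _lognorm_params(mean, weber_fraction)
    t = rng.lognormal(mu, sigma, size=n)
    return np.maximum(t, 0.05)


def _opto_redraw(
    n: int,
    mean: float,
    cv: float,
    multiplier: float,
    window_end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample first-lick times under a hazard multiplied by ``multiplier``
    on [0, window_end] and unmodified afterwards.

    If S is the unmodified survival function, the modified one is
    S(t)^m for t <= E and S(E)^m * S(t)/S(E) for t > E; sampling is by exact
    inverse transform, so m = 1 reproduces the original law exactly.
    """
    mu, sigma = _lognorm_params(mean, cv)
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    u = rng.uniform(size=n)
    s_end = dist.sf(window_end)
    cut = s_end**multiplier
    t = np.empty(n)
    inside = u > cut  # event before the stimulation window closes
    t[inside] = dist.isf(u[inside] ** (1.0 / multiplier))
    t[~inside] = dist.isf(u[~inside] * s_end ** (1.0 - multiplier))
    return np.maximum(t, 0.05)


def classify_outcome(first_lick: float, cfg: TaskConfig) -> str:
    """Outcome label from the first-lick latency (s post-cue, NaN = none).

    Windows are half-open [lo, hi); a lick exactly at the criterion time is
    rewarded.  Licks after trial end but before the ITI ends count as
    iti_lick; absent licks are no_lick.
    """
    if first_lick is None or (isinstance(first_lick, float) and np.isnan(first_lick)):
        return "no_lick"
    if first_lick < 0:
        raise ParameterError("first-lick time cannot be negative")
    if first_lick < cfg.reaction_cutoff:
        return "reaction"
    if first_lick < cfg.criterion_time:
        return "early"
    if first_lick < cfg.trial_end:
        return "reward"
    if first_lick < cfg.iti_end:
        return "iti_lick"
    return "no_lick"


def build_trial_timeline(
    times: np.ndarray,
    cfg: TaskConfig,
    opto: Optional[OptoParams] = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Lay trials on the session clock and label outcomes.

    ``times`` are first-lick latencies post-cue (NaN for no lick).  Each trial
    occupies a slot of lamp-off delay + iti_end seconds; lamp-off of trial 0
    sits at SESSION_PAD.  When ``opto`` is given, a random fraction of trials
    is flagged and their first-lick time re-drawn from the hazard-multiplied
    law fitted (by moment matching) to the input sample.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times[np.isfinite(times)] < 0):
        raise ParameterError("first-lick times must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(times)
    delays = rng.uniform(cfg.lampoff_delay_low, cfg.lampoff_delay_high, size=n)

    opto_on = np.zeros(n, dtype=bool)
    times = times.copy()
    if opto is not None:
        k = int(round(opto.fraction * n))
        stim_idx = rng.choice(n, size=k, replace=False)
        opto_on[stim_idx] = True
        finite = times[np.isfinite(times)]
        m_hat = float(np.mean(finite))
        cv_hat = float(np.std(finite) / m_hat)
        times[stim_idx] = _opto_redraw(
            k, m_hat, cv_hat, opto.hazard_multiplier, cfg.trial_end, rng
        )

    # licks past the ITI end never register within the trial
    times[times >= cfg.iti_end] = np.nan

    lampoff = np.empty(n)
    cue = np.empty(n)
    t0 = SESSION_PAD
    for i in range(n):
        lampoff[i] = t0
        cue[i] = t0 + delays[i]
        t0 = cue[i] + cfg.iti_end

    outcome = [classify_outcome(t, cfg) for t in times]
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "lampoff_time": lampoff,
            "cue_time": cue,
            "first_lick_time": times,
            "outcome": pd.Categorical(
                outcome, categories=["reaction", "early", "reward", "iti_lick", "no_lick"]
            ),
            "opto_on": opto_on,
        }
    )


def transient_kernel(k: KernelParams, fs: float, support: float = 2.0) -> np.ndarray:
    """Sampled first-order transient, peak-normalized to k.amplitude."""
    t = np.arange(0.0, support, 1.0 / fs)
    shape = (1.0 - np.exp(-t / k.rise_tau)) * np.exp(-t / k.decay_tau)
    peak = shape.max()
    if peak <= 0:
        return np.zeros_like(t)
    return k.amplitude * shape / peak


def _add_events(trace: np.ndarray, times: np.ndarray, kernel: np.ndarray, fs: float) -> None:
    """Add a kernel at each event time, in place."""
    n = len(trace)
    for t in np.asarray(times, dtype=float):
        i = int(round(t * fs))
        if i < 0 or i >= n:
            continue
        j = min(n, i + len(kernel))
        trace[i:j] += kernel[: j - i]


def synthesize_session(
    trials: pd.DataFrame,
    gp: GenerativeParams,
    cfg: TaskConfig,
    seed: int | np.random.Generator = 0,
) -> SessionTimeline:
    """Render continuous channels for a laid-out trial table.

    gcamp   = bleach(t) * [F_rest + baseline_offset(T) + latent(t; T)
                           + kernels * events + shared artifact + noise]
    control = bleach'(t) * [F_rest' + gain * shared artifact + noise]
    emg / accel carry bursts at artifact and lick events only.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = cfg.sampling_rate
    end_of_last = float(trials["cue_time"].iloc[-1]) + cfg.iti_end
    n_samp = int(round((end_of_last + SESSION_PAD) * fs))
    tgrid = np.arange(n_samp) / fs

    if np.any(np.diff(trials["cue_time"].to_numpy()) <= 0):
        raise ParameterError("overlapping trials: cue times must strictly increase")

    gcamp = np.full(n_samp, gp.rest_fluorescence, dtype=float)
    latent_only = np.zeros(n_samp)  # baseline offset + ramp/step, pre-bleach
    control = np.full(n_samp, 0.9 * gp.rest_fluorescence, dtype=float)
    emg = np.zeros(n_samp)
    accel = np.zeros(n_samp)

    cue_times = trials["cue_time"].to_numpy()
    lampoff_times = trials["lampoff_time"].to_numpy()
    fl = trials["first_lick_time"].to_numpy()
    lick_abs = cue_times[np.isfinite(fl)] + fl[np.isfinite(fl)]
    rewarded = trials["outcome"].to_numpy() == "reward"
    reward_times = cue_times[rewarded] + fl[rewarded]

    gt_baseline = np.zeros(len(trials))
    gt_slope = np.full(len(trials), np.nan)
    gt_step = np.full(len(trials), np.nan)

    step_frac = rng.uniform(size=len(trials))  # drawn for every trial for seed stability
    for i in range(len(trials)):
        T = fl[i]
        have_lick = np.isfinite(T)
        # movement-time-dependent baseline offset spans the pre-trial baseline
        # (3 s before lamp-off) through the lick (or trial end)
        T_eff = T if have_lick else cfg.trial_end
        offset = gp.baseline_gain / T_eff
        gt_baseline[i] = offset
        a = int(round((lampoff_times[i] - 3.0) * fs))
        b = int(round((cue_times[i] + T_eff) * fs))
        latent_only[max(a, 0) : min(b, n_samp)] += offset

        if not have_lick or gp.ramp_peak_amplitude == 0:
            continue
        c = int(round(cue_times[i] * fs))
        lick_i = int(round((cue_times[i] + T) * fs))
        if gp.dynamics_mode == "ramp":
            dur = T - gp.ramp_onset_lag
            if dur <= 0:
                continue
            slope = gp.ramp_peak_amplitude / dur
            gt_slope[i] = slope
            on = int(round((cue_times[i] + gp.ramp_onset_lag) * fs))
            seg = np.arange(max(on, 0), min(lick_i, n_samp))
            latent_only[seg] += slope * (seg / fs - (cue_times[i] + gp.ramp_onset_lag))
        else:  # step mode: step time uniform on the cue-to-lick interval
            st = step_frac[i] * T
            gt_step[i] = st
            s = int(round((cue_times[i] + st) * fs))
            latent_only[max(s, 0) : min(lick_i, n_samp)] += gp.ramp_peak_amplitude

    gcamp += latent_only

    _add_events(gcamp, cue_times, transient_kernel(gp.cue_kernel, fs), fs)
    _add_events(gcamp, lick_abs, transient_kernel(gp.lick_kernel, fs), fs)
    _add_events(gcamp, reward_times, transient_kernel(gp.reward_kernel, fs), fs)

    # spontaneous licks during ITIs / lamp-off intervals (outside cue->trial_end)
    spont = []
    if gp.spontaneous_lick_rate > 0:
        n_spont = rng.poisson(gp.spontaneous_lick_rate * tgrid[-1])
        cand = np.sort(rng.uniform(0, tgrid[-1], size=n_spont))
        for t in cand:
            k = np.searchsorted(cue_times, t) - 1
            if k < 0 or t > cue_times[k] + cfg.trial_end or t < cue_times[k]:
                spont.append(t)
        spont = np.array(spont)
        _add_events(gcamp, spont, transient_kernel(gp.lick_kernel, fs), fs)
    else:
        spont = np.array([])

    # shared movement artifacts: brief biphasic deflections in both channels,
    # bursts in the movement channels
    n_art = rng.poisson(gp.artifact_rate * tgrid[-1])
    art_times = np.sort(rng.uniform(0, tgrid[-1], size=n_art))
    art_kernel = transient_kernel(KernelParams(gp.artifact_amplitude, 0.005, 0.03), fs, 0.3)
    _add_events(gcamp, art_times, art_kernel, fs)
    _add_events(control, art_times, gp.control_artifact_gain * art_kernel, fs)
    burst = np.concatenate([np.ones(int(0.05 * fs)), np.zeros(1)])
    for ch, gain in ((emg, 1.0), (accel, 0.6)):
        for t in np.concatenate([art_times, lick_abs, spont]):
            i = int(round(t * fs))
            j = min(n_samp, i + len(burst))
            if 0 <= i < n_samp:
                ch[i:j] += gain * burst[: j - i] * rng.normal(1.0, 0.2)

    if gp.noise_sd > 0:
        gcamp += rng.normal(0, gp.noise_sd, n_samp)
        control += rng.normal(0, gp.noise_sd, n_samp)
        emg += rng.normal(0, 0.05, n_samp)
        accel += rng.normal(0, 0.05, n_samp)

    gcamp *= np.exp(-tgrid / gp.bleach_tau)
    control *= np.exp(-tgrid / (1.2 * gp.bleach_tau))

    trials = trials.copy()
    trials["gt_baseline_offset"] = gt_baseline
    trials["gt_ramp_slope"] = gt_slope
    trials["gt_step_time"] = gt_step

    events = {
        "lampoff": lampoff_times,
        "cue": cue_times,
        "first_lick": lick_abs,
        "lick": np.sort(np.concatenate([lick_abs, spont])),
        "reward": reward_times,
        "opto": cue_times[trials["opto_on"].to_numpy()],
    }
    meta = {"params": gp, "task": cfg}
    return SessionTimeline(
        channels={"gcamp": gcamp, "control": control, "emg": emg, "accel": accel},
        events=events,
        trials=trials,
        sampling_rate=fs,
        meta=meta,
    )


def make_session(
    gp: GenerativeParams | None = None,
    cfg: TaskConfig | None = None,
    seed: int = 0,
) -> SessionTimeline:
    """Convenience end-to-end generator: sample lick times, lay out the
    timeline, and render channels, all from one seed."""
    gp = gp or GenerativeParams()
    cfg = cfg or TaskConfig()
    rng = np.random.default_rng(seed)
    times = sample_first_lick_times(gp.n_trials, gp.mean_move_time, gp.weber_fraction, rng)
    trials = build_trial_timeline(times, cfg, gp.opto, rng)
    session = synthesize_session(trials, gp, cfg, rng)
    session.meta["seed"] = seed
    return session
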