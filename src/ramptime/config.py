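"""Task and generator configuration objects.

The self-timed movement task: the houselamp turns off at trial start, a random
delay (uniform 0.4-1.5 s) precedes an audiovisual start-timing cue, and the
animal's first lick after the cue determines the outcome.  Licks before the
reaction cutoff (0.5 s) are reactions; licks before the criterion time are
early (unrewarded); licks between criterion and trial end are rewarded; later
licks fall in the intertrial interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


class ParameterError(ValueError):
    """Raised when a configuration or operation parameter is invalid."""


@dataclass
class TaskConfig:
    """Timing structure of one behavioral session.

    Defaults are the 3.3 s task variant: early window 0-3.333 s, reward
    window 3.333-7 s, ITI up to 17 s post-cue.
    """

    criterion_time: float = 3.333
    trial_end: float = 7.0
    iti_end: float = 17.0
    lampoff_delay_low: float = 0.4
    lampoff_delay_high: float = 1.5
    cue_duration: float = 0.1
    reaction_cutoff: float = 0.5
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.criterion_time < self.trial_end < self.iti_end):
            raise ParameterError(
                "require criterion_time < trial_end < iti_end, got "
                f"{self.criterion_time}, {self.trial_end}, {self.iti_end}"
            )
        if not self.lampoff_delay_low < self.lampoff_delay_high:
            raise ParameterError("lamp-off delay range must have low < high")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def task_5s(cls, **kw) -> "TaskConfig":
        """The 5 s task variant (criterion 4.95 s, trial end 10 s, ITI 20 s)."""
        kw.setdefault("criterion_time", 4.95)
        kw.setdefault("trial_end", 10.0)
        kw.setdefault("iti_end", 20.0)
        return cls(**kw)


@dataclass
class KernelParams:
    """First-order transient shape: amp * (1 - exp(-t/rise)) * exp(-t/decay),
    peak-normalized to `amplitude`."""

    amplitude: float
    rise_tau: float
    decay_tau: float


@dataclass
class OptoParams:
    """Optogenetic manipulation: a hazard multiplier applied on a random
    fraction of trials from the cue until `trial_end`."""

    fraction: float = 0.30
    hazard_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ParameterError("opto fraction must be in (0, 1]")
        if self.hazard_multiplier <= 0:
            raise ParameterError("hazard_multiplier must be > 0")


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the synthetic photometry session.

    The signal channel carries, per trial, a movement-time-dependent baseline
    offset (baseline_gain / T) and a latent cue-to-lick dynamic: in ``ramp``
    mode a linear ramp from a fixed onset lag after the cue to a common
    endpoint amplitude (slope inversely proportional to the timed interval);
    in ``step`` mode a discrete step at a uniformly drawn time within the
    interval.  Both channels share bleaching-like decay, broadband noise and
    sparse movement artifacts; only the signal channel carries the timing
    structure.
    """

    n_trials: int = 500
    weber_fraction: float = 0.30
    mean_move_time: float = 3.0
    dynamics_mode: str = "ramp"  # or "step"
    ramp_peak_amplitude: float = 5.0
    ramp_onset_lag: float = 0.2
    baseline_gain: float = 3.0
    rest_fluorescence: float = 100.0
    cue_kernel: KernelParams = field(default_factory=lambda: KernelParams(3.0, 0.02, 0.10))
    lick_kernel: KernelParams = field(default_factory=lambda: KernelParams(6.0, 0.02, 0.15))
    reward_kernel: KernelParams = field(default_factory=lambda: KernelParams(8.0, 0.03, 0.25))
    bleach_tau: float = 2000.0
    noise_sd: float = 0.3
    artifact_rate: float = 0.1
    artifact_amplitude: float = 2.0
    control_artifact_gain: float = 0.7
    spontaneous_lick_rate: float = 0.05
    opto: Optional[OptoParams] = None

    def __post_init__(self) -> None:
        if self.weber_fraction <= 0:
            raise ParameterError("weber_fraction must be > 0")
        if self.mean_move_time <= 0:
            raise ParameterError("mean_move_time must be > 0")
        if self.ramp_peak_amplitude < 0:
            raise ParameterError("ramp_peak_amplitude must be >= 0")
        if self.dynamics_mode not in ("ramp", "step"):
            raise ParameterError("dynamics_mode must be 'ramp' or 'step'")
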