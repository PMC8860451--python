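# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices that were genuinely open, and what the synthetic data
do and do not establish.

## Task model and synthetic sessions

A session is a sequence of trials on a common clock: houselamp off, a random
delay uniform on 0.4–1.5 s, a 100 ms start-timing cue, and the first lick at
latency `T` after the cue. Outcomes partition `T` with half-open windows:
reaction (< 0.5 s), early (0.5 s–criterion), reward (criterion–trial end),
ITI lick (trial end–ITI end), no-lick otherwise; a lick exactly at the
criterion time is rewarded. Defaults follow the 3.3 s task (criterion
3.333 s, trial end 7 s, ITI end 17 s); a 5 s variant is provided.

First-lick times are drawn from a log-normal with moments matched to a mean
`μ` and Weber fraction `w` (`σ/μ`), truncated below at 0.05 s. The
log-normal is a modeling choice: timing distributions in this task family
are broad and right-skewed but no parametric family is canonical, so the
family here is chosen for qualitative match, and the scalar property (CV
invariant to the target interval) holds by construction. Defaults:
`w = 0.30`, mean 3.0 s — a trained-animal-like distribution that anticipates
the 3.3 s criterion.

The signal channel is rendered as

```
gcamp(t)   = bleach(t) · [F_rest + offset(T) + latent(t;T) + Σ kernels∗events + artifacts + noise]
control(t) = bleach'(t) · [F'_rest + g·artifacts + noise]
```

with `offset(T) = baseline_gain / T` applied from 3 s before lamp-off to the
lick (movement-time-dependent baseline), and `latent` either a linear ramp
from 0.2 s post-cue to a common endpoint amplitude (slope
`A/(T − 0.2)` — slope inversely proportional to the timed interval), or, in
step mode, a step of amplitude `A` at a time uniform on (0, T). Cue, lick
and reward transients are peak-normalized first-order kernels
`(1 − e^(−t/τ_r)) e^(−t/τ_d)`; bleaching is a per-channel single exponential
(default τ = 2000 s, as appreciable bleaching needs minutes); sparse
movement artifacts are injected into both fluorescence channels with a
per-channel gain and into the EMG/accelerometer channels as bursts. Every
trial records its ground truth (offset, ramp slope or step time), and
identical seeds give bit-identical sessions.

Optogenetic stimulation multiplies the first-lick hazard by `m` on a random
30% of trials from the cue until the trial end. Sampling uses the exact
inverse transform of the power-transformed survival function
(`S_m(t) = S(t)^m` inside the stimulation window, proportional continuation
after), so `m = 1` reproduces the unstimulated law exactly — the property
the null-calibration tests rely on.

What the generator does **not** emulate: hemodynamic or wavelength-specific
artifacts, sensor nonlinearity or saturation, slow within-session drifts of
the timing distribution, lick-bout microstructure, and cross-trial latent
state beyond the baseline offset. Passing tests therefore certify the
statistical machinery under these idealized conditions, not performance on
real recordings.

## dF/F and the Distortion Index

Singularities (isolated runs of ≤ 3 samples beyond 15 SD of the mean) are
replaced by linear interpolation; longer excursions are left as signal. The
four `F0` conventions: per-trial 5 s pre-trial mean; zero-phase low-pass of
the whole session (corner 5·10⁻⁵ Hz); the 11-trial (n−5…n+5) multiple
baseline; and the centered 200 s moving average, window shrunk symmetrically
at the session edges. The low-pass corner is far below any practical direct
design at the acquisition rate, so `F0` is computed on a 1 Hz block-mean
decimation with a zero-phase Butterworth (order from the steepness
convention, capped at 4 for stability; DC is passed exactly by filtering the
demeaned series), then interpolated back; it is validated by attenuation at
10× the corner. The filter's startup region is handled by `filtfilt`
padding and is reported, not corrected.

The Distortion Index pairs consecutive trials in which an early lick
(0.7–2.9 s) neighbors a rewarded one (3.4–7 s) (ER and RE orders), takes the
±20 s window around the second trial's cue, min-max normalizes raw `F` and
`dF/F` over the window, and averages `|F̂ − d̂F/F|` across pairs; it is
invariant to affine rescaling of either trace. On baseline-coupled sessions
the per-trial baseline normalization shows the largest DI over the timing
interval, because it subtracts behaviorally meaningful baseline structure.

## Hazard analysis

250 ms half-open bins from zero; hazard = counts / remaining opportunities;
bins with zero remaining opportunities are *undefined* (NaN), never zero.
The survival recursion reconstructs the histogram exactly and is tested as a
round trip. Both pooled-trial and per-session-then-average forms are
provided; averaging across sessions is the default presentation.

## Nested encoding GLM

The session signal from lamp-off to lick (concatenated across trials) is
regressed on cumulative nests: offset; control channel; cue (24
raised-cosine kernels on 0→0.5 s, log-spaced) plus lick (28 kernels,
−0.5→0 s); nuisance-movement kernels (44, −0.5→+0.5 s around thresholded
EMG/accelerometer events, 3 SD above a 1 s rolling baseline with a 200 ms
refractory); a per-trial constant offset with amplitude proportional to the
timed interval; and 500 stretch indicators each tiling 1/500 (0.2%) of the
cue→lick interval. The raised-cosine family is a standard GLM basis choice;
the kernel counts are the defaults above and configurable.

Each predictor is max-abs scaled to 1 (computed over the whole session, so
rescaling a raw input never changes predictions). Fits solve the ridge
normal equations on per-trial Gram matrices accumulated in one pass —
sessions of millions of timepoints never materialize a dense design. The
penalty is selected per nest on a 13-point log grid (10⁻³…10³) by five-fold
CV blocked by *trial*; the per-nest contribution ledger reports the relative
held-out (unpenalized) MSE improvement over the previous nest, with nest 0
scored against the signal-mean null. Coefficient uncertainty uses the ridge
sandwich covariance `σ²A⁻¹(XXᵀ)A⁻¹`, `A = XXᵀ + nλI`, with multivariate
normal draws and simulated prediction bands.

Ramping intervals for PCA span cue+0.7 s to lick−0.6 s (minimum 0.1 s,
first-lick within 1.4–17 s), linearly interpolated to the maximum possible
interval length — `(7 − 0.7 − 0.6) s = 5.7 s`, i.e. 5700 samples at 1 kHz —
before PCA across trials; reconstructions are down-sampled back to native
durations.

## Threshold decoding

Signals are smoothed with a 100 ms Gaussian (truncated at ±3σ). A crossing
at level θ is the first sample reached from below after which the signal
stays ≥ θ through the interval end; non-crossings encode 0, and an
all-non-crossing predictor becomes a constant-ones column (penalized but
uninformative). Candidate thresholds are 100 evenly spaced levels spanning
the session's pooled interval range; 'mid' is the lowest level with maximal
crossings, 'min'/'max' the lowest/highest with ≥ 50, and a relaxed mode
(for control channels, which rarely satisfy the debounce) takes the
most-crossed level regardless.

The decoder predicts `log T` from nested predictors in the order: previous
lick time; four previous-outcome indicators; median signal in the 10 s
pre-lamp-off window; median lamp-off→cue signal; control crossing; signal
crossing — all min-max normalized to (0,1), ridge/5-fold CV per nest.
Medians (not means) summarize the ITI and lamp-off windows.

On step-mode synthetic sessions the slope-vs-level profile is *not* flat at
the point-estimate level: baseline offsets and noise interact with which
trials cross each level, producing weak, noisy slope differences. The
discriminative test is therefore whether consecutive levels' slope
confidence intervals separate — they do for ramps at 500 trials and do not
for steps.

## Ramp-vs-step inference

Trials are min-max normalized so the noise scale σ lives in (0,1). Ramp
proposals are Gaussians centered on a dynamic-noise RANSAC consensus line
(two-point samples, 50 iterations, inlier band 2× the running median
absolute residual) with SD equal to `maxslope` (signal range / duration) for
the slope and `|b_max|` (the intercept implied by `maxslope`) for the
intercept; σ is Beta with mode `std(signal)`. Step proposals draw the step
time uniformly from the top-5%-derivative interior samples (rank-based, so
a lone clean step is found despite ties; flat-derivative signals fall back
to all interior points), segment amplitudes from Gaussians around the
segment means, σ Beta with mode `std(left segment)`. A Beta needs a
concentration the mode alone does not fix; ν = α+β = 10 is used as a weakly
informative, mode-preserving choice. The printed spread notation for the
proposals is read as a standard deviation. The score of a hypothesis is its
log class prior (fair coin) + log proposal density + iid Gaussian residual
log-likelihood.

Classification runs 20 traces × 50 rounds; each round flips the class coin,
draws a fresh proposal, and retains the best score so far (the per-round
class re-flip keeps the two classes symmetric; a per-trace-only flip is
available behind a flag). Because the conditioning data never change within
a trial, the RANSAC consensus and step-candidate statistics are computed
once per trial and all 1000 proposals drawn from them — equivalent in
distribution to re-running the proposal program each round, and an order of
magnitude faster. `p(ramp)` is the fraction of traces ending on a ramp; it
is invariant to affine rescaling of the input and ≥ 80% accurate per class
at SNR 10 on labeled trials.

Diagnostics: step-aligned averaging (align each trial at its best step time;
true steps give a clean step, true ramps a transient on a positively sloped
background) and the variance profile (trials pooled by first-lick second,
truncated at the pool's earliest lick, variance at 10% landmarks; uniform
step times predict an inverted U, common-endpoint ramps a monotone decline).

## Movement-state decoding

Signals are smoothed (100 ms Gaussian) and down-sampled to 100 Hz. Per
licked trial, timepoints from the cue to 160 ms before the lick are state 0
and the single point 150 ms before the lick is state 1. Predictors are nine
200 ms-mean history bins reaching 2 s back (most distant first) plus the
current value; by default history bins read the *continuous* recording (so
every post-cue timepoint has a full 2 s history extending into the lamp-off
interval); a trial-confined mode zeroes pre-cue history instead. Each nest
is fit 100 times on balanced subsets (all state-1 points plus an equal
count of random state-0 points) with a lightly ridge-stabilized logistic
(guarding against separation), and coefficients are averaged.

The fitted hazard converts the balanced-fit predictions back to the true
probability scale by removing the case-control intercept shift
`log(n₀/n₁)`, aggregates per-timestep probabilities into per-250 ms-bin
hazards via `1 − (1 − p̄)^(bin·fs)` (the per-bin probability of at least one
transition), and averages across trials alive in each bin. Fitted and
empirical hazards are then min-max normalized and compared by
`R² = 1 − SSE/SST` over bins whose empirical hazard rests on at least 10
remaining trials (fewer opportunities make the empirical bin mostly
binomial noise). The intercept correction and hazard aggregation are what
let a correctly specified 500-trial session reach R² ≥ 0.9; shuffling the
labels before fitting collapses R² to ≤ 0.1.

The logistic ground-truth generator used for recovery checks drives each
trial's hazard as `logistic(−12 + 6.5·x(t))` on a noisy ramp `x` with
trial-specific slope (mean 0.6/s, CV 0.15). These constants make the hazard
rise steeply near the typical movement time — as in trained behavior — so
the 250 ms histogram bins that carry the rise are populated by hundreds of
trials and the empirical hazard's binomial noise is usually small relative
to the R² budget at 500 trials. That noise floor still fluctuates from
realization to realization: against the *true* hazard the fitted curve
scores R² ≈ 0.94–0.99, but against a single session's *empirical* hazard
the comparison is ~0.95 in the median and can dip below 0.9 for unlucky
draws even when the model is exactly right — a property of the comparison,
not of the fit.

Time-slice model selection fits 500 ms slices (one point per trial per
slice, trials contributing until their lick) for candidate predictor sets
(slice signal; signal + n−1 history; + n−2; history only) and sums BIC over
slices where every candidate converges.

## Opto statistics

KS via the standard two-sample statistic (exact p below 5 samples, with a
warning). Bootstrap shifts draw `n_boot` stimulated/unstimulated pairs and
summarize the difference distribution by its median or mean with a
percentile CI; tests use 10⁵ draws (CI widths scale as expected), the
configurable default is 10⁶. dAUC is the exact integral of
`cdf_stim − cdf_unstim` over 0.7–7 s (each sample contributes
`7 − clip(x, 0.7, 7)`, so no grid is involved); the sign convention here is
stim − unstim (activation → positive), with a `legacy_sign` flag for the
opposite orientation seen in some reports. Permutation p-values use the
add-one estimator `(b+1)/(n+1)` over 10⁴ label shuffles. Under the
simulated null the tests' type-I error at α = 0.05 is calibrated within
±0.04 over 200 sessions.

## Problem sizes and determinism

The test suite and the acceptance script run synthetic sessions at 100 Hz
with a 9 s ITI (all analyses are sampling-rate-agnostic; the generator's
1 kHz default matches the acquisition convention). Session sizes per check:
500 trials for the encoding, threshold-slope and movement-state criteria;
200 labeled trials per class for the classifier; 200 null sessions for
type-I calibration; 10⁵ bootstrap draws and 10⁴ permutations. Every random
quantity is seeded; identical seeds give identical reports end to end.

## Known limitations

- The encoding model is Gaussian; non-Gaussian observation noise and basis
  shape learning are out of scope.
- The nest-4 baseline-offset predictor is linear in the interval while the
  generator's ground-truth offset is inverse in it; the nest still reduces
  held-out loss (rank information), but its coefficient is not a direct
  estimate of the generator's gain.
- Ramp-vs-step inference explores proposals by importance-style
  retain-best refinement, not full posterior inference; `p(ramp)` is a
  classification score, not a posterior probability.
- The movement-state model is plain discrete-time logistic regression, not
  a survival model; its hazard comparison inherits the empirical hazard's
  binomial noise in sparsely populated bins.
- The optional loader for deposited real data is not included; all analyses
  here run on synthetic sessions or user-provided session stores.
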