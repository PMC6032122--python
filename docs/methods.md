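# Methods

This note documents the models, conventions, numerical choices, and
known limitations of `fixsens`, in the order of the analysis chain.

## Conventions

* Time in seconds; gaze in degrees of visual angle; microsaccade
  amplitudes in arcmin; velocities in °/s; eye index 0 = left.
* Trial latency τ = t_stim − t_onset of the *nearest* microsaccade:
  τ > 0 means the stimulus appeared after the microsaccade began. Ties
  at equal |τ| resolve deterministically to the later event (the more
  conservative choice for suppression-window assignment).
* All logarithms applied to contrasts and sensitivity ratios are base
  10. The log sensitivity ratio of a condition is
  SR = log10(sensitivity / baseline sensitivity)
  = −(log10 μ − log10 μ_baseline): negative = suppression (threshold
  elevated), positive = facilitation. This is the only sign convention
  under which a suppression profile is negative, and it is used
  consistently by the observer template, the empirical timecourses, and
  the gain model.
* Baseline trials are those in which *no* microsaccade onset falls
  inside the perisaccadic zone — the stimulus lies more than 0.1 s
  before and more than 0.5 s after every event, i.e. every event has
  τ ≤ −0.1 or τ ≥ +0.5. The same zone, applied to samples instead of
  stimuli, defines the drift baseline. Trials of sessions with no
  events at all carry a τ = +∞ sentinel and are baseline-eligible.

## Synthetic sessions (module `synth`)

The generator produces the statistical structure the analysis assumes,
with these defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| sampling rate | 500 Hz | standard video-based tracking rate |
| microsaccade rate | 1.5 /s (per-subject draws 0.8–2.2 /s in studies) | population range 0.3–2.3 /s, typically 1–2 /s |
| refractory gap | 0.15 s | intersaccadic interval floor |
| amplitude | log-normal, median 12 arcmin, ln-SD 0.5, clipped to [3, 60] | typical fixational-saccade amplitudes, filter bounds of the analysis |
| main sequence | V = 70·A^0.9 °/s (A in °), ln-noise SD 0.1 | gives 20–30 ms durations across the amplitude range |
| velocity profile | raised cosine (peak 2A/D) | smooth, zero-endpoint, unimodal; the analysis is agnostic to the exact shape |
| drift | 2-D Brownian walk, 0.004 °²/s per axis | produces realistic drift speeds (~0.5–1 °/s at 500 Hz differentiation) and a stationary (flat) drift profile |
| tracker noise | 0.002° per eye, independent | exercises the binocular-overlap filter |
| direction | von Mises mixture at 0°/180°, κ = 4 | reproduces the strong horizontal dominance of fixational saccades |
| blinks | 0.1 /s, 0.15 s, pupil = 0 | sparse, enough to exercise masking and trial exclusion |
| ITI | uniform 0.8–4.0 s (+0.2–0.6 s response latency) | the task's stated timing |
| staircases | 1-up-3-down, 0.05 log10 steps, start 0.3 above threshold | converges at p = 0.5^(1/3) ≈ 0.794 |
| observer | log10 thresholds (−1.3, −1.7, −2.0, −2.1, −1.8) at (0.1, 0.33, 1, 2, 5) cycles/°; slope 0.08; lapse 0.055 | a contrast sensitivity function peaking at 1–2 cycles/° |

The observer's sensitivity template is a sum of two Gaussians in τ: a
suppression dip (depth per spatial frequency given by the empirical
cubic over log10 sf — −0.169 log10 units at 0.1 cycles/° — centered at
0.02 s, width 0.067 s) and a facilitation bump (largest +0.08 at
2 cycles/°, centered 0.125 s, width 0.05 s). A trial's threshold is the
baseline threshold shifted by −SR(τ, sf). Both eyes render one
generative event stream; the generator returns the ground-truth event
list for recovery testing.

What the generator does *not* emulate: oculomotor inhibition after
stimulus onset (reported to be weak for near-threshold stimuli),
glissades/overshoot dynamics beyond what the merge rule absorbs,
drift curvature or self-avoidance, tracker calibration error, and
any orientation dependence of suppression. Passing recovery tests
therefore validates the estimators under these idealized conditions,
not the biology of real recordings.

## Preprocessing and detection

Blink samples (pupil = 0) and a 200-ms buffer on each side are
invalidated jointly for both eyes, with no interpolation; trials with a
blink within 100 ms of the stimulus are excluded. Velocities use the
5-sample moving-window differentiator
v_n = (p_{n+2} + p_{n+1} − p_{n−1} − p_{n−2})/(6Δt), which is exact for
affine signals; velocities are invalid wherever the window spans an
invalid sample (no shortened-window estimates — masking happens before
differentiation). Radial velocity gets an additional 5-point moving
average for the drift analyses only.

Detection thresholds per eye and component use the median-based SD
σ = sqrt(median(v²) − median(v)²) over all valid samples of the block
(stationarity within a block is assumed), multiplied by 6, combined in
the elliptic criterion (vx/ηx)² + (vy/ηy)² > 1. Candidates closer than
50 ms (offset to onset, transitively) merge; events shorter than 6 ms
or with net onset→offset displacement outside 3–60 arcmin are dropped;
events must overlap in time across both eyes (any overlap), and the
left eye's parameters are reported. Amplitude is net displacement, not
path length; direction is atan2 of net displacement (0° = rightward,
counterclockwise positive).

## Psychometric fitting

The 2AFC logistic is fit on log10 contrast. Protocol: a joint ML fit of
all data estimates one lapse λ and per-frequency (μ, s); λ and s are
then frozen and every time-binned fit frees only μ. Optimization is
deterministic — a 41-point grid over the contrast range followed by
bounded Brent for μ-only fits, L-BFGS-B from grid-prefit starting
values for joint fits — so fits reproduce without seeds. All-correct or
all-wrong bins are flagged (`boundary`) rather than suppressed; bins
with fewer than 30 trials carry a `low_n` flag.

Sliding bins are 0.1 s wide, stepped by 0.002 s by default; the
recovery tests and example pipelines step by 0.01 s, which samples the
same 0.1-s-wide information at 5× fewer bins and changes no conclusion.

## Resampling

Baselines are matched to each bin's per-subject trial proportions by
drawing without replacement from each subject's baseline pool
(largest-remainder rounding; subsample size = the largest size every
pool supports at those proportions, capped at the baseline size), and
the baseline threshold is the mean over 50 such replicates (smaller
replicate counts are used inside bootstrap loops). Bootstrap CIs
resample trials with replacement before binning (percentile method).
Permutation tests pool the two groups, permute labels preserving sizes,
and use the two-sided statistic |Δ log10 μ| with the add-one correction
p = (1 + #{null ≥ observed})/(n_perm + 1). No correction is applied
across sliding bins; raw p-values are reported.

Family-wise null checks ("SR within CI of zero at *all* bins"; "all
orientation bins mutually compatible") use the simultaneous versions:
Bonferroni-adjusted normal-approximation bootstrap CIs for the former,
pairwise CI overlap for the latter. Literal per-bin 95% checks would
fail under the null with high probability once tens of bins are tested.

## Drift

Left-eye positions are collated in ±1 s epochs around each onset;
samples inside any detected event are removed; truncated edge epochs
are flagged. Box counts use 0.01° square cells anchored at the
coordinate origin (deterministic and comparable across bins; anchoring
shifts counts by ±1 cell occasionally) in 50-ms bins. Both metrics are
divided by their baseline means; empty bins propagate as missing
values. SE bands are computed across events, matching event-level
pooling. An optional partition key allows computing the timecourse per
stimulus spatial frequency; no numeric claims attach to it.

## Delayed normative gain model

The initial state is the separable profile
SR(t, sf) = a·exp(−((t − t_peak)/c)²) × P(log10 sf) with t_peak =
0.02 s, c = 0.067 s, and cubic coefficients
(−0.0723, −0.09754, 0.07958, −0.0641). Two printed-formula ambiguities
are resolved on mathematical grounds: the Gaussian's exponent carries a
minus sign (a growing exponential cannot be a fitted suppression time
course), and the divisive normalization acts on *linear* sensitivity
ratios, i.e. mean subtraction in log space — dividing log ratios by log
ratios can yield neither the zero-net conservation at t_delay = 0 nor
positive rescale factors.

Normalization iterates time bins in ascending order, subtracting from
each bin's channels the channel-mean of the (already updated) state
t_delay earlier; lookbacks before the grid use a zero (baseline) term.
Because the whole operator is linear in the input scale, the two-pass
rescaling is exact: after rebuilding the profile with
a = SR_initial/SR_model at the anchor (t_peak, 0.1 cycles/°), the
final model reproduces the initial fit there to machine precision.

Grids: time −0.1…0.4 s in 2-ms steps (the empirical binning step), the
five studied frequencies as channels. The rescaled amplitudes depend on
these choices at the few-percent level: with a denser or wider grid, or
a different channel set, the delay-0 value moves by several percent
(the default grid yields 2.33; at t_delay = 0.14 the lookback from the
suppression peak precedes the grid entirely, so a = 1.00 exactly).
Emergent behavior checked by tests: facilitation appears without being
built in, its peak time is nondecreasing in t_delay, its spatial tuning
broadens with delay, and for t_delay > 0 the net-SR curve rings
(≥ 2 zero crossings after the suppression peak).

## Problem sizes used by the test suite

Recovery and calibration tests run at sizes chosen to make their
statistical claims decidable while keeping the suite practical: the
recovery study is 15 subjects × 1,000 trials (matching the scale of the
empirical data set per subject), the null study 6 × 800; bootstraps use
200 replicates (scaled from 1,000; CI endpoints are stable to within
5% of the CI width when doubling), permutations 199–999 depending on
the p-value resolution the claim needs; the 20-seed significance check
re-seeds the resampling on a fixed study. The acceptance script's main
sequence uses a single ~420-s session (≥ 500 detected events).

## Known limitations

* The median-based σ estimator is computed over whole-block valid
  samples; traces with strongly nonstationary noise would need
  per-segment thresholds (configurable but not default).
* Amplitudes of detected events are clipped by threshold-crossing
  onsets/offsets, biasing the main-sequence slope below the generating
  exponent (observed ~0.8 vs 0.9); the correlation is unaffected.
* λ and s are point estimates frozen before binned fits; their
  uncertainty is not propagated into SR CIs (the bootstrap covers
  trial-level variability only, matching the original protocol).
* The gain model is a proof of concept on a fitted suppression surface;
  it does not fit empirical SR surfaces by optimization, and channel
  bandwidths/inhibition kernels are out of scope.
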