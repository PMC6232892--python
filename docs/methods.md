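# Methods

This note documents the models, the numerical choices, and what the
synthetic test bed does and does not establish.

## Signal model and preprocessing

Recordings are `C × T` matrices in mV from a circumferential array of `C`
bipolar electrodes (default 8) at 1 kHz. Preprocessing is a 3rd-order
Butterworth high-pass with a 20 Hz break frequency, designed with the
bilinear transform (`scipy.signal.butter`). The high-pass removes
electrode drift and motion artifact below the sEMG power band while
leaving 20–450 Hz content essentially untouched (gain ≥ 0.99 above
~80 Hz; exactly −3 dB at the break). Causal filtering (`lfilter`) is the
default because it is what a real-time decoder sees; zero-phase
(`filtfilt`) is available for offline work where group delay matters.

## Features

Sliding windows of 200 ms at a 100 ms stride. The stride equals the
decoder's decision cadence; the window length is the usual sEMG
bias/latency compromise (shorter windows are noisier, longer ones lag the
user) and is configurable. Per channel and window we compute the four
time-domain features — MAV, curve (waveform) length, zero crossings and
slope sign changes — in channel-major column order (`ch0_MAV … ch7_SSC`,
32 columns at the defaults). Details that are easy to get subtly wrong:

* Curve length is the *unnormalized* sum of absolute successive
  differences; no `1/N` factor.
* ZC counts index pairs with a strict sign change (`np.sign` inequality,
  so an exact zero sample breaks runs on both sides) whose amplitude step
  clears the deadband; SSC counts strict interior extrema
  (`(xᵢ−xᵢ₋₁)(xᵢ−xᵢ₊₁) > 0`) whose larger adjacent step clears the
  deadband. Both deadbands default to 0.01 mV — a small, configurable
  noise-floor guard; 0 disables it.
* A window's label is the cue covering its *center*; windows straddling a
  cue boundary take the center's cue, uncued windows are −1. Cue
  intervals are half-open `[onset, onset + duration)`.
* The vectorized extractor is tested to agree exactly with a per-window
  loop over the scalar feature functions.

## Decoder

LDA with class means `μₖ`, priors `πₖ` (class frequencies by default;
uniform available, since training reps are balanced by design), and the
pooled within-class covariance `S = scatter/(N−K)` shrunk toward a scaled
identity, `Σ(λ) = (1−λ)S + λ(tr S/D)I`. Default `λ = 10⁻³`: a 2 s-per-rep
training burst yields ~19 windows per class, so the 32-dimensional `S` is
routinely near-singular, and trace-scaled ridging is the minimal,
rotation-equivariant fix. `λ = 0` is allowed and raises a dedicated
singular-covariance error (with the suggestion to use a positive λ) when
`Σ` is numerically singular (relative eigenvalue floor 10⁻¹²).

Decisions maximize `gₖ(x) = xᵀΣ⁻¹μₖ − ½μₖᵀΣ⁻¹μₖ + ln πₖ`, computed via a
Cholesky factorization of `Σ`. Scores within `10⁻⁹·max(1, |g_max|)` of
the row maximum are treated as tied and resolved to the lowest class id:
exact discriminant ties (e.g. a probe equidistant between equal-prior
means) land a few ulp apart after the linear algebra, and the tolerance
makes the documented tie-break deterministic in floating point. The
decoder is verified against an explicit equal-covariance Gaussian
log-posterior oracle, a nearest-Mahalanobis-mean oracle, scikit-learn's
`LinearDiscriminantAnalysis`, and an affine-invariance property.

## Protocols and assessment

Passive sessions cue all 11 motions in 120 s blocks, one canonical-order
pass followed by seeded random-order passes. The session score is
stratified 5-fold cross-validated LDA accuracy over the cue-labeled
windows. Cross-validation was chosen over resubstitution because an
"average accuracy score" computed by refitting on its own training
windows is optimistically biased, especially at ~19 windows per class;
resubstitution is available as an option for comparison, and the fold
assignment is seeded (scores on separable simulations move by well under
3 percentage points across fold seeds).

Active assessment runs one trial per motion: the signal is consumed in
100 ms steps, each step classifying the 200 ms window ending at the
decision instant (so a trial needs the 5 s timeout plus one window of
lead-in from its source), stopping at 10 correct decisions or at the
50-decision timeout. Per-motion accuracy is correct/total decisions
*made*; the session score is the arithmetic mean over motions (a pooled
mode is provided), and the completion ratio is reported separately rather
than folded into the score. The session pass flag uses ≥ 95%, while
`proportion_above_threshold` counts strictly > 95%, matching the two ways
such thresholds are conventionally reported.

## Synthetic sEMG generator

Each channel is unit-RMS Gaussian noise band-passed to 20–450 Hz (4th
order Butterworth) and multiplied by a cue-driven RMS envelope: `rest_rms`
(default 0.05 mV) outside cues, the cued class's per-channel activation
inside, with 100 ms linear onset/offset ramps to avoid step
discontinuities that would spike CL/SSC. Class activation patterns are
circular Gaussian bumps centred at equally spaced positions around the
electrode ring plus a small seeded jitter, both scaled by a `separation`
factor: at 0 all classes equal rest; pairwise pattern distances grow
linearly with it. Empirically the full pipeline decodes at ~chance for
separation ≲ 0.05, ~85–90% near 0.2, and ≥ 95% from about 0.3; separation
3 is a comfortably separable regime used for end-to-end checks.

The generator carries class identity purely in the across-channel RMS
pattern — exactly the structure MAV and CL capture. It does *not* model
motor-unit action potentials, electrode crosstalk, fatigue, posture
changes, or non-stationary noise. Passing end-to-end tests therefore
demonstrates the correctness and internal consistency of the pipeline
(features, decoder, protocols, scoring), not clinical-grade decoding
performance on real residual-limb sEMG.

`synth_cohort` emulates a longitudinal study by increasing separation by
`improvement_rate` per session and running the full train→assess pipeline
per (subject, session). Its defaults (base 0.2, +0.02/session) start
subjects in the high-80s and climb toward ceiling over ~20 sessions —
the trajectory shape typical of pattern-recognition training — because
larger baselines saturate every score at 100 and leave no trend to
detect. `simulate_score_table` instead draws scores directly from the
random-intercept model and is the right tool for statistical calibration
studies where the signal chain is irrelevant.

## Longitudinal model

`yᵢⱼ = β₀ + β₁·tᵢⱼ + bᵢ + εᵢⱼ` with `bᵢ ~ N(0, σ_b²)`,
`εᵢⱼ ~ N(0, σ²)`, fitted by maximum likelihood via `statsmodels.MixedLM`
with Wald inference on β₁. ML + Wald is the plainest reading of an
"unadjusted longitudinal mixed model"; a REML flag is provided. The time
variable defaults to session index (1, 2, …), with calendar `day_offset`
as an alternative. Groups are limbs, so a bilateral participant
contributes two independent baselines.

Numerical edge handling: when the σ_b² estimate lands on the zero
boundary, `MixedLM`'s fixed-effect estimates and Hessian-based standard
errors are unreliable (the Hessian is singular there), so the fit falls
back to pooled OLS — which *is* the exact ML solution at σ_b² = 0. The
fallback triggers at `σ_b² ≤ 10⁻⁸·σ²` or a non-finite Wald p-value, and
also if both the L-BFGS and Powell optimizers fail. Calibration is
checked by simulation: 95% Wald CIs cover a true slope of 0.45 %/session
in ≥ 90% of 200 cohorts of 9 limbs × 20 sessions, and null-slope p-values
are uniform (KS test at α = 0.01).

Degenerate inputs are rejected with actionable messages: one session per
subject (suggests OLS), constant scores (no variance to decompose), zero
variance in the one-sample t-test.

## Problem sizes

Unit and property tests run on seconds-long recordings and small
synthetic cohorts. End-to-end checks use the protocol-defined sizes: 24 s
active training sessions (6 motions × 2 reps × 2 s), full passive
sessions of 22 two-minute blocks (~44 min of 8-channel signal), 5 s
assessment trials, and 200 simulated 9×20 cohorts for the slope-recovery
study. All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give bit-identical signals, schedules and scores.

## Known limitations

* The simulator's amplitude-pattern model makes class separability almost
  entirely an MAV/CL phenomenon; ZC/SSC contribute little on synthetic
  data, so their discriminative value on real sEMG is untested here.
* The passive vocabulary fixes six of its eleven motion names by
  convention (the grasp/deviation fillers); they are labels only and are
  user-configurable.
* No online adaptation of the decoder, no random slopes or covariate
  adjustment in the longitudinal model, and no avatar/rendering layer —
  cues exist only as schedules.
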