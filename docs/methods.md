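# Methods

This package decodes three mental states — mental arithmetic (MA), motor
imagery (MI) and idle state (IS) — from simultaneously recorded EEG and
NIRS, and evaluates the decoder by repeated stratified cross-validation.
This note documents the models, the parameters that matter, the synthetic
data the tests run on, and the numerical choices made where the design was
genuinely open.

## Signal model and preprocessing

**EEG.** Recordings arrive as channels × samples at any rate; if above the
working rate of 200 Hz they are polyphase-resampled (Kaiser-windowed FIR
anti-aliasing) with event onsets rescaled to the nearest sample, ties
toward zero. A 0.1–50 Hz 6th-order Butterworth band-pass removes DC drift
and line noise. "Zero-phase" throughout means the 6th-order design applied
forward–backward, i.e. a 12th-order effective magnitude response with no
group delay; all IIR filtering uses second-order sections because a
direct-form 6th-order filter with a 0.1 Hz edge at 200 Hz is numerically
unstable. Ocular artifacts are removed by a pluggable strategy whose
default regresses every EEG channel on the EOG reference(s) and keeps the
residual; the interface accepts any `(eeg, eog) -> cleaned` callable so an
ICA/BSS variant can be dropped in. Epochs span −5 to 25 s around each task
onset (half-open windows; sample *k* covers [k/rate, (k+1)/rate)).

**NIRS.** Optical-density changes at 780/805/830 nm are converted per
source–detector pair to chromophore concentration changes through the
modified Beer–Lambert law with the fixed 2×3 coefficient matrix

    (ΔHbR)   ( 1.8545  −0.2394  −1.0947) (ΔOD780)
    (ΔHbO) = (−1.4887   0.5970   1.4847) (ΔOD805)   [mM·cm]
                                         (ΔOD830)

assuming unit pathlength (no differential pathlength factor), so outputs
are concentration × pathlength in mM·cm. The chromophore order (HbR, HbO)
is fixed package-wide to prevent silent channel swaps. A 0.01–0.09 Hz
6th-order zero-phase band-pass removes cardiac (~1.1 Hz), respiratory
(~0.25 Hz) and Mayer-wave (~0.1 Hz) oscillations; it is applied to the
continuous record before epoching, with generous reflective padding,
because a 0.01 Hz edge on 30 s segments would be transient-dominated.
Epoching at 13.3 Hz uses half-open windows with floor rounding (a 30 s
epoch is exactly 399 samples); each trial, channel and chromophore is
baseline-corrected by subtracting its own −1..0 s mean.

## Features

**EEG — filter-bank CSP.** Within each band of a θ (4–8), α (8–13),
β (13–30 Hz) filter bank, common spatial patterns solves the generalized
eigenproblem `C_A w = λ (C_A + C_B) w` on the two class-mean covariances of
the 0–10 s task window. Per-trial covariances are trace-normalized before
averaging (scale-robustness; standard CSP practice), and the composite
covariance receives a relative ridge of 1e−10 × mean diagonal to guard the
rank deficiency that EOG regression can introduce. The eigenvalue
λ ∈ [0, 1] is the class-A variance fraction of its component and serves as
the selection score; the first three and last three components by score
are kept. Filters are sign-normalized so the largest-magnitude coefficient
is positive (log-variance is sign-invariant; the convention makes outputs
deterministic). Features are the log task-window variances of the 6 kept
components × 3 bands = 18 per trial and binary problem.

**NIRS — temporal means.** Per channel and chromophore, the mean of the
baseline-corrected trace over 5–10 s and 10–15 s (the hemodynamic response
peaks ~6 s after onset and outlasts the task): 16 × 2 × 2 = 64 features,
ordered channel-major, then chromophore, then window. Slope/variance
descriptors are deliberately not provided.

## Classification

The ternary problem is decomposed one-versus-one into MA-vs-MI, MA-vs-IS
and MI-vs-IS. Each binary problem has an EEG base classifier, a NIRS base
classifier, and a meta-classifier, all shrinkage LDAs: the empirical
covariance S is replaced by `(1−λ)S + λνI` with λ the analytic
Schäfer–Strimmer/Ledoit–Wolf intensity (clipped to [0, 1]) and ν the mean
diagonal of S. The ν-scaled target keeps the regularizer on the data's own
scale and reduces to the plain identity target for standardized features;
a literal `λI` mode is available behind `shrinkage_identity_literal`. The
discriminant is `w = Σ_λ⁻¹(μ₊ − μ₋)` with the bias placing the boundary
midway between projected class means; decision values are signed and
continuous.

The meta-classifier is a 2-input sLDA on the stacked (EEG, NIRS) decision
values, each standardized by its training spread so neither modality
dominates by raw magnitude. Its training inputs come from a 5-fold inner
cross-validation within the training fold — base CSP filters and sLDAs are
refit on every inner split — so the meta stage never sees
resubstitution-optimistic decisions, which would otherwise bias stacking
toward the overfit modality.

The final label is the majority over the three binary votes; the 1-1-1
cycle is broken by the largest absolute decision value, with remaining
ties falling back to the fixed problem order (deterministic).

Evaluation is a repeated, label-stratified k-fold cross-validation
(default 10 repetitions × 10 folds; with 30 trials per class each fold
tests exactly 3 trials per class). EEG-only and NIRS-only results vote on
raw base decisions without the meta stage; the hybrid votes on meta
decisions. Nothing computed from test trials enters any fitted parameter.
For speed, per-trial band-filtered task-window covariances and the NIRS
feature matrix are computed once per session and reused across folds —
these are per-trial statistics; training-set averaging still happens
strictly within each training fold, so the leakage contract is unchanged
(and the label-permutation canary in the test suite checks it).

## Metrics

The information transfer rate is the Wolpaw bit rate
`ITR = 60/τ · [log₂N + p·log₂p + (1−p)·log₂((1−p)/(N−1))]` bits/min, with
`p log₂ p := 0` at p = 0; it is zero at chance and log₂N bits per trial at
p = 1. τ is always explicit — the package does not presume whether a
"trial" is the 10 s task or the full ~28 s cycle. ERSP maps use a
short-time Fourier transform (1 s Hann window, 90 % overlap; the estimator
is pluggable), average power over trials and a channel group, and express
it per frequency in dB relative to the mean power in the −4..−3 s
baseline window.

## Synthetic sessions

No per-trial human recordings are available to this package, so the
simulator generates the study conditions directly: 30 trials per class in
one globally permuted order, 10 s tasks, onsets separated by 16–18 s
uniform breaks, 21 EEG channels (10 frontal, 11 central) + 1 EOG at
200 Hz, 16 frontal NIRS channels at 13.3 Hz. EEG is 1/f background plus
band-limited θ/α/β oscillations; class effects are multiplicative
band-amplitude factors per region with 0.5 s cosine ramps (MI: central
α/β attenuation, modeling ERD; MA: frontal θ increase with mild α
decrease; IS: none). Blinks are Gaussian-shaped transients on the EOG
channel leaking into frontal channels with fixed gains. NIRS hemodynamics
convolve the task boxcar with a double-gamma response (peak 6 s,
undershoot 16 s, HbO:HbR amplitude 3:−1) and add Mayer/respiratory/cardiac
sinusoids, white noise, and band-limited 0.004–0.09 Hz baseline drift;
per-trial response amplitudes scatter log-normally. The (HbR, HbO) pair is
encoded into three OD traces through the Moore–Penrose right-inverse of
the MBLL matrix, so conversion recovers the constructed hemodynamics
exactly — a built-in consistency oracle.

EEG is generated directly at 200 Hz (the working rate); higher-rate
generation exists only to exercise the downsampler. The default effect
sizes were chosen once to make the default subject *realistic* — ternary
accuracies in the mid-70s (EEG), high-50s (NIRS) and mid-80s (hybrid)
with the hybrid > EEG > NIRS ordering typical of this paradigm. Three
documented presets fix the conditions used by the acceptance suite:
`strong_effect_config` (high SNR; hybrid ≥ 90 %), `null_config` (no
class-conditional structure; decoding must sit in the 90-trial binomial
95 % band around 1/3, ≈ [0.24, 0.43]) and `complementary_config` (EEG
carries only the MI signature, NIRS only the MA response; neither
modality alone separates all three classes, so fusion must beat both).

What the simulator does **not** model: volume conduction and realistic
spatial mixing, photon-transport optics, subject-to-subject variability
beyond its config, non-stationary drifts in EEG, motion artifacts in
NIRS. Passing tests therefore demonstrate the correctness and
leakage-freedom of the pipeline under known ground truth, not expected
accuracy on human data.

## Problem sizes and runtime choices

Full-protocol runs (90 trials, 10 × 10-fold, 5-fold inner stacking)
complete in seconds thanks to the covariance caching above; the test
suite uses 2 repetitions where many sessions are decoded (the fusion
check averages 10 subjects) and the full 10 where a single subject's
protocol is the point. The acceptance script always runs the full
10 × 10-fold protocol.

## Known limitations

* The MBLL conversion is literal (unit pathlength); absolute concentration
  scaling is therefore conventional, which is irrelevant to classification
  but matters if values are compared against DPF-corrected pipelines.
* The regression EOG remover subtracts any genuine brain activity
  correlated with the EOG reference; the pluggable interface exists
  precisely so a BSS method can replace it.
* The "eigenvalue score" selection keeps fixed first/last component
  counts; mutual-information-based FBCSP variants are out of scope.
* Accuracy summaries treat repetitions as the unit of dispersion for the
  sd; with a single subject this understates between-subject variability
  by construction.
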