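# Methods

This note documents the models, estimators, conventions and numerical
choices behind `neuromse`, including the points where the design was
genuinely open and the package had to commit to one convention.

## Signals and artifact rejection

A recording is a uniformly sampled trace with a per-sample boolean validity
mask; time is measured in seconds since the hemorrhage (ictus), and
`monitoring_start` records the admission delay so the 48-h early-prediction
window can be defined against monitoring onset.  Rejected data is encoded
only through the mask — ICP can legitimately be negative, so sentinel
values are never used.  Cleaning is monotone (it only invalidates) and
therefore idempotent; rules run in a fixed order: manual annotations →
per-sample range rules → windowed spectral rules.

Windowed rules operate on non-overlapping 10-s sections aligned to the
recording start.  The section length is a package convention chosen to
match the downstream 10-s averaging grid.  Sections already less than half
valid are skipped, because periodograms of gap-ridden windows are not
trustworthy.  Two estimators drive the windowed rules:

* **Pulse amplitude** — peak-to-peak amplitude of the largest Fourier
  component within the cardiac band 0.67–3 Hz (40–180 bpm):
  `2 × (2|X_k|/n)`.  For a sinusoid at a bin-aligned frequency this equals
  the true peak-to-peak exactly, which makes the estimator testable in
  closed form.  A beat-detected max−min would be an alternative; the
  spectral estimator was chosen for determinism and robustness to missing
  beat detection.
* **Spectral edge frequency (SEF95)** — smallest frequency below which 95%
  of the power of the mean-subtracted window lies, from a single
  periodogram with the DC bin excluded.  No Welch averaging: 10-s windows
  are too short to segment further.

Thresholds (ABP range [0, 300] mmHg, 15 mmHg ABP pulse amplitude, ICP range
[−20, 200] mmHg, 0.04 mmHg ICP amplitude, SEF95 > 10 Hz) live in
`CleaningConfig` with these defaults.

## 10-s channels

Seven channels share one 10-s grid per patient: ABP/ICP window means, SBP
and DBP (mean of per-beat maxima/minima, beats delimited by the cardiac
fundamental period estimated from the window spectrum — deterministic and
exactly testable on sinusoidal beats, unlike peak detection), AMP (the same
spectral pulse-amplitude estimator applied to ICP), CPP = ABP − ICP where
both are valid, and HR (recorded channel if present, otherwise 60 × the
ABP cardiac fundamental; the recorded channel wins on disagreement).  A
window counts only if ≥ 50% of its samples survived cleaning (spectral
estimators require a fully valid window).  Patients without ICP monitoring
simply lack ICP/AMP/CPP; all downstream analyses are available-case per
metric.

## Multiscale entropy

Sample entropy uses m = 2 and tolerance r = 0.15 × SD of the patient's
scale-1 series, with one r reused at every scale (the standard multiscale
convention; an absolute-r mode exists).  Fixing r from scale 1 makes the
metric exactly invariant under affine rescaling of the input and produces
the characteristic decaying curve for white noise — for iid Gaussian data
the value at scale τ has the closed form −ln(2Φ(0.15·√(τ/2)) − 1), which
the tests exploit.

Templates are indexed 1…n−m for both the m- and (m+1)-length counts, pairs
i < j only, self-matches excluded; hence A ≤ B always, SampEn ≥ 0, and a
constant series scores exactly 0.  Scales 1–20 of the 10-s grid (10 s to
200 s blocks) cover the slow-wave band; the scalar summary is the
trapezoidal area under the entropy-versus-scale curve over unit-spaced
scale indices, reported only when every scale is defined.

**Gaps.**  Contiguous valid runs shorter than 60 windows (10 min) are
dropped; longer runs are coarse-grained per segment, and the A/B counts are
pooled across segments before the logarithm.  Pooling keeps short segments
from biasing the estimate the way averaging per-segment entropies would,
and templates never span a gap.  Whether entropy should be pooled over a
whole stay or computed per day and averaged is genuinely open; the package
computes it over the full cleaned stay by default, and the 48-h
early-prediction analysis is a window mode, not a separate code path.

The pair counter is an O(n²) kernel, JIT-compiled when numba is available,
with an exactly equivalent chunked-numpy fallback; both are checked against
a brute-force triple-loop oracle for identical integer counts.

## Outcome models

Unfavorable outcome is GOSE 1–4 (event = 1), so complexity metrics — which
are protective — carry odds ratios below 1 in every framework.  WFNS and
mFisher enter regressions as ordinal integers (keeping the
events-per-parameter ratio sensible at cohort sizes of a few hundred);
t-tests are Welch by default with a pooled-variance option; Tukey HSD
follows the one-way ANOVA across the four ordinal GOSE groups; the
Hosmer–Lemeshow test uses ten risk deciles (groups with zero expected
events are merged).  Raw p-values are reported without multiplicity
adjustment, consistent with an exploratory analysis.

Implemented here because no installed library provides them: DeLong
structural-component AUC variance (midrank formulation, logit-scale CI
clipped to [0, 1]), the paired DeLong comparison, the Harrell optimism
bootstrap (refit on each resample, evaluate on resample and original data,
corrected = apparent − mean excess; single-class resamples are redrawn),
the Brant–Wald proportional-odds test (per-cutoff binary logits, Wald
statistic on slope differences using the between-model covariance), and
the sliding dichotomy (baseline-covariate risk model → risk tertiles with
boundary ties assigned to the lower-risk group → favorable cut GOSE ≥ 7 /
≥ 5 / ≥ 3 by rising risk group → logistic regression of the adjusted
indicator on the metric alone).  Calibration intercept and slope come from
one joint logistic recalibration of the outcome on the frozen linear
predictor (ideal 0 and 1).  Logistic and proportional-odds fits themselves
go through statsmodels (Newton and BFGS respectively), cross-checked in
the tests against a Newton-from-zero oracle.

## Synthetic cohorts

The generator emulates what the study setting provides, with ground truth
at every stage:

* **Waveforms** — mean level + cardiac pulse (fundamental at the heart
  rate, default 70 bpm, plus a 30% second harmonic) + respiratory component
  (15 /min) + three slow waves in 0.005–0.05 Hz + 1/f^β Gaussian noise.
  Defaults (ABP 95 mmHg, pulse 40 mmHg; ICP 10 mmHg, pulse 2 mmHg) pass the
  cleaning rules by construction.  β is the complexity control: 0 = white,
  1 = pink, synthesized by exact spectral shaping of white noise with
  unit-variance normalization, so the periodogram slope is checkable.
* **Artifacts** — five classes matched to the rules (damped arterial
  trace, out-of-range spikes, ICP flatline, high-frequency noise bursts,
  drain-opening episodes recorded as manual annotations), injected on the
  10-s grid without overlap and returned with exact intervals for
  recall/precision scoring.
* **Clinical tables** — covariate marginals follow the derivation-cohort
  mix (age 58 ± 13, WFNS spread over all grades, two thirds high modified
  Fisher, 26% DCI, ICP monitored in 62%).  Each patient's latent MSE is
  computed by the production entropy module on their generated series;
  GOSE is then drawn from a latent-logistic proportional-odds model whose
  linear predictor combines covariate effects with the complexity effect
  (default log 0.8 per MSE-area unit), written out directly with its own
  logistic draws so the generator shares no statistical code with the
  analysis it tests.  Cutpoints are calibrated against a target marginal
  GOSE distribution (≈ 42% unfavorable) on a large reference draw, which
  also fixes the prevalence.  A `nonproportional_shift` switch adds
  cutoff-varying slopes to power the Brant test's alternative.  Event flags
  (rebleeding, edema, herniation, seizures, hydrocephalus, vasospasm) are
  Bernoulli with realistic base rates and an optional complexity link.

Defaults are 24-h records per patient.  Real stays run roughly ten times
longer; 24 h keeps a single cohort tractable while leaving scale-20
entropy well estimable for every β.  On records of only a few hours a
high-complexity (pink-like) patient can have an undefined scale-20 value
(no extended matches among the few coarse samples); the generator then
redraws that patient's series (logged), i.e. it conditions on a computable
complexity summary, mirroring a study's restriction to patients with
computable metrics.

**What the generator does not emulate:** nonstationarity over the stay
(interventions, complications, circadian structure), physiologic coupling
between channels beyond a shared complexity parameter, realistic vasospasm
dynamics, and measurement idiosyncrasies of specific monitors.  Passing
tests therefore demonstrate correctness of the estimators and the
statistical machinery under the stated generative model, not clinical
performance on real recordings.

## Problem sizes in tests

Simulation-based checks use scaled-down problem sizes chosen once:
parameter recovery runs 100 replicates of 300-patient cohorts with 4-h
series (plus pool-based replicates — patients drawing their MSE from a
precomputed entropy-module pool — for the 500-replicate coverage and
300-replicate null-coverage checks); calibration self-simulation uses
n = 5000; the Brant type-I rate uses 200 replicates at n = 400 and its
power 30 replicates at n = 2000.  Closed-form entropy checks average five
independent n = 10,000 realizations.

## Known limitations

* The spectral pulse-amplitude estimator reads the cardiac *fundamental*;
  for strongly non-sinusoidal pulses it understates the true max−min
  peak-to-peak by design.
* SampEn on short segments is biased upward at deep scales when matches
  are rare; the 60-window minimum segment length and the
  defined-at-all-scales requirement for the area summary are guards, not
  cures.
* The Wald CIs for the proportional-odds common OR assume the model holds;
  the bootstrap CI option is provided for smaller cohorts.
* The pipeline assumes one contiguous recording per patient file; multiple
  monitoring episodes must be concatenated with gap windows in between.
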