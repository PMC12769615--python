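# Methods

## The problem being modelled

A vocalizer produces two call types on cue across a training period: a
baseline call (BL) whose acoustics should stay put, and a conditioned call
(CD) shaped by operant conditioning to include cyclic mouth
opening/closing — which, under source-filter theory, modulates the vocal
tract's resonances (formants). The analysis asks three questions of the
formant contours F1–F3: do the two call types differ in formant placement
and variability; does CD's modulation *grow* over training days while BL's
does not; and does the growing difference make the two types increasingly
separable in a modulation-feature space.

## Synthetic data generator

The generator is the package's test bed: it produces contours whose ground
truth is known, so every downstream stage can be validated without
recordings.

Model per vocalization, per formant j:

    BL:  f_j(t) = c_j + e_j(t)
    CD:  f_j(t) = c_j + A_j(d) sin(2π r t + φ) + e_j(t)

with centers c = (504.4, 1513.2, 2522.1) Hz (quarter-wavelength tube,
L = 0.17 m, c = 343 m/s), modulation rate r = 4 Hz (the mouth-cycle rate;
dominant contour period 0.25 s), phase φ uniform per vocalization, and
AR(1) jitter e with marginal sd 30 Hz and lag-1 correlation ρ = 0.5.
The learning ramp is logistic in the training day d:

    A_j(d) = A_j^max / (1 + exp(−k (d − d_half)))

with d_half = 27 (mid-study of the 54 sampled days), k = 0.15/day, and
asymptotic amplitudes A^max = (150, 60, 120) Hz for (F1, F2, F3).

Why these numbers:

* **54 days, ≥3 s duration, 0.0125 s contour step** are the experimental
  conditions being emulated (the reinforcement minimum and the tracker's
  frame step at a 0.05 s window).
* **Jitter sd 30 Hz** makes a flat BL contour's CV ≈ 30/500 ≈ 0.06, in the
  middle of the empirically observed CV range for this kind of data.
* **A^max ordering F1 > F3 > F2** mirrors the finding that training
  diverges F1 and F3 most (the mouth cycle mostly moves the front cavity);
  the magnitudes put late-training CD modulation depth in the tens of
  Hz/step, the scale reported for real contours (median ≈ 18, max ≈ 118
  Hz/step).
* **AR(1) rather than white jitter** keeps adjacent-point transitions
  realistically small, so the jump filter's 95th-percentile threshold is
  non-degenerate. ρ is configurable.
* **~10 vocalizations per type per sampled day** reproduces the overall
  yield of the emulated experiment (~1100 vocalizations over 54 days).

Artifacts: with probability `edge_spike_prob`, points in the first/last 5%
of a contour get a ±600 Hz excursion (poorly tracked onsets/offsets); a
fraction `misassign_frac` of time points (2–10% in the robustness
simulation) has its (F1, F2, F3) triple replaced by a uniformly drawn
*non-identity* permutation — so "fraction corrupted" means exactly what it
says. A pristine copy travels with every synthetic contour.

The audio route renders contours as an impulse (or sawtooth) train through
a cascade of time-varying two-pole resonators with fixed bandwidths
(80/120/160 Hz). What the generator does **not** model: amplitude
envelopes, harmonic source structure beyond f0, nonstationary noise,
reverberation, or physiologically detailed articulation. Passing tests
therefore demonstrate correctness of the *analysis chain*, not robustness
to every field-recording pathology.

## Formant tracking

Praat-style pipeline: Hann stop-band filter above the 3 kHz ceiling
(raised-cosine transition of ±50 Hz, implemented in the frequency domain),
FFT resampling to 2× the ceiling, pre-emphasis with coefficient
exp(−2π·50/fs), Gaussian-windowed frames of 0.05 s every 0.0125 s, Burg
AR estimation, polynomial root-solving to (frequency, bandwidth)
candidates, ascending assignment to F1..F3.

Numerical choices that matter:

* **FFT (brick-wall) resampling**: a polyphase anti-alias filter's
  transition band attenuates the F3 peak near the new Nyquist and biases
  its pole estimate low by >100 Hz.
* **Pole budget**: the default is a 5-candidate search (order 10), with
  candidates broader than 400 Hz bandwidth rejected before taking the
  lowest three. A strict six-pole fit (`n_candidate_formants=3`) is
  available, but on resampled audio it must also model decimation zeros
  and residual spectral tilt, which biases F3 beyond the ±50 Hz recovery
  budget; the order-10 fit absorbs those into wide-bandwidth poles. This
  matches the common tracker default of searching five formants under a
  given ceiling.
* Candidates below 50 Hz or above the ceiling are dropped; roots within
  50 Hz of each other merge, keeping the lower bandwidth.
* Constant/silent frames are degenerate: they yield missing values, never
  fabricated formants.

No Viterbi-style track smoothing is applied: the QC stage, not the
tracker, handles outliers.

## Outlier QC

Stage 1 — *tail trim*: per formant, pooled over the entire dataset (a
single dataset-wide pair of cutoffs, not per-vocalization), values in the
lower/upper 2.5% quantile tails become missing. Quantiles use linear
interpolation.

Stage 2 — *jump filter*: per formant, the absolute transition between
adjacent surviving points is pooled across the dataset; the 95th
percentile becomes the cutoff, and the **second** point of each offending
pair is removed in a sequential per-contour scan. Sequential matters: once
a spike is removed, the pair it formed with its successor no longer exists
(gaps are never re-bridged), so an isolated spike costs one point. Fixed
Hz cutoffs can be supplied instead of the percentile.

Removed points stay as missing values in place, keeping downstream window
bookkeeping explicit. Both filters accept a frozen report of previously
computed thresholds, under which they are idempotent.

The *robustness simulation* corrupts pristine contours at shuffle levels
2–10%, applies the two filters **with thresholds frozen from the pristine
data** — the question is how the procedure's dataset-derived cutoffs cope
with corruption — and reports the percentage deviation of each formant's
mean from truth before and after QC. On the package's default synthetic
conditions the post-QC deviation is ~0.01%, far inside the 1% budget;
re-estimating percentile thresholds on heavily corrupted data instead
would inflate the jump cutoff into the contaminant range and leave
percent-level residuals at the 8–10% corruption levels.

## Modulation metrics

* **CV** = sample sd (n−1) / mean of the surviving points; dimensionless.
* **MD** = |f_{k+1} − f_k| between *adjacent* surviving samples (0.0125 s
  apart); pairs spanning a QC gap are excluded, never bridged. Hz per step.
* **SE**: sliding 40-point (0.5 s) windows every 20 points (50% overlap).
  Per window: interior missing points are linearly interpolated unless
  more than 25% are missing (window skipped); mean subtraction; a single
  rectangular-taper periodogram (no Welch averaging — the window is only
  40 points); DC bin dropped; remaining bin powers normalized to sum to 1;
  H = −Σ p log₂ p, in bits, bounded by log₂(20) ≈ 4.32. A window with
  numerically zero power scores 0. Contours shorter than one window yield
  a single value over all available points. Entropy is in **bits** —
  with 40-point windows the observable range then spans up to ~4.3,
  consistent with reported entropy ranges for this construction, which
  exceed the natural-log ceiling ln(21) ≈ 3.0.
* **Dominant period**: Morlet (cmor1.5-1.0) continuous wavelet transform
  of the mean-subtracted contour on 64 logarithmic scales spanning periods
  from 2·dt to the contour duration; the period of maximum time-averaged
  power. Undefined (NaN) on constant contours. Its role is to validate
  the 0.5 s entropy window: the window must cover at least one cycle of
  the dominant periodicity (0.25 s at 4 Hz).
* Per-vocalization summaries: CV plus the 25/50/75/100th percentiles of
  the MD and SE series per formant — nine numbers per formant, and 18
  classification features over F1 and F3.

The 0.0125 s step is used consistently for MD (one point per tracker
frame); the 40-point window times this step is exactly the 0.5 s window
the entropy analysis is built on.

## Longitudinal models

Responses are transformed with an ordered-quantile normalizing transform:
the i-th order statistic maps to Φ⁻¹((i − 0.5)/n), ties get averaged
scores, new values interpolate linearly (linear extrapolation outside the
training range). The transform is applied directly, without a
cross-validated selection among alternative normalizers.

Models are Gaussian linear mixed models (statsmodels `MixedLM`, maximum
likelihood) with fixed effects `formant * vocal_type * day` (or the
two-factor version for single-formant responses) and a random intercept:
per vocalization for formant values and MD; per session for CV and SE,
which have one/few values per vocalization — an all-singleton grouping
makes the vocalization-level intercept unidentifiable, and such fits are
flagged singular and refit with the fallback grouping.

Inference: (1) likelihood-ratio test of the full fixed structure against
the random-intercept-only null (χ² with df = number of fixed terms
dropped); (2) backward removal of the highest-order interaction block when
its joint Wald test has p ≥ 0.05 (α fixed at 0.05); (3) per-vocal-type day
slopes by the estimated-marginal-trends construction — the design-matrix
difference X(day+1) − X(day) averaged over the levels of the remaining
factors, exact for models linear in day — with delta-method standard
errors and a Wald z contrast (equivalent to a Tukey comparison for two
groups). Coefficient p-values are Wald z; Satterthwaite degrees of freedom
are not attempted.

## Classification

Complete-case 18-feature rows are split into epochs by the quartiles of
the sampled-day list: start = first quartile, end = fourth; the middle
half is not used. Features are z-scored before embedding (they mix
dimensionless CVs, Hz and bits); UMAP (2 components, fixed seed,
n_neighbors shrunk automatically for small samples) is fit independently
per epoch, as each epoch gets its own classifier. The random forest uses
800 trees and a stratified 70/30 split; OOB error and per-class errors
come from the training forest, ROC/AUC from held-out P(BL) scores. AUC is
computed as the Mann–Whitney pairwise statistic (identical to the
trapezoidal ROC area). The DeLong comparison is the unpaired variant —
start and end contain disjoint vocalizations — with
D = (AUC₁ − AUC₂)/√(v₁ + v₂) from placement-value variances and a
two-sided t reference with Welch–Satterthwaite df. BL is scored as the
positive class; sensitivity is BL recall, specificity CD recall, balanced
accuracy their mean.

## Problem sizes in the test suite

The suite verifies statistical properties at sizes chosen to keep the
whole run desk-scale while retaining power: Monte-Carlo means use 40–200
replicates; mixed-model coverage and type-I checks use 40 and 100
simulated fits with binomial acceptance bands; the end-to-end divergence
property runs 50 seeded replicates of a compact experiment (16 sampled
days spanning days 1–54 at the default 10 vocalizations/day/type) and
requires the full learning signature — MD up and SE down for CD relative
to BL, and end-epoch AUC above start-epoch AUC with DeLong p < 0.05 — in
at least 90% of replicates.

## Known limitations

* The tracker has no formant-path optimization; crossing or closely
  spaced formants can swap assignments (exactly the artifact the QC stage
  and the misassignment simulation address).
* `MixedLM` fits only random intercepts here; random slopes are out of
  scope.
* The DeLong df formula follows the Welch–Satterthwaite form on the two
  curve variances; other implementations differ slightly in small samples.
* UMAP determinism holds for a fixed seed, library version and thread
  count (n_jobs is pinned to 1).
* The generator's BL drift term defaults to zero: unintended baseline
  changes exist in real data but have no principled parameterization.
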