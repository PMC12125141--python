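# Methods

## Scope and data model

`pshrisk` models the risk of paroxysmal sympathetic hyperactivity (PSH)
after traumatic brain injury from 72-hour multimodal neuromonitoring
trends. The unit of analysis is a patient record of five channels on a
shared 60-s grid — mean arterial pressure ABP [mmHg], heart rate HR
[bpm], baroreflex sensitivity BRS [ms/mmHg], intracranial pressure ICP
[mmHg] and the pressure reactivity index PRx [−1..1] — together with a
clinical-metadata row and a binary at-risk label. Timestamps are seconds
from monitoring start; each sample is labeled by the start of its
interval (0-based, half-open), which fixes all window arithmetic.
Missingness is always explicit (NaN / empty CSV cell), never dropped.

## Preprocessing and quality control

Interior gaps of at most 10 consecutive trend samples (10 min) are
filled by linear interpolation; longer runs and runs touching a record
boundary stay missing. A record is usable when it covers 72 h and every
channel's residual missing fraction after interpolation is ≤ 10%; any
channel failing the rule fails the record. The QC report records both
the per-channel fractions and the decision, and the rule is applied
*after* interpolation — the alternative (before) is stricter, and the
choice is surfaced in the report rather than hidden.

## Waveform-derived indices

When raw 200-Hz ABP/ICP waveforms are available the trend channels are
derived as follows.

* **HR** — the first cardiac harmonic of a detrended, Hann-windowed
  60-s ABP segment, searched in 0.67–2.33 Hz (40–140 bpm). The estimate
  is rejected (missing) when the in-band peak is below 5× the median
  in-band magnitude or below 20% of the global non-DC peak; the second
  gate protects against spectral leakage from a strong out-of-band
  component such as respiration.
* **Beats** — systolic peaks by local-maximum detection with a 0.25-s
  refractory period and prominence ≥ 30% of the signal's peak-to-peak
  range (both configurable; nothing in the problem fixes them).
* **BRS** — the time-domain cross-correlation method: beat-wise systolic
  pressure and interbeat interval are resampled to a 1-s grid; over each
  10-s segment the correlation between IBI and SBP delayed by 0–5 s
  (integer lags) is maximized, and the regression slope of IBI on SBP at
  the best lag is the segment estimate. Segments whose best correlation
  is not positive are discarded as physiologically uninterpretable (the
  baroreflex is a positive SBP→IBI coupling); a significance gate on the
  correlation is deliberately off by default. Segment slopes are
  averaged into 60-s trend bins.
* **PRx** — both pressures are reduced to 10-s means (slow-wave
  filtering) and PRx is the Pearson correlation of the 30 most recent
  means — a 5-min window updated every 10 s — then averaged onto the
  60-s grid. Being a correlation it is invariant to positive affine
  rescaling of either channel and flips sign under negative scaling.
* **Trend averaging** — non-overlapping 60-s means; a bin with more than
  50% missing source samples is missing.

## Transient features

For each of the six ANS×hemodynamics pairs, a rolling Pearson
correlation is computed over a window of W ∈ {3, 6, 12, 24} h, stepping
one 60-s sample, using pairwise-complete samples, gated at ≥ 90% window
completeness (the record-level 10% rule mirrored at window scale) and at
non-degenerate variance. Values are labeled by window start, so only
windows fully inside the record exist. Numerically the correlation uses
cumulative window moments after centering each channel by its global
mean — the centering is analytically neutral but keeps the cumulative
sums well conditioned; the implementation agrees with a naive
per-window correlation to 1e-12.

The 72-h axis is then divided into ⌈72/W⌉ consecutive bins of length W
and, within each bin, three metrics summarize the correlation values
whose window start falls in the bin: MEAN, sample STD, and the
zero-crossing rate

    ZCR = 1/(N−1) Σ |sgn(corr[n]) − sgn(corr[n−1])|,  sgn(0) = 0,

applied literally (a zero touch contributes 1 per adjacent pair; range
[0, 2]; missing values are dropped before pairing). Bins with fewer than
two defined values — always including the last bin, whose windows would
extend past 72 h — yield missing features, left for fold-local
imputation at model time. The two-level windowing (correlation window
*and* aggregation bin both of length W) is a recorded design decision:
it yields time-indexed features (24 bins at W = 3 h), which the temporal
importance profile requires; a single aggregate per pair would not.

## Feature sets and the group comparison

Level I: 13 metadata columns (age, sex, GCS sum, ISS, trauma type, Hb,
WBC, six CT-lesion flags, flags encoded 0/1). Level II adds the five
72-h channel means (missing excluded, after interpolation). Level III
adds one metric × one window of transient features: 6 pairs × ⌈72/W⌉
bins named `metric_ans_hemo_wW_bNN`, 162 columns total for (ZCR, 3 h).
Matrices nest exactly and column order is deterministic. The cohort
table comparison uses the two-sided Mann–Whitney U test for numeric
variables (exact null distribution when there are no ties) and Fisher's
exact test for flags, α = 0.05.

## Risk model

L2-penalized logistic regression with stratified five-fold
cross-validation (per-fold class counts differ by at most one), over the
grid of regularization strengths {2N, N, 1, 1/N, 1/(2N)} — interpreted
as the *inverse* penalty weight (sklearn's `C`), the only convention
under which the reference best values N and 2N for a 41-patient cohort
are coherent — crossed with balanced/unbalanced class weighting. N is
the full-cohort instance count, not the training-fold size. Inside each
training fold, and only there, missing values are imputed by the
training medians and features are z-scored; the accuracy threshold is
0.5 on predicted probability. The best configuration maximizes mean
AUC; ties prefer the stronger penalty, then balanced weighting.

## Interpretability

Importance is the absolute regression coefficient per feature per fold
(meaningful across features because fitting standardizes). The additive
attribution of feature j for instance i is the exact linear-model
Shapley value `coef_j · (x_ij − background_j)` with the training-fold
feature means as background; attributions plus the base value
reconstruct the linear predictor to machine precision. Both views are
aggregated as the sum of absolute values across folds (and validation
instances), then min–max rescaled to [0, 1]; an all-equal aggregate is
degenerate and reported as zeros with a warning. The temporal profile
averages normalized importance across the six pairs per time bin; the
influential span is the set of bins *strictly* exceeding the mean of the
per-bin values, so a flat profile has an empty span.

## Synthetic cohort

The generator defines the package's study conditions; it emulates the
statistical structure the analysis assumes, not any patient's
physiology.

* **Metadata** — log-normal for skewed variables (age, WBC), normal for
  Hb, discrete uniform over the printed interquartile range for ordinal
  scores (GCS 4–8, ISS 20–34), Bernoulli flags, all matched to the
  reference cohort's published medians/IQRs and rates. Only WBC is
  group-dependent (medians 20.3 vs 14.2 ×10³/µl): it was the one
  metadata variable with a significant group difference, and treating
  the remaining per-group spreads as population structure would
  overstate the metadata-only model.
* **Trends** — each channel is a patient-level baseline (between-patient
  sd) plus unit-variance fluctuations (within-record sd) built from
  shared latent drivers: every pair carries a latent standard-normal
  process z with weight √c on both channels (c = 0.3), the hemodynamic
  side multiplied by a ±1 sign that switches as a Poisson process. The
  short-horizon correlation of a pair therefore tracks sign·c. The
  baseline switch rate is 0 — coupling direction is treated as stable
  over a stationary 72-h record — and the injected at-risk effect is a
  rate of 20 switches/hour for HR–ICP and HR–PRx during the first
  three hours. The rate follows from the recovery requirement: the
  number of zero crossings of a W-long rolling correlation inside one
  W-bin scales as √(2λW)/π, so λ = 20/h yields roughly two crossings in
  bin 0 while slower switching leaves most at-risk records without any.
  PRx values are clipped to [−1, 1]. Ground-truth switch times are kept
  on the record.
* **Gaps** — missing runs (default 3% of samples in runs of 2–8) are
  punched into every channel; explicit run-length specs support QC
  testing. An empty spec is the identity.
* **Waveforms** — ABP is a baseline plus a zero-mean three-harmonic
  pulse train, respiratory (0.25 Hz) and Mayer (0.1 Hz) sinusoids, a
  band-limited (0.005–0.05 Hz) slow component and white noise; beat
  timing responds to the lagged systolic modulation with the configured
  baroreflex gain and delay, and ICP shares the slow component scaled by
  the coupling coefficient. The record stores the exact lagged drive
  each interbeat interval responded to, making the gain relation
  verifiable by direct least squares.

Everything is deterministic given the cohort seed (per-patient streams
are spawned from it), and different seeds change noise, metadata draws
and gap placement.

What the generator does **not** emulate: artifacts and sensor dropouts
with structure, nonstationary baselines (drug titration, ICP crises),
autocorrelated within-channel dynamics beyond the latent coupling,
arrhythmias, and any feedback between channels beyond the pairwise sign
model. Passing tests therefore demonstrate that the pipeline recovers
the *kind* of effect it is designed for under controlled conditions —
not that the effect exists, or is recoverable, in real monitoring data.

## Problem sizes and numerical choices

The simulation studies use 41-patient cohorts (14 at risk) for effect
recovery and 200-patient cohorts for the permutation-null calibration
of the grid search — the null's headline statistic is a maximum over
ten cross-validated configuration means, which sits near 0.55 with
seed-level spread ~0.05 under the null, so calibration is asserted on
the across-seed mean. Correlation windows of zero variance and bins
with fewer than two values propagate as missing rather than silent
zeros; entirely-missing feature columns are imputed to 0 and end up
with zero coefficients (recorded per fold). The logistic solver runs at
tolerance 1e-8, matching an independent penalized-likelihood optimizer
to ~1e-6 on the coefficients.

## Known limitations

Hyperparameters are selected on the same folds used to report
performance (no nesting), as in the reference design; the reported best
AUC is therefore optimistically biased, which is exactly what the
permutation-null study quantifies. PSH labels are an input — the
assessment scale itself is out of scope. Real-data idiosyncrasies
(artifact structure, treatment effects, nonstationarity) are untested by
construction.
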