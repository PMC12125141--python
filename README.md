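# pshrisk

Modeling the risk of **paroxysmal sympathetic hyperactivity (PSH)** after
traumatic brain injury from *transients* in the coupling between
autonomic-nervous-system (ANS) activity and cerebral hemodynamics.

PSH is an episodic sympathetic storm syndrome (tachycardia, hypertension,
hyperthermia, sweating, posturing) that typically declares itself one to
two weeks after severe TBI, while the physiological groundwork appears to
be laid much earlier. `pshrisk` implements a pipeline that asks whether
the *stability* of the relationship between ANS metrics — heart rate
(HR), mean arterial pressure (ABP), baroreflex sensitivity (BRS) — and
cerebral hemodynamics — intracranial pressure (ICP), pressure reactivity
index (PRx) — during the first 72 h of neuromonitoring carries early
predictive information, for researchers working with multimodal
neurocritical-care trend data.

## Method

For each signal pair (ANS × hemodynamics, six pairs), a rolling Pearson
correlation `corr[n]` is computed on the 60-s trend grid over a sliding
window of W ∈ {3, 6, 12, 24} h, stepping one sample. Within consecutive
W-long time bins, three variability metrics summarize the track: the
mean (MEAN), the sample standard deviation (STD), and the
**zero-crossing rate**

    ZCR = 1/(N−1) · Σₙ |sgn(corr[n]) − sgn(corr[n−1])| ∈ [0, 2],

which counts how often the coupling *changes direction*. These transient
features augment two nested baselines:

* **level I** — clinical metadata (age, sex, GCS, ISS, trauma type, Hb,
  WBC, six admission-CT lesion flags; 13 features),
* **level II** — level I + the five 72-h neuromonitoring means,
* **level III** — level II + one variability metric per pair per bin.

A logistic-regression risk model is evaluated by stratified five-fold
cross-validation over a grid of L2 regularization strengths
{2N, N, 1, 1/N, 1/(2N)} (inverse penalty weight, N = cohort size) ×
{balanced, unbalanced} class weighting, reporting mean ± sd AUC and
accuracy. Feature importance (|coefficients|) and exact additive
attributions for the linear model are aggregated across folds, min–max
normalized, and projected onto the time axis to find the most
influential monitoring period.

Because no patient monitoring data can ship with the package, a
first-class synthetic cohort generator produces 41-patient cohorts (14
at risk) with matched metadata distributions and trend signals whose
pairwise coupling sign follows a latent Poisson switching process — the
at-risk group switches faster, concentrated in the first three hours.
Raw 200-Hz ABP/ICP waveform segments with known cardiac frequency,
baroreflex gain/delay and slow-wave coupling close the loop on the HR,
BRS and PRx estimators.

## Worked example

```python
from pshrisk import synthetic
from pshrisk.features import build_feature_set, transient_feature_table
from pshrisk.model import ModelConfig, grid_search_cv

meta, records = synthetic.gen_cohort(synthetic.CohortParams(seed=1))
transient = transient_feature_table(records, window_hours=3.0)
fm1 = build_feature_set(1, meta)
fm3 = build_feature_set(3, meta, records=records,
                        transient_features=transient,
                        metric="zcr", window_hours=3.0)
for fm in (fm1, fm3):
    rep = grid_search_cv(fm, ModelConfig(seed=1))
    print(f"level {fm.level}: AUC {rep.best.mean_auc:.2f} ± {rep.best.sd_auc:.2f}"
          f"  (C={rep.best_strength:g}, {rep.best_weighting})")
```

prints

```
level 1: AUC 0.82 ± 0.11  (C=0.0243902, balanced)
level 3: AUC 0.97 ± 0.07  (C=0.0243902, unbalanced)
```

— the metadata-only model is driven by the white-blood-cell count alone
(this seed draws a fairly separable cohort; averaged over cohorts it
sits near 0.63), while adding the 3-h ZCR transients recovers the
coupling instability injected into the at-risk group's first three
hours and lifts the cross-validated AUC consistently — 0.83 on average
over cohorts, beating level I in over 90% of them (see
`scripts/acceptance.py` below).

The same run from a shell:

```bash
pshrisk run-all --out run --seed 1
```

writes trend CSVs, the QC report, transient features, feature matrices,
the CV report (JSON), importance tables and the temporal profile, plus
a manifest; `pshrisk --help` lists the stage-by-stage subcommands
(`simulate`, `qc`, `derive`, `transients`, `features`, `fit`, `explain`).

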