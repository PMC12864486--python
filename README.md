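# eegmci

Longitudinal resting-state EEG features and machine learning for predicting
one-year progression from amnestic mild cognitive impairment (aMCI) to
Alzheimer's disease.

## The problem

aMCI is the earliest clinically detectable stage on the path to AD; roughly
10–15% of patients convert per year. Cross-sectional EEG markers of
"slowing" (power shifting from alpha/beta into delta/theta), reduced signal
complexity, and alpha-band disconnection overlap heavily between converters
and non-converters. The idea implemented here is to measure each patient
repeatedly — four visits at four-month intervals — extract cross-sectional
EEG features at the first three visits, summarize each feature's *trajectory*
with trend descriptors, and feed those longitudinal features to classifiers
that predict the visit-4 outcome (progressive, PMCI, vs stable, SMCI).

Because the underlying clinical recordings are not public, the package ships
a synthetic cohort generator that reproduces the study's group × time
statistical structure (group differences negligible at visits 1–2, pronounced
at 3–4), so the entire pipeline is testable and reproducible end to end.

## What is computed

Per 30 s, 16-channel recording (10–20 montage, 250 Hz), after common-average
referencing, 0.1–70 Hz zero-phase FIR band-pass, 50 Hz notch, downsampling
and segment selection — 328 features:

* **Spectral (160).** Welch PSD (2 s Hann, 50% overlap); band powers over
  δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz; the five slowing ratios
  per channel: `Ratio1 = δ/α`, `Ratio2 = θ/α`, `Ratio3 = δ/(α+β)`,
  `Ratio4 = θ/(α+β)`, `Ratio5 = (δ+θ)/(α+β+γ)`; and the within-band PSD
  entropy `E = −Σ p_i ln p_i` with `p_i` the normalized PSD bins.
* **Nonlinear (48).** Permutation entropy (m = 3, τ = 1, normalized by
  ln m!); sample entropy (m = 2, r = 0.2 SD, Chebyshev distance,
  SE = −ln(A/B)); and M-DCPSR — the median Euclidean distance of 3-D
  delay-embedded points from their centroid, with the delay taken from the
  first zero crossing of the autocorrelation function.
* **Connectivity (120).** Alpha-band phase lag index for every channel pair:
  `PLI = |⟨sign sin(φ_x − φ_y)⟩|`, 0 for no consistent lag, 1 for perfect
  locking at a lag different from 0 or π.

Each feature trajectory `X(t)` over visits 1–3 (months 0, 4, 8) yields six
trend descriptors — mean (MF), SD (SDF), range (RF), trapezoidal area under
the trajectory (AF), and mean/SD of the interval velocities (MVF, SDVF) —
for 6 × 328 = 1,968 longitudinal features per subject.

Classification uses stratified 10 × 5-fold cross-validation of eight
classifiers (SVM, decision tree, Gaussian NB, LDA, AdaBoost, 1-NN, random
forest, logistic regression). Inside every training phase the features are
standardized and the top 100 by ANOVA F-statistic retained, so no statistic
ever sees test rows. Metrics (ACC, SEN, SPE, PPV, F1, rank-formula AUC, with
PMCI as the positive class) are aggregated over the 50 evaluation folds.

## Worked example

```python
import numpy as np
from eegmci import (EffectSchedule, generate_cohort, preprocess_epoch,
                    extract_features, longitudinal_stats)

cohort = generate_cohort(n_smci=2, n_pmci=2, timepoints=(1, 2, 3),
                         duration=30.0, seed=7)
epoch = preprocess_epoch(cohort.subjects[0].epochs[1])
features = extract_features(epoch)
print(len(features))                      # 328
print(round(features["Ratio2__O1"], 3))   # 0.538 — theta/alpha at O1
print(longitudinal_stats([1, 2, 4], (0, 4, 8)))
# {'MF': 2.3333..., 'SDF': 1.5275..., 'RF': 3.0, 'AF': 18.0,
#  'MVF': 0.375, 'SDVF': 0.1767...}
```

The trajectory (1, 2, 4) measured at months (0, 4, 8) has mean 2.33, sample
SD 1.53, range 3, area 18 (two trapezoids: 6 + 12), interval velocities
(0.25, 0.5) per month with mean 0.375 and SD 0.177.

The numbered scripts under `analysis/` run the whole study in order
(`01_simulate_cohort.py` → `05_classify.py`), writing tables under
`results/`; the `eegmci` CLI exposes the same stages
(`simulate`, `preprocess`, `features`, `longitudinal`, `classify`,
`compare`, `run`).

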