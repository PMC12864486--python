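# Methods

## Overview

The package implements a longitudinal EEG prediction framework: repeated
resting-state measurements of amnestic-MCI patients, cross-sectional feature
extraction at the first three of four equidistant visits, trend-feature
construction over those visits, and leakage-safe repeated cross-validated
classification of the one-year outcome (stable vs progressive MCI). Since the
underlying clinical recordings are private, a synthetic cohort generator
provides the data substrate; it is a first-class, tested component whose
defaults encode the study conditions.

## Synthetic cohort model

Each channel of a recording is a sum of independent parts:

1. **Band-limited stochastic components.** White noise is brick-wall filtered
   (FFT mask) into the five classical bands. Base relative amplitudes
   (δ 1.0, θ 0.8, α 1.3, β 0.55, γ 0.25) follow the usual eyes-closed
   resting-state profile; a mild anterior–posterior gradient makes alpha
   strongest occipitally and the slow bands slightly frontal. Within each
   band the noise is shaped as 1/f^χ; the exponent χ is a schedule parameter
   (see below).
2. **A shared alpha source** injected into every channel with a fixed,
   channel-specific phase rotation (offsets spaced so every pairwise
   difference lies strictly inside (0, π)), weighted by the coupling
   coefficient κ ∈ [0, 1]. The channel's independent alpha noise is weighted
   √(1−κ²), so κ = 0 gives independent channels (PLI near 0) and κ = 1 a
   pure lag-locked common source (PLI near 1).
3. **A deterministic quasi-periodic component** (two incommensurate
   theta-range tones, 5.2 and 7.6 Hz, with subject- and channel-specific
   phases), weighted by the regularity coefficient ρ ∈ [0, 1]. Raising ρ
   makes the signal more predictable, which lowers permutation and sample
   entropy *emergently* — entropy is never a fitted target.
4. **A pink-noise floor** (1/f, relative weight 0.25).

The output is scaled to ~20 µV RMS times a group × visit amplitude factor.
Subject heterogeneity enters as log-normal per-band and overall amplitude
random effects (σ = 0.15), a per-band tilt offset (σ = 0.2), and a small
per-epoch amplitude jitter (σ = 0.05); subject effects are constant across
visits, which is exactly what makes within-subject trend features
informative.

### Group × time schedule

The default `EffectSchedule` sets both groups identical at visits 1–2 and
diverges the progressive group at visits 3–4:

| parameter | SMCI (visits 1→4) | PMCI (visits 1→4) |
|---|---|---|
| δ, θ multipliers | 1, 1, ~1.1, ~1.2 | 1, 1, 1.35/1.5, 1.7/2.0 |
| α, β multipliers | 1, 1, ~0.97, ~0.94 | 1, 1, 0.75/0.85, 0.55/0.7 |
| in-band tilt χ (δ, θ) | 1.0/0.8 → mild drift | flattens to 0.3/0.2 (entropy ↑) |
| in-band tilt χ (α, β) | mild drift | steepens to 1.1/2.4 (entropy ↓) |
| α coupling κ | 0.6, 0.6, 0.55, 0.5 | 0.6, 0.6, 0.35, 0.2 |
| regularity ρ | 0.2, 0.2, 0.25, 0.3 | 0.2, 0.2, 0.6, 0.75 |
| amplitude scale | 1, 1, 0.95, 0.9 | 1, 1, 0.6, 0.45 |

These magnitudes are calibration choices (no effect sizes exist to copy);
they were set once so that the generated cohort reproduces the qualitative
structure the analysis assumes — essentially no separating features at visit
1, a large majority at visit 3, slowing ratios rising, complexity and
alpha-band PLI falling in the progressive group — and they are fully exposed
in configuration. `EffectSchedule.null()` removes all group and time effects
and is used for type-I and leakage calibration.

**What the generator does not emulate:** eye-blink/EMG artifacts (the manual
screening and ICA of clinical practice are out of scope), volume conduction
through a head model, per-band directional detail of gamma entropy, and
label noise. Synthetic cohorts are therefore *cleaner* than clinical data:
passing classification checks shows the pipeline recovers programmed
structure without leakage, not that clinical accuracy would be this high —
observed synthetic accuracies (≈95–100%) are upper bounds of that kind.

## Preprocessing

Order: common-average re-reference → zero-phase FIR band-pass (0.1–70 Hz) →
FIR notch (48–52 Hz) → polyphase downsampling to 250 Hz → fixed-length
segment selection. Filters are Hamming windowed-sinc designs applied
forward–backward; each edge's transition bandwidth is edge/5, realized as a
high-pass/low-pass cascade. The tap count is capped at one third of the
recording so the forward–backward pass is feasible; on 30 s recordings the
cap loosens only the 0.1 Hz edge, whose nominal design would need more taps
than samples. Filtering uses even-extension edge padding: the default odd
extension injects a DC step at the boundaries that very long high-pass
filters turn into large transients. The segment selector's default strategy
scans 1 s-spaced candidate windows and keeps the one with the smallest peak
amplitude — an automated stand-in for manual selection of clean background
rhythm. ICA, bad-channel interpolation and examiner-based rejection are
deliberately not implemented (human-in-the-loop steps).

## Feature definitions and numerical choices

* **Welch PSD:** 2 s Hann segments, 50% overlap → 0.5 Hz resolution at
  250 Hz, enough to resolve the 0.5 Hz delta edge. Band powers are Riemann
  sums over half-open bins lo ≤ f < hi, so shared band edges (4, 8, 13,
  30 Hz) are counted exactly once.
* **PSD entropy:** Shannon entropy of the normalized in-band PSD bins,
  natural log (configurable base), 0·log 0 ≡ 0; bounded by ln(N_bins).
* **Permutation entropy:** m = 3, τ = 1 by default (7,500 samples vastly
  exceed the 6 patterns); rank ties broken by temporal order (stable sort);
  normalized to [0, 1] by ln(m!).
* **Sample entropy:** m = 2, r = 0.2 × SD, strict Chebyshev "< r", unordered
  template pairs i ≠ j, both template lengths over the same N − m start
  indices. The O(N²) pair count runs in a numba kernel with early exit; an
  optional `se_window_s` knob averages SE over non-overlapping windows
  (pipeline runs use 10 s windows; the plain function default is the full
  series).
* **Delay estimation (for M-DCPSR):** biased FFT autocorrelation of the
  centered series; first lag j with R(j−1)·R(j) ≤ 0; the delay is then the
  side of the crossing with the *larger* |R| (τ = j when |R(j−1)| ≤ |R(j)|,
  else j−1). That comparison direction is kept as specified upstream even
  though choosing the nearer-zero side would be the more natural reading;
  a `delay_rule="nearest_zero"` switch provides the alternative. If no
  crossing occurs within lag ⌊N/2⌋, the fallback is fs/10 samples with a
  logged warning. Delays are estimated per channel per recording.
* **M-DCPSR:** 3-D embedding (x_n, x_{n+τ}, x_{n+2τ}), centroid, median
  Euclidean distance. Homogeneous of degree 1 in amplitude — the one feature
  here that tracks signal scale.
* **PLI:** alpha-band zero-phase FIR, Hilbert transform, 1 s trimmed per
  edge; PLI = |mean sign sin(Δφ)| with sign(0) contributing 0. A printed
  variant that folds |Δφ| into [0, 2π) before taking the sign is retained
  behind `method="folded_abs"` for audit only: it is provably non-negative
  and saturates near 1, contradicting the defining zero-lag behavior, so the
  standard signed form is the default.
* **Longitudinal descriptors:** measurement times 0/4/8 months, δt = 4. MVF
  and SDVF use the T−1 = 2 consecutive-interval velocities by default;
  `include_span_slope=True` adds the month-0→8 slope as a third velocity
  (note that for equidistant times the span slope equals the mean of the
  consecutive slopes, so the option changes SDVF only). AF is the
  two-trapezoid area between the first and last visit. The range descriptor
  is max − min. Subjects missing a visit are excluded (complete-case, with a
  logged warning).

## Modeling

Stratified 5-fold CV repeated 10 times (per-repeat seed = base seed +
repeat index), 50 evaluation folds, aggregated as mean ± SD over folds —
fold-level aggregation is used rather than repeat-mean aggregation, and the
report labels it. Inside each training phase: standardize on training rows,
rank all 1,968 features by two-group ANOVA F (ties broken by canonical
column order), keep the top 100, fit. Classifier configurations are pinned:
linear SVM (C = 1), CART/Gini tree, Gaussian NB, pooled-covariance LDA,
AdaBoost (100 depth-1 rounds), 1-NN Euclidean, random forest (100 trees,
√P features per split), unpenalized logistic regression. AUC scores are
predicted probabilities where available, otherwise signed decision values;
the AUC itself is the rank-sum formula with average ranks on ties (equal to
pair-counting with ties at ½). Fold metrics with empty denominators are
reported as undefined and excluded from averages with a count. Group
comparisons use the two-sided Mann–Whitney U per feature (exact for small
tie-free samples, normal approximation with tie correction otherwise),
uncorrected at α = 0.05 by default with an optional Benjamini–Hochberg flag.

## Problem sizes

Tests exercise a 12-subject, 8 s mini cohort end to end plus the full
65-subject, 30 s cohort for the cohort-structure checks (with 10 s sample-
entropy windows); `scripts/acceptance.py` runs the complete 65-subject study
design with 10 × 5-fold CV of all eight classifiers. These sizes are the
package's chosen desk-scale defaults; every stage accepts larger inputs.

## Known limitations

* EDF import/export is not provided; cohorts persist as an npz archive with
  a JSON sidecar and CSV manifest.
* The 0.1 Hz high-pass edge cannot reach its nominal transition bandwidth on
  30 s recordings (see the tap cap above); its effective transition is
  ~0.33 Hz there.
* No multiscale entropy, weighted PLI, graph metrics, linear mixed models,
  hyperparameter tuning or nested CV; these are outside the implemented
  design.
* Synthetic-cohort results quantify pipeline correctness, not clinical
  performance.
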