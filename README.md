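# tcmdetect

Detection of **typical compensatory movements (TCM)** versus **clinically
prescribed execution (CPE)** in three low-back-pain rehabilitation exercises
— Prone-Rocking, Bird-Dog and Bent-over Rowing — from three tri-axial
accelerometers mounted along the spine (L5/S1, Th1/C7, back of the head).

The package is aimed at researchers in wearable-sensor movement analysis and
rehabilitation engineering who want a fully reproducible, testable version
of this classification pipeline: because the original recordings are not
publicly deposited, a synthetic-data generator that emulates the study
design (30 subjects × 2 categories × 3 sets × 6 repetitions per exercise,
200 Hz, 12-bit quantization, push-button repetition markers) is a
first-class, tested part of the package.

## Method

1. **Segmentation & normalization** — each set is cut into repetitions at
   the push-button markers; every repetition is linearly resampled onto the
   time grid of the longest repetition of the set (100 % duration) and the
   six repetitions are averaged sample-wise into one 9-channel trace.
2. **Features** — per sensor the tilt angle against gravity

   φ = cos⁻¹( A_Z / √(A_X² + A_Y² + A_Z²) ),  φ ∈ [0°, 180°],

   and per channel the statistics aRMS, max, σ² (variance), skewness *s*
   and kurtosis *k* (population moments, raw kurtosis: normal → 3).
   Together with φRMS per sensor and the maxima of the signed tilt
   differences max(Δφ₁,₂) and max(Δφ₂,₃) this gives 50 features
   (16 in single-sensor mode). Every column is z-scored, z = (n − n̄)/σ.
3. **Feature selection** — wrapper forward selection: candidate subsets are
   scored by the misclassification loss of a CART tree under stratified
   5-fold cross-validation; the subset grows greedily until the loss stops
   improving, capped at 5 features (≤ N/2 for N = 36 observations per
   training process).
4. **Classifier** — a binary CART tree with Gini impurity
   G = 1 − Σₖ pₖ², split thresholds searched exhaustively over the
   midpoints of consecutive feature values, and a single stopping rule:
   each feature is used at most once per tree.
5. **Validation** — leave-one-subject-out (LOSO): every subject's sets are
   predicted by a tree trained on the other subjects only.

`GiniTreeClassifier` and `ForwardTreeSelector` are scikit-learn-compatible
estimators (`fit`/`predict`/`transform`, `get_params`, `clone`); the
module-level functions (`fit_cart`, `cv_loss`, `forward_select`,
`loso_evaluate`, …) are thin wrappers for pipeline scripting.

## Worked example

Run the whole pipeline on the default synthetic cohort (30 subjects, all
three exercises):

```sh
tcmdetect run-all --seed 1 --out runs/demo
```

prints

```
bird_dog: features=['max_Z1', 'var_Z3', 'skew_Z2'] loso_acc=0.972
prone_rocking: features=['var_Y2', 'var_Y1'] loso_acc=0.956
rowing: features=['maxdphi_1_2'] loso_acc=0.967
```

Reading: for Prone-Rocking the selector found the variance of the lateral
(Y) acceleration of the upper-back sensor, `var_Y2` — exactly the channel
the simulated compensatory spine twist feeds — and LOSO accuracy on sets of
completely unseen subjects is 95.6 %. `runs/demo/` contains the per-exercise
feature matrices, selection traces, tree models (JSON), evaluation reports
and scatter plots with dashed lines at the fitted split values;
`evaluation_prone_rocking.json` reports the split value −0.55 (z-units) on
`var_Y2` with sensitivity = specificity = 0.956 (confusion 86/86/4/4).

The stage-by-stage commands (`simulate`, `preprocess`, `extract`, `select`,
`train`, `evaluate`, `report`) expose the same pipeline over CSV/JSON files;
see `tcmdetect --help`.

Library use:

```python
from tcmdetect import (generate_cohort, preprocess_cohort,
                       build_feature_matrix, forward_select,
                       SelectionConfig, loso_evaluate)

recs, _ = generate_cohort(n_subjects=30, exercises=["prone_rocking"],
                          master_seed=1)
fm = build_feature_matrix(preprocess_cohort(recs))     # 180 x 50, z-scored
sel = forward_select(fm, SelectionConfig(rng_seed=1))  # ['var_Y2', 'var_Y1']
print(loso_evaluate(fm, sel.accepted_features).accuracy)  # 0.9556
```

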