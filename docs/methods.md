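# Methods

This note documents the models, procedures, defaults and numerical
choices behind `beamselect`, and what the synthetic-data experiments do
and do not demonstrate.

## The classification problem

A cohort of n subjects (default 41: 12 non-functionally limited, label 0;
29 functionally limited, label 1) is described by p region-averaged
white-matter diffusion features (default 68, after the ICBM-DTI-81
parcellation; the metric is LDH or FA). The task is binary severity
classification with a soft-margin SVM, with feature subsets chosen by a
wrapper search. Throughout, label 1 is the positive class: *sensitivity*
is the correct-identification rate of functionally limited subjects,
*specificity* of non-functionally limited subjects. AUC is the
Mann–Whitney probability that a random positive out-scores a random
negative, ties counted one half.

## Zero-mean normalization

Each feature is z-scored, (x − μ)/σ. Two conventions are explicit:

* **SD denominator** — population (divide by n) by default, matching the
  plain reading of σ(xⱼ) as "the standard deviation of the feature over
  the fitted rows"; `use_sample_sd=True` switches to n−1. The choice only
  rescales the whole feature space uniformly and is practically
  irrelevant downstream.
* **Leakage policy** — `leakage="train"` (default) fits μ, σ on the
  training rows of each resample and applies them to the held-out rows;
  `leakage="all"` fits once on the full cohort before resampling, which
  mimics published small-cohort pipelines that normalize before
  splitting. Both modes are available in every engine; published reports
  of this design are ambiguous about which was used, so both are kept.

A feature constant on the fitted rows raises an error naming the feature;
inside bootstrap resamples (where a column can collapse by chance) the
column is passed through centred with unit scale — it carries no
information on that draw.

## Beam-search wrapper selection

* **Scoring.** A subset's score is the mean out-of-bag AUC of the SVM
  over `n_bootstrap` bootstrap resamples: each resample draws n subjects
  with replacement as the training multiset and tests on the never-drawn
  subjects. Draws whose training multiset or out-of-bag set lacks a class
  (or whose out-of-bag set is empty) are redrawn, so every score
  aggregates exactly `n_bootstrap` valid repetitions; redraw counts are
  logged. The per-subset resampling seed derives deterministically from
  `(seed, subset)`, so a subset scores identically wherever it appears —
  across loops, runs, and exhaustive-enumeration cross-checks. Scores are
  cached per subset.
* **Search.** Loop 0 scores all C(p, k_init) subsets (k_init = 3; for
  p = 68 that is 50,116) and keeps the best `beam_width` (default 100) as
  the priority queue, ranked by mean AUC with deterministic tie-breaking
  (higher AUC, then smaller subset, then lexicographic order). Each
  subsequent loop extends every queued subset by every absent feature,
  deduplicates, scores, and keeps the best `beam_width` of the new
  candidates. The search stops when the best candidate improves on the
  previous loop's best by less than `stop_delta` (default 0.002). The
  terminating loop still contributes its queue and optimal subset —
  consistent with accepting a final subset whose last step improved "only
  slightly" — and `return_previous_on_stop` restores the stricter
  alternative. If the search exhausts the feature set instead (possible
  when `stop_delta` is negative), the queue of the best-scoring loop is
  returned.
* **Frequency.** For the final queue, each feature's frequency is the
  fraction of queued subsets containing it — a stability measure of
  selection; features at frequency 1 appear in every top subset.
* **Bootstrap count.** Published versions of this scheme quote 1,000
  bootstrap repetitions per subset, which prices loop 0 at ~5×10⁷
  classifier fits. The default here is `n_bootstrap=50` — subset
  *ranking* stabilizes far below 1,000 repetitions — and the full 1,000
  is a configuration away. The experiment-scale runs in the test suite
  and the acceptance script use 50–100.

### The compiled SVM solver

Subset scoring fits millions of SVMs on 41-row matrices; generic SVM
interfaces spend most of that time in per-call overhead. The hot loop is
therefore a numba-compiled kernel covering the whole per-resample
pipeline (bootstrap indexing, z-scoring, SMO fit, decision scores,
tie-aware AUC). The solver optimizes the standard C-SVC dual (equality
constraint, box constraints, maximal-violating-pair working-set
selection, KKT tolerance 1e-3, alphas snapped onto the box to avoid
floating-point stalls). It covers the linear kernel; other kernels fall
back to scikit-learn. The test suite checks the solver against
scikit-learn's `SVC` on randomized problems: identical predictions and
decision scores matching to solver tolerance. Everything outside the hot
loop — `train_classifier`, both validation engines, PCA, stratified
folds — uses scikit-learn directly.

## Baseline selectors

* **ReliefF** — standard nearest-hit/nearest-miss weighting: Manhattan
  distance on range-scaled features, k nearest hits and misses per
  sampled instance (k = 10, capped at smaller-class size − 1), miss
  contributions weighted by class priors, diffs normalized by feature
  range (zero-range features contribute zero), instances visited in row
  order — fully deterministic. The top-m features are kept (m = 10 by
  default; the number retained is not standardized in the literature).
* **PCA** — components ordered by explained variance; the smallest count
  reaching `variance_threshold` (default 0.95) is kept; test rows are
  projected with training loadings. PCA is refit inside every resample,
  so it is never leaked even in "as-published" selection mode.

## Validation engines

* **Bootstrap out-of-bag** (default 1,000 repetitions): mean and SD over
  repetitions of each metric. Expected out-of-bag fraction is
  (1 − 1/n)ⁿ ≈ 0.363 for n = 41.
* **Repeated stratified 5-fold CV** (default 10 repeats): folds preserve
  class proportions as closely as integer counts allow (12 vs 29 with
  k = 5 gives every test fold ≥ 2 negatives and ≥ 5 positives) and
  partition the cohort within each repeat. The SD is taken across all
  k × repeats fold results by default (`cv_sd_mode="per_fold"`, the
  convention that produces visibly non-trivial deviations in report
  tables); `"per_repeat_mean"` first averages folds within a repeat.

Classifier defaults: linear kernel, C = 1, no class weighting. None of
these is standardized in the motivating literature; with a 29/41 majority
class, unweighted SVMs on weak feature sets reproduce the characteristic
high-sensitivity / low-specificity pattern such studies report. All three
are configurable (`rbf`, any C > 0, `"balanced"`).

### Selection leakage

`selection_mode="as_published"` (default) selects features once on the
full cohort and then validates the fixed subset by resampling on the same
subjects. This is the procedure the motivating studies report, and it is
optimistically biased: the selected subset has already seen every test
subject. `selection_mode="nested"` re-runs selection inside every
training resample and logs a warning that results are not comparable
between modes. The acceptance-script numbers use the as-published mode
deliberately, to reproduce the published protocol's behaviour.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, not any
particular dataset:

* Per-feature Gaussians with region-specific baselines drawn once per
  cohort: means uniform on [0.3, 0.8] (an FA-like range) and SDs uniform
  on [0.5, 1.5] × `noise_sd` (default 0.05, matching the few-percent
  spread of region-averaged diffusion metrics). Gaussianity is an
  assumption — region-level LDH/FA distributions are not publicly
  documented — chosen because region averages are continuous and
  unimodal and because it makes planted effect sizes exactly
  interpretable.
* Informative features shift the group-1 mean by
  `effect_size × (feature SD)`, i.e. `effect_size` is a standardized
  (pooled-SD) Cohen's d. Realized per-feature effects at n = 12/29 have
  sampling SD ≈ 0.44 around the nominal value; the generator reports the
  realized values as ground truth.
* Optional equicorrelated blocks of adjacent features (Gaussian shared
  factor) mimic anatomically neighbouring regions; off by default.
* The experiment-scale default plants the ten regions a published LDH
  analysis selected, at d = 0.6 each. That regime is chosen to match the
  published evidence: per-region differences individually short of
  univariate significance (t ≈ 1.75 at these group sizes), while ten
  such regions jointly give a Mahalanobis distance ≈ 1.9 and a
  theoretical AUC ≈ 0.91 — weak dispersed signal, detectable only
  multivariately.

What the generator does **not** reproduce: inter-region correlation
structure of real white matter (beyond the optional blocks), scanner or
site effects, non-Gaussian tails, label noise in clinical ratings, and
any relationship between LDH and FA. Passing tests therefore demonstrate
correctness and calibration of the *machinery* under the stated
statistical model, not clinical validity on real cohorts.

## Numerical and determinism choices

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical configurations reproduce every
  report byte for byte. Derived seeds are tagged per stage so that
  subsystems never share streams.
* AUC uses average ranks; tied decision scores contribute one half.
* SMO: KKT tolerance 1e-3 (the libsvm default), iteration cap 2×10⁵ pair
  updates, box-snap tolerance 1e-12·(1+C).
* Degenerate inputs fail loudly: single-class training sets, zero-variance
  features at fit time, classes smaller than the fold count, malformed
  cohort CSVs (with row/column locations), invalid configuration values.

## Known limitations

* The recovery behaviour of bootstrap-AUC wrapper selection is limited by
  the cohort size, not by the search: the beam provably attains the
  global optimum of its scoring objective on small instances, yet at
  strong planted effects (d ≥ 2) the objective's own argmax frequently
  swaps a planted feature for a sample-lucky noise feature, because
  out-of-bag AUC on 41 subjects saturates near 1 and noise features can
  carry genuine in-cohort discrimination. Feature *frequencies* over the
  final queue are more robust than the single top subset.
* As-published selection plus same-cohort validation overstates
  generalization; nested mode is the honest estimate and is markedly
  more expensive for the beam selector.
* The compiled fast path covers the linear kernel only; `rbf` runs
  through the slower scikit-learn path.
* Subset scoring always uses the population-SD convention inside
  resamples; `use_sample_sd` affects the validation engines and the
  public scaler only (the two conventions differ by a uniform rescale).
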