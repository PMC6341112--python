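# Methods

`sitemorph` implements a multi-site case-control analysis of regional
brain-morphometry feature tables: leakage-free covariate normalization,
site-stratified random-forest classification evaluated leave-site-out, and a
decomposition that asks how much of the discriminative signal is carried by a
small set of global brain-structural summary measures.  Because the kind of
pooled clinical MRI tables the pipeline targets are rarely shareable, the
package ships a synthetic-cohort generator with fully known ground truth;
every downstream stage is exercised and tested against that generator.

## The synthetic study

`simulate.SimulationConfig` fixes the study conditions.  A feature atlas
(`atlas.build_feature_atlas`) defines two feature families — 122
grey-matter-density-like regional measures and 152 surface-reconstruction
measures (thickness, area, volume) — plus total intracranial volume (ICV)
and the global summary set described below.  Feature values are generated on
a standardized latent scale `z` and mapped to measurement units as
`mean_size * (1 + 0.10 * z)`, so configured effect sizes are Cohen's-d-like
per feature and independent of structure size.

Each subject's latent feature vector is the sum of:

* **Covariate effects.**  Linear age (default −0.02 z/year), a weak
  quadratic age term, sex (0.3 z), and ICV (0.4 z per ICV standard
  deviation; zero for thickness measures, which do not scale with head
  size).  Per-feature multipliers jitter these baselines uniformly in
  [0.5, 1.5]; the realized coefficients are recorded in the ground truth.
* **Site structure.**  A per-(site, feature) mean offset drawn once from
  N(0, 0.3²), plus scanner-vendor (SD 0.2) and field-strength (SD 0.15)
  offsets tied to each cohort's acquisition.  The magnitudes are
  moderate-fraction-of-noise choices, not calibrated estimates — real
  inter-site variability is not well characterized — and are exposed as
  configuration knobs.
* **Global factors.**  K = 3 correlated per-subject latent factors
  (pairwise r = 0.3) emulating shared, atrophy-like whole-brain variation.
  Loadings are positive, scale with `sqrt(mean_size / median size)` (capped
  at [0.4, 3.0]) so larger structures carry more global signal, and are
  sign-flipped for ventricles (atrophy enlarges them).
* **Disorder effect.**  The dial `global_mediation` (μ) splits a total
  case-control effect `d` (default 0.8): each global factor mean is shifted
  by μ·d in cases, and each of `n_regional_informative` designated regional
  features receives a direct marginal shift of (1−μ)·d.  The analytic
  marginal d per feature, `(μ·d·Σλ + direct) / sqrt(λᵀΣλ + σ²)`, is recorded
  and tested against the empirical tables.  Bipolar-like validation cases
  share the factor shift at 0.75× magnitude; ADHD-like cases carry a
  mixed-sign signal on a disjoint regional set (no net projection onto the
  global direction), with the adolescent cohort aged 12–18.
* **Noise.**  Independent N(0, 1).

The age-confound knob for matching experiments draws controls from a wider,
on-average-10-years-older pool that still overlaps the case range — the kind
of imbalance 1:1 matching can actually repair (a rigidly shifted control
distribution is a support failure no caliper-free matcher fixes).

What the generator does **not** emulate: non-linear covariate effects beyond
age², longitudinal structure, missing data, heavy-tailed measurement error,
or spatial correlation beyond the factor structure.  Passing tests therefore
demonstrate the correctness and calibration of the *procedures*, not the
effect sizes to be expected on real scanners.

## Matching and normalization

Within each cohort, cases are 1:1 matched to controls on a logistic
propensity of case status on age and sex: greedy nearest-neighbour on the
logit, cases in seeded random order, each control used once, no caliper.
Degenerate propensity fits (perfect separation) fall back to standardized
covariate-distance matching with a warning.  Cohorts can be flagged to skip
matching and pass through unmatched.

Covariate adjustment is two-step and fit on training cohorts only:

1. **Within-dataset:** per training cohort, each feature is regressed on
   age, age² (age centered at the pooled training mean, which decorrelates
   the linear and quadratic terms), sex and ICV — ICV omitted for thickness
   features — and the per-cohort coefficients are averaged unweighted into
   one model per feature.  Residuals are formed for training and test data
   alike; ICV is then appended as a feature.  Note that with more than one
   training cohort the *averaged* model's pooled residuals are no longer
   exactly orthogonal to the covariates; exact orthogonality holds for
   single-cohort fits and for the single joint fits of the later steps.
2. **Between-dataset:** vendor and field-strength factors (reference-coded)
   are removed by a single linear fit on the training cohorts; levels absent
   from training predict at the reference level with a warning.

A `LeakageAudit` object records every fit's subject set and raises (or, in
non-strict mode, flags) the moment a declared held-out subject enters a
design matrix.  Whole-dataset analyses (univariate statistics, pooled
out-of-bag evaluation, explained-variance regressions) additionally
residualize a site factor (vendor dropped when aliased with site).  An
optional secondary step sets each feature's mean in a held-out cohort
exactly to zero, the standard repair for cross-site score shifts.

## Classifiers and evaluation

The **site-stratified random forest** grows unpruned Gini-split trees
(`mtry = floor(sqrt(p))`, default 5000 trees) on per-tree bags holding
exactly `s` subjects drawn without replacement from every training site.
The literal rule `s = n_min` (smallest site size) keeps that site's subjects
in-bag for every tree and leaves their out-of-bag (OOB) scores undefined;
the default is therefore `s = ceil(0.632 · n_min)` — the in-bag fraction of
a classical bootstrap — with `strict_bag=True` restoring the literal rule.
A subject's OOB score is the fraction of its OOB trees voting case; feature
importance is the mean unnormalised Gini decrease.  The linear SVM
comparator tunes its cost over 10⁻⁵…10⁵ (11 log-spaced values) by 10-fold
CV on training data only.

Evaluation harnesses: leave-site-out (matching and both normalization steps
refit per fold; median and range of per-site AUC; sensitivity/specificity
at a 0.5 vote cutoff to expose cross-site score shifts), within-site OOB
with label-permutation significance (empirical p = #{null ≥ observed}/B,
reported as `<1/B` when zero), and external specificity (fraction of an
independent cohort classified non-case; any training overlap is rejected).
AUC is the Mann–Whitney tie-aware probability; an independent brute-force
pairwise oracle backs it in the tests.

## Feature importance and the global signal

**Backward elimination** drops the least important 20% of features per
round, refits, tracks OOB error, and returns the smallest visited set whose
error is within one binomial standard error of the minimum.  **Importance
overlap** takes one task's top-m features and computes the one-sided
rank-sum of their importances in a second task's forest; the null re-trains
that forest under within-site label permutation (B default 5000; permutation
forests may use fewer trees, default 500, with strict parity available).
The test is calibrated when the top set is uninformative for the second
task, and deliberately conservative (p → 1) when the second task's signal
sits on a disjoint feature set — the top set then ranks anomalously low.
Per-permutation forests reuse fixed m from the observed run; variable
selection is not repeated inside the null.

The **global feature set** has 22 members: 19 measured whole-brain summary
features (hemisphere aggregates, total grey/white matter, ventricles, …),
ICV, a per-subject median of all ventricle features, and a per-subject
median over the active family's regional features (computed after covariate
adjustment, consistent with using covariate-adjusted globals as
regressors).  The two family modes differ only in that last member.
Regional features are residualized against all 22 globals by additive OLS —
fit on training subjects only in leave-site-out mode, preserving the
pipeline's leakage discipline — with two controls: row-permuted globals
(residualization per se) and within-cohort permuted diagnoses (the chance
band; matching and normalization are label-free given the matched sets, so
only classification is re-run per repetition).  Explained variance per
regional feature is the OOB R² of a random-forest regression on the globals
(mtry = p/3, minimum node size 5), floored at zero for reporting, and its
Spearman correlation with structure size is reported.

## Numerical and scaling choices

* Seeds: every stochastic element derives from one master seed through
  `numpy.random.SeedSequence` spawning; identical configurations reproduce
  identical tables, scores and report digests.
* OLS everywhere uses `numpy.linalg.lstsq`; rank-deficient designs drop
  collinear columns greedily with a warning; constant covariates within a
  cohort drop that cohort's coefficient.
* Ties in importance rankings break lexicographically by feature id; the
  rank-sum statistic uses midranks.
* Desk-scale defaults: the simulation experiments in the analysis scripts,
  tests and acceptance script use 40 + 40 regional features, 4 cohorts of
  50 + 50 subjects, and forests of 100–300 trees; the model contract itself
  defaults to 5000 trees.  Scaled experiments preserve the *fraction* of
  informative regional features (e.g. 4 of ~80 ≈ 15 of 275) — the family
  median is a median over regional features, so inflating the informative
  fraction would let it absorb regional signal that is negligible at full
  scale.
* Permutation depths are scaled similarly (B = 50–200 in scripts and tests
  versus the 1000/5000-fold defaults of the full procedure).

## Known limitations

The averaged within-dataset model leaves small covariate correlations in
pooled multi-cohort residuals (see above).  Specificity estimates in
validation cohorts inherit the vendor/field extrapolation rule when a level
was unseen in training.  The OOB explained-variance estimator is downward
biased for smooth multi-regressor signals at moderate n; recovery tests use
single-regressor constructions where the bias is small.  The decomposition
controls permute diagnosis within matched sets rather than re-matching,
which is exact given label-free matching covariates but would differ if
matching used diagnosis-correlated variables beyond age and sex.
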