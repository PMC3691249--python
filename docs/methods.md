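# Methods

This note documents the models and procedures `earlymet` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Study design being modelled

The pipeline targets a nested case-control expression study of early
prostate-cancer metastasis. Patients fall into three outcome groups:
no evidence of disease (NED), PSA/biochemical recurrence only (PSA), and
clinical metastasis within five years of BCR (MET). MET patients are the
cases; NED and PSA are pooled as controls, justified by the near-total
absence of differential expression between the two control groups. A fixed
training/validation split (≈ 2:1) is part of the input; every fitting stage
sees training data only.

## Synthetic cohorts

`simulate.generate_cohort` draws a log2-scale expression matrix

    x_fs = mu_f + batch_offset(b_s, f) + delta_fs + eps_fs

with per-feature baselines `mu_f ~ N(7, 1.5²)` (a typical normalized
microarray intensity scale), i.i.d. noise `eps ~ N(0, noise_sd²)`
(default 1.0), and additive per-(batch, feature) offsets
`~ N(0, batch_sd²)` (default 0.3, 19 batches). The planted signal
`delta_fs = effect_size · g_s · d_f` applies only to cases on the
`n_informative` marker features: `d_f = ±1` is a per-feature direction and
`g_s ~ N(1, 0.25²)` (truncated positive) is a per-case severity factor.
Because `g_s` also scales the case's hazard of metastasis and
cancer-specific death (exponential event times, uniform censoring on
5–20 years), tumours with a larger expression shift progress faster — the
qualitative property the survival analyses rely on. NED and PSA samples
draw from exactly the same expression distribution and differ only in
clinical fields (salvage therapy is structurally impossible for NED).

Clinical covariates are sampled per class with the qualitative gradients of
real registries (cases: ~61% GS ≥ 8, ~50% SVI, ~60% ECE, ~22% N+; controls:
~27%, 28%, 43%, 8%); pre-operative PSA is log-normal with ~3% missing
values. Defaults (5,000 features, 300 samples = 110/95/95, 30 markers, unit
effect, train fraction 359/545) are a desk-scale rendition of the cohort
structure the pipeline is meant for; they are fixed study conditions, not
tuning knobs.

Technical replicates emulate a cell-line control profiled once per batch:
a fixed profile plus per-feature noise of scale 0.15, inflated ×10 for a
2% "unreliable" subset, which therefore lands in the top variance decile
with probability ≈ 1.

What the generator does **not** emulate: probe-level intensities and
summarization, correlated co-expression modules, heavy-tailed intensity
distributions, batch-by-class confounding, or informative censoring.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative model, not performance on real
arrays.

## Preprocessing

* Metadata filter: keep features with ≥ 4 probes and no cross-hybridization
  flag.
* Technical-variance filter: per-feature variance across replicate columns
  (ddof = 1); the cutoff is the 90th percentile of the *replicate
  experiment's* variance distribution and every feature at or above it is
  removed (ties all go). Anchoring the cutoff to the replicate experiment
  makes re-application a no-op and lets the replicate matrix cover a
  superset of the working features. The filter is blind to biology: at
  default settings it removes ~10% of planted markers by chance, exactly as
  it would remove real markers.
* Batch correction: the feature-centred matrix is decomposed by SVD;
  sample-space component scores `s_k v_k` are scored against batch by
  one-way-ANOVA R² (between-group over total sum of squares — scale-free and
  monotone in the F statistic); the 2 highest-R² of the first 10 components
  are subtracted. Feature means are untouched, so total variance drops by
  exactly the removed components' variance, and the corrected matrix is
  orthogonal to the removed directions. No re-scaling is applied after
  removal. By default the decomposition uses all samples (training +
  validation, matching the source procedure); `batch_fit_on="train"`
  restricts the fit to training samples and projects the rest off the
  fitted feature-space loadings, for strict validation hygiene.

## Feature selection

* t-filter: two-sided Welch (unequal-variance) t-test per feature, with
  the pooled-variance variant available via `equal_var=True`; unadjusted
  p < 0.01 — a complexity-reduction step, not an inference. Degenerate features (zero variance in both groups) are
  excluded with a warning.
* Stability selection: for each of `n_boot` (default 1000; 100 in the
  desk-scale runs) class-stratified bootstrap resamples of size n, an
  elastic-net logistic regression (saga; mixing α = 0.5) is fitted with the
  penalty strength chosen by 3-fold cross-validated log-loss over 6
  log-spaced values *within that resample* (a `tuning="global"` option
  fixes one strength for all resamples). A feature's tally is the number of
  resamples with an exactly-zero-free coefficient (the solver's active set,
  no magnitude threshold); features with tally/n_boot ≥ 0.25 survive.
  Features are standardized to unit variance inside each resample so the
  penalty treats them symmetrically. Stratification guarantees both classes
  in every resample; solver failures skip the round (warned above 1% lost).
  At desk-scale candidate counts (tens of t-filter survivors against ~200
  training samples) the cross-validated penalty is weak and most candidates
  tally above threshold — the stage confirms rather than prunes; its
  sparsifying role grows with the candidate-to-sample ratio typical of
  transcriptome-scale inputs.

## Genomic classifier

* Backward elimination: each round fits a 1000-tree forest (200 at desk
  scale), records the 10-fold cross-validated **Brier MSE** of out-of-fold
  case-probabilities against the 0/1 label (the natural reading of "MSE"
  for a probability forest), and drops the `drop_frac = 10%` of features
  with the lowest mean-decrease-Gini importance, at least one per round,
  down to a single feature. The chosen size is the curve's argmin with ties
  resolved to the smaller set (the "knee"). Note the knee *prunes redundant
  markers*: when many planted markers carry correlated signal the argmin
  sits well below the planted count, with the survivors almost always a
  subset of the true markers. Recovery of the full marker set is a property
  of the stability-selection stage, not of elimination.
* Tuning: grid over `mtry ∈ {1, ⌈√p⌉, ⌈p/3⌉, ⌈p/2⌉, p}` and
  `nodesize ∈ {1, 2, 5, 10, 20}` (both configurable), each cell scored by
  mean held-out accuracy at the 0.5 threshold over `tune_boot` repeated
  stratified 1/3-fit / 2/3-test splits (splits shared across cells); ties
  break to smaller nodesize, then smaller mtry. Cells with mtry > p are
  skipped with a warning.
* Final model: a probability forest refitted on the full training set with
  the tuned parameters; the score is the forest's case-probability (mean
  terminal-node case frequency), guaranteed in [0, 1]. Scores > 0.5 are
  called high risk; exactly 0.5 is low. Models serialize to JSON metadata
  plus a joblib ensemble bundle and reload score-identically.

## Clinical and integrated classifiers

CC is a maximum-likelihood logistic regression on GS ≥ 8, log2 pre-operative
PSA (training-median imputed, with a missingness indicator), SVI, SM+, ECE
and N+. Constant covariates are pruned; complete separation raises an error
naming the covariate. GCC is a logistic regression on the (GC, CC) score
pair; when the training scores separate the classes perfectly — routine for
in-sample forest scores — the unpenalised likelihood has no maximum and a
lightly ridge-penalised fit (α = 1) is substituted with a warning, keeping
the [0, 1] score contract. Collinear or constant CC scores drop to a
GC-only fit, warned.

## Evaluation

* AUC: Mann–Whitney concordance (ties ½) with a class-stratified percentile
  bootstrap 95% CI (default 2000 resamples); DeLong intervals available via
  `method="delong"`.
* Odds ratios: 2×2 Wald (`z = 1.959964`); a single zero cell triggers the
  Haldane–Anscombe +0.5 correction (flagged); a zero margin is an error.
  Continuous predictors use logistic fits; classifier scores are reported
  per 0.10 score increment. Multivariable fits drop rank-deficient columns
  with a warning, fall back from Newton to BFGS on singular Hessians, and
  warn when coefficient magnitudes indicate separation. P-values are Wald.
* Kaplan–Meier: lifelines product-limit curves; median = first time the
  curve reaches ≤ 0.5 (undefined otherwise); unweighted log-rank p
  (χ², 1 df for two groups).
* Reclassification: Gleason {≤6, 7, 8, ≥9} × GC risk {≤0.5, >0.5} cells
  with metastasis and cancer-death counts; percentages use one decimal
  below 10%, integers otherwise (report style).
* Follow-up: reverse Kaplan–Meier — deaths censored, end of contact as the
  event — reporting that curve's median.

## Orchestration and reproducibility

`run_pipeline` wires the stages in order, logging the feature funnel
(input → reliable → t-pass → stability-selected → final markers). All
randomness flows from one master seed through named substreams (crc32-keyed
`numpy` SeedSequences), so runs are pure functions of (inputs, config) and
the artifact manifest's SHA-256 hashes are byte-identical across repeats.
Validation outcome labels live behind an access guard that raises if read
before the evaluation stage. If stability selection returns fewer than
`min_selected` features (e.g. under a null cohort), the top-tally features
are substituted with a warning so the downstream stages remain exercisable.

Desk-scale problem sizes used by the demonstration and control runs:
5,000 × 300 with 100 stability bootstraps, 200 trees and 20 tuning
resamples for the planted-signal demo; 1,500 × 200 with zero effect for the
no-signal control. These sizes keep single-CPU runs in the minutes range
while leaving every stage's statistical behaviour observable.

## Known limitations

* The elastic-net penalty grid (10⁻² … 10¹ on sklearn's C scale) is fixed;
  extremely sparse or dense designs may want a wider path.
* Gini importance is biased toward high-cardinality features; with
  continuous expression on a common scale this is benign, but mixed-type
  inputs would need permutation importance.
* The ANOVA-R² batch score targets mean shifts; multiplicative batch
  effects (scale changes) are out of scope, as is ComBat-style adjustment.
* Percentile-bootstrap AUC intervals can undercover at very small n; use
  DeLong there.
* The reclassification table assumes the cohort's endpoint hierarchy
  (cancer death only after metastasis); cohorts violating it fail the
  table's internal consistency check by design.
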