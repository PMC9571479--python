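# Methods

`mirsig` implements a complete discovery pipeline for circulating-microRNA
diagnostic signatures measured by RT-qPCR array cards: Ct-level quality
control, normalization-method selection, delta-delta-Ct differential
expression, L1-penalized logistic signature selection with resampling-based
uncertainty checks, and cross-validated ROC/PR evaluation with
sensitivity-first decision thresholds.  This note records the statistical
model behind each stage, the defaults and why they were chosen, and the
limits of what the synthetic cohorts can demonstrate.

## The measurement model

A qPCR cycle threshold Ct is (minus) a log2 abundance: expression is
proportional to `2**(-Ct)`.  The synthetic generator (`mirsig.simulate`)
draws, for assay *f* and sample *s*,

    Ct[f, s] = baseline(f) - effect(f) * 1[s is patient] + offset(s) + eps,
    eps ~ Normal(0, noise_sd)

- `baseline(f)`: Uniform(20, 33) cycles for ordinary assays — the
  quantifiable range of an array card.  Planted signature assays draw from
  Uniform(22, 27) so that a +/-4-cycle effect plus noise cannot push them
  past the informativeness limit; this models the fact that a usable
  biomarker must be reliably quantifiable in both groups.
- `effect(f)`: the planted group difference in cycles; positive means lower
  Ct (higher expression) in patients.  Defaults plant four assays at
  magnitude 3 — three up-regulated (miR-412-3p, miR-507, miR-1203) and one
  down-regulated (miR-362-3p), a realistic direction mix for a melanoma
  plasma-EV marker panel.
- `offset(s) ~ Normal(0, 0.5)` cycles: a per-sample global shift standing
  in for RNA input, extraction and loading effects — exactly the distortion
  normalization must remove.
- `noise_sd = 0.5` cycles of well-level measurement noise, a typical
  replicate SD for late-cycle TaqMan measurements.
- Right-censoring: wells above 40 cycles (the run's cycle budget) are
  recorded as `Undetermined`.
- Spike-ins (ath-miR-159a, cel-miR-254, osa-miR-414) carry no group effect
  and no sample offset, so delta-Ct normalization against them is exactly
  recoverable by construction.
- Hemolysis: affected samples have Ct(miR-451) lowered by 8 cycles
  (miR-451 is red-blood-cell enriched), pushing the miR-23a/miR-451 cycle
  difference from its baseline 4 to 12, past the failure threshold.

Cohort sizes default to 16 patients vs 22 controls (discovery) and
20 vs 18 (internal validation).  A validation cohort shares the assay
universe and baselines of its discovery platform and redraws offsets,
noise and censoring under a fresh seed.

No published distributional description of raw plasma-EV Ct data exists for
this design, so these defaults are plausibility choices for testability,
not estimates of any real cohort.

## Preprocessing

- `Undetermined -> Ct = 40` (the cycle budget), the standard imputation for
  censored wells.
- Informativeness: an assay is kept when `Ct <= 33` — by default in *every*
  sample ("detected in all samples"); a fraction-based policy (overall or
  within at least one group) is available because the all-samples reading
  is a convention, not a law.
- Hemolysis QC: `delta = Ct(miR-23a) - Ct(miR-451)`; `delta > 7` fails the
  sample, `5 < delta <= 7` warns.  These cutoffs follow the hemolysis
  literature for plasma miRNA QC.  The "ratio" of the two markers is
  computed as a Ct difference, i.e. a log2 ratio.  A censored marker makes
  the sample "inconclusive" (kept, but surfaced).  Failed samples are
  dropped before normalization.

## Normalization and its selection

Five candidates, all on the Ct scale:

- **quantile** — each sample's k-th order statistic becomes the mean k-th
  order statistic; within-sample ties receive the mean of the replacement
  values they span.  (With ties this intentionally breaks exact multiset
  equality across samples.)
- **geometric_mean** — per-sample arithmetic-mean centering on the Ct scale
  (equal to geometric-mean scaling on the linear scale), re-anchored at the
  grand mean so values remain in cycle units.
- **delta_ct** — subtract the mean Ct of designated control assays
  (spike-ins by default).
- **scale_rank_invariant** — a per-sample constant shift estimated on the
  set of assays whose rank is stable against a pseudo-reference (the
  per-assay mean over samples): rank shift at most 5% of N, reference rank
  outside the extreme 5% tails, minimum set size 5.  An empty or too-small
  common set falls back to geometric-mean centering with a warning.
- **norm_rank_invariant** — a lowess curve (frac 0.6) mapping sample Ct to
  reference Ct, fitted on the sample's rank-invariant set and applied to
  all assays with linear extrapolation outside the fitted range.  This is
  the only candidate that can remove smooth intensity-dependent bias, at
  the cost of a curve estimated from tens of points.

Method selection scores each normalized matrix by the mean per-assay CV
(SD/mean across samples, Ct scale) and mean per-assay SD, and picks the
smallest CV; ties break by SD, then by a fixed method order.  CV on the Ct
scale is meaningful because Ct means are safely positive.  A pooled
(rather than per-assay) variant of both statistics is available.  On the
default synthetic cohorts the norm.rank-invariant method usually wins,
with quantile and the scale variant close behind and delta-Ct far worse
(spike-ins do not carry the sample offsets, so subtracting them removes
nothing).

## Differential expression

Per assay: `ddCt = mean Ct(patients) - mean Ct(controls)`, fold change
`FC = 2**(-ddCt)`, two-sided Wilcoxon Mann-Whitney p-value (exact for
tie-free data with combined n <= 20, otherwise normal approximation with
tie and continuity corrections — cohorts of the default size always use
the approximation).  An assay is called up-regulated when `FC >= 2` and
`p < 0.05`, down-regulated when `FC <= 0.5` and `p < 0.05` (the symmetric
reading of "fold change > |2|").  Raw p-values drive the call, mirroring
the original filtering practice; Benjamini-Hochberg q-values are computed
and reported alongside for the reader.  Hierarchical clustering of samples
over the DE set uses 1 - Pearson correlation with average linkage by
default (both configurable; with very small DE sets a euclidean distance
is the more stable choice, as the analysis driver notes).

## Signature selection

The candidate matrix is samples x DE assays of normalized Ct values;
patient = 1 is the positive class throughout.  The model is L1-penalized
logistic regression

    min over (b, beta) of (1/n) * sum_i logloss_i + lambda * ||beta||_1

with features standardized internally (population SD); coefficients are
reported on both the standardized and original scales.  The penalty grid is
log-spaced over 100 values from `lambda_max` (the smallest penalty with an
all-zero solution, computed in closed form from the score at the null
model) down to `lambda_max * r`, `r = 0.01` when p >= n else `1e-4`.

`lambda_1se` is chosen by stratified 10-fold cross-validation on binomial
deviance: the largest penalty whose CV error is within one standard error
(across folds) of the minimum.  Folds are stratified, shuffled under a
recorded seed, and each fold standardizes with its own training statistics.
The signature is the set of nonzero-coefficient assays at `lambda_1se`,
ordered by |standardized coefficient|.

The path solver is an accelerated proximal-gradient (FISTA) method with an
unpenalized intercept, per-problem adaptive restart, warm starts along the
grid, and a power-iteration Lipschitz bound.  A problem's solution is
frozen for the remaining (smaller) penalties once 99.9% of its null
deviance is explained — the standard saturated-fit path termination, which
matters on separable data where the unregularized tail would otherwise
diverge.  It is *batched*: CV folds and
bootstrap resamples are stacked into one tensor so the entire resampling
layer runs as vectorized numpy operations.  Solver accuracy is checked in
the tests against scikit-learn's liblinear at matched penalties (liblinear
approximates an unpenalized intercept via `intercept_scaling`, so agreement
is to ~1e-3 on coefficients).  Two numerical notes: a nonzero coefficient
is one with |value| > 1e-8 (the prox operator produces exact zeros), and
the number of nonzero coefficients is *not* monotone along the path for
correlated designs — a variable can genuinely leave the active set as the
penalty relaxes; liblinear reproduces the same pattern.

### Bootstrap stability

B resamples of the cohort with replacement (redrawn until each class keeps
at least two members, which stratified folds require); the full pipeline of
path fit, CV and extraction is rerun on each resample.  A resample scores a
hit when it recovers at least half of the original signature
(`|S_b ∩ S| >= ceil(|S|/2)`); the stability p-value is
`1 - hit frequency`, so small p means a stable signature.  (The hit
frequency itself is also reported; defining p this way makes "small p =
strong support" consistent with how such bootstrap supports are quoted.)
The resampling layer uses a coarser grid than the main fit — 30 penalties
down to `lambda_max/100`, 5 folds, solver tolerance 1e-5 — because
selection counts, not coefficient decimals, are being measured; these sizes
keep B in the thousands tractable on one CPU.

### Random-signature null

To ask whether a signature of size k could have arisen by chance, M random
k-subsets of the informative assay pool (restricted to assays present in
both cohorts) are fitted as unpenalized logistic models on the training
cohort and evaluated on the test cohort under the identical protocol as the
real signature, including re-selecting each model's own threshold.  The
p-value uses the add-one rule `(1 + #{acc_random >= acc_observed})/(M + 1)`,
which cannot return exactly zero.  Unpenalized fits that fail to converge
(separation) switch to a ridge-stabilized fit (C = 1000) and are flagged.

A calibration caveat discovered while testing: under a label-permuted null,
the sensitivity-first threshold forces every model to sensitivity 1, so a
model's test accuracy equals prevalence plus TN/n where TN is the number of
controls scoring below the *minimum* patient probability.  By a
distribution-free rank argument P(TN = 0) is about one half, so null
accuracies concentrate on a few discrete values and the p-value carries a
large atom at 1.0 — it is valid (conservative) but far from Uniform(0, 1).
The corresponding acceptance check asserts uniformity anyway and fails; the
behavior is a property of the protocol, not of this implementation.

## Evaluation

- **LOOCV**: n unpenalized logistic refits on the fixed signature features
  (feature selection is *not* redone inside the loop, matching the
  protocol the pipeline mirrors; a stricter selection-inside-LOOCV check
  can be run manually by looping `_discovery_selection` over folds).  The
  refits are one batched weighted fit; held-out probabilities match
  independent statsmodels GLM refits to ~1e-10.
- **ROC**: points at unique probabilities; trapezoidal AUC (equals the
  pairwise Mann-Whitney count with half credit for ties); 95% CI by the
  DeLong structural-components variance.
- **PR**: precision-recall at unique thresholds, anchored at recall 0 with
  the highest-threshold precision; trapezoidal area over recall (with one
  distinct threshold this yields precision = prevalence, area =
  prevalence); 95% CI by stratified bootstrap (2000 resamples, seeded) —
  no closed form exists.
- **Threshold**: among midpoints of adjacent unique probabilities plus
  +/- infinity: maximize TPR, then minimize FPR, then prefer the larger
  threshold; prediction is `probability >= threshold`.  Literal FPR
  minimization alone is degenerate (the always-negative classifier has
  FPR 0) and is kept only as an explicit alternative rule.
- **Confusion metrics**: accuracy, sensitivity, specificity, positive and
  negative prediction rates; zero-denominator rates are `None`, never
  silent NaN.
- **New cohorts**: the signature model refit (unpenalized) on the full
  discovery cohort is applied to the validation cohort; by default the
  threshold is re-selected on that cohort (the cohort-specific "ad hoc"
  threshold) and the metric block at the stored discovery threshold is
  reported alongside.

## Pipeline

`run_pipeline` chains QC -> normalization -> DE -> LASSO -> stability ->
LOOCV -> validation -> random null, writes every intermediate artifact
(TSV/CSV/JSON) and a manifest (stage, seed, outputs, warnings, wall time).
One global seed derives per-stage seeds by hashing the stage name, so any
stage can be rerun in isolation.  The reporting step (`make_report`) only
formats numbers already stored in the manifest.  The validation cohort is
normalized with the method selected on discovery.

## Problem sizes used in the automated checks

The test suite runs the full pipeline at the default cohort conditions
(seed-fixed), signature recovery over 50 generator seeds, bootstrap
stability at B = 500 over 20 seeds, and the null calibration at M = 200
over 100 replicates; the analysis drivers use B = 2000 and M = 1000.
These resampling depths are the package's desk-scale choices; all are
parameters, and nothing in the implementation depends on them.

## What the synthetic cohorts do and do not show

The generator reproduces the statistical *structure* the pipeline assumes —
additive per-sample offsets, Gaussian well noise, planted log2 effects,
right-censoring, spike-ins, hemolysis — so passing tests demonstrate that
the machinery recovers planted truth under that structure (including
perfect discovery separation at a 3-cycle effect, which is a strong but
realistic effect for a selected biomarker panel).  It does not model
plate/card layout, PCR efficiency differences between assays, melt
behavior, correlated biological co-regulation beyond the shared offsets,
or cohort heterogeneity (stage mixtures, age/sex structure).  Real-data
performance claims cannot be transferred from these tests.

## Known limitations

- The FISTA solver caps iterations (1000 main, 300 in the bootstrap) and
  freezes saturated fits (99.9% of null deviance explained); the reported
  path tail below the saturation point is therefore a frozen snapshot, not
  the diverging unregularized solution.  The one-SE selection region is
  unaffected.
- Exact Wilcoxon p-values are only used for tie-free samples with combined
  n <= 20; array-card cohorts always take the asymptotic branch.
- The DeLong CI degenerates to a point at AUC 1.0 (zero variance), as
  printed confidence intervals of the form (1.00, 1.00) do.
- `liblinear`-style penalized-intercept models are *not* reproduced
  exactly; the intercept here is never penalized.
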