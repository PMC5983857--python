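# Methods

## Outcome model

The unit of analysis is the target (gene/protein), not the drug asset.
Asset-indication records carry one of ten outcomes (`Succeeded`, five
`InProgress-*`, four `Failed-*` stages). Eligibility filters keep records
with exactly one target, a human target, a non-cancer indication class and
a definitive phase III outcome (`Succeeded` or `Failed-PhaseIII`);
withdrawn and pre-phase-III failures are excluded because they are
dominated by safety/engagement rather than efficacy failures. Targets are
scored best-outcome-wins: any qualifying approval ⇒ success; otherwise any
qualifying phase III failure ⇒ failure; otherwise unlabeled. The reported
success rate is always the computed ratio n_S/(n_S+n_F); at the historical
counts 259/331 this is 78.2%. Indication class is an explicit input column
— mapping indications to a disease ontology is out of scope, so the cancer
exclusion reduces to a class test.

## Feature preparation

Datasets are gene × feature matrices of three value shapes, each with its
own standardization:

* quantitative filled-in — columns z-scored with the population (ddof = 0)
  SD, the classic z-score (a column `[1,2,3]` maps to `[−1.2247, 0,
  1.2247]`); zero-variance columns are dropped with a warning;
* quantitative sparse — columns divided by their mean (zeros are
  absences and must stay zero); zero-mean columns are dropped;
* categorical sparse — binary values pass through unchanged.

Per-gene row summaries `mean` and `stdv` are appended after column
standardization, computed over the dataset's original feature columns
only. The text describing the source procedure is ambiguous about whether
summaries precede or follow standardization; we follow the order in which
the operations are described (standardize, then summarise) and note that
the row SD uses the sample (ddof = 1) convention — the two SD conventions
differ because each is pinned by its own worked example. The optional
expression-entropy feature H = Σ Pᵢ log₂(1/Pᵢ), Pᵢ = Eᵢ/ΣEᵢ, is computed
on the raw, un-log-transformed values (entropy of a z-scored profile would
be meaningless); all-zero profiles get H = 0 and negative raw values are
rejected. Features with fewer than three non-zero values among the
outcome-labeled targets present in the dataset are dropped; "non-zero" is
an exact comparison.

## Redundancy reduction

Pairwise association is Spearman's ρ for filled-in data and the cosine
coefficient for sparse/categorical data (cosine of a zero vector is
defined as 0). The association matrix is squared and thresholded at
r² ≥ 0.5 (for Spearman, one feature explaining half the variance of
another; for cosine, alignment within 45°) — squaring first lets
anticorrelated features group. Features are ordered by decreasing number
of correlated partners (ties: original column order) and grouped greedily;
membership always refers to the original association matrix (no
recomputation against group means — the sequential-exclusion wording of
the source procedure implies none). A group containing the dataset `mean`
summary is represented by the dataset mean itself; other groups by the
plain average of their members, labeled by the seed feature.

## Permutation screen

The test statistic for every feature is mean(successes) − mean(failures);
a permutation null makes the same test applicable to continuous, sparse
and binary features alike. When the number of distinct labelings
(product of per-stratum binomial coefficients) is at most `n_perm`, the
null is enumerated exhaustively and p-values are exact fractions;
otherwise `n_perm` shuffles are sampled and the add-one convention
p = (1 + #extreme)/(1 + P) keeps the test valid and the p-value positive.
Comparisons use an absolute slack of 1e−12 so ties are never lost to
floating-point noise. One permutation indicator matrix is drawn per
screening call and shared by all of the dataset's features: each
per-feature p-value remains a valid empirical p, the induced dependence is
covered by the Benjamini–Yekutieli adjustment (which is valid under
arbitrary dependence), and the vectorised matrix product makes full
datasets screenable in milliseconds. BY is applied within each dataset
only; features with adjusted p < α = 0.05 are significant.

The stratified variant shuffles labels only within target-class strata, so
the null preserves each class's success/failure ratio and a feature must
separate outcomes *within* classes to score. Unclassified targets form
one pooled stratum by default (giving each its own stratum would freeze
its label and destroy power); targets listed under several classes keep
their first listed class, since stratification needs a partition.

Note the finite-permutation floor: with m features in a dataset the
smallest attainable BY-adjusted p is roughly m·c(m)/(n_perm·rank), so a
screen at α = 0.05 needs n_perm ≳ 20·m·c(m) to be able to reject at all.
Desk-scale runs in this repository use 1000–20,000 permutations
accordingly; the full-scale procedure used 10⁵.

## Robustness and generalizability

Replication probability of a feature = fraction of bootstrap rounds
(sampling labeled targets with replacement, sample size = resampling pool
size) in which the feature stays significant when the *entire*
within-dataset screen is rerun (same permutation count, same BY family =
the dataset's full representative list, same stratification); pass
threshold 0.8, configurable. Rounds with fewer than two of either outcome
are redrawn (warned above 10%). Three schemes: plain bootstrap;
class-holdout bootstrap whose pool excludes members of outcome-correlated
classes (after class exclusion the reduced set is the natural "original
set", so the bootstrap sample matches its size); and the bootstrap of the
within-class stratified test. Target classes themselves are tested as
binary membership features with the same permutation machinery (BY across
classes as one family), and significant classes are then tested against
significant features via the members-vs-non-members mean difference
(BY across all pairs).

## Nested cross-validation

Outer loop: 5-fold, outcome-stratified (with 72 failures among 331,
unstratified folds can lose a class), repeated 200 times ⇒ 1000 cycles.
Per cycle, with no test-target leakage anywhere:

1. univariate selection per dataset on training targets only — stratified
   permutation test (10⁴ permutations at full scale), BY within dataset,
   adjusted p < 0.05; the *weak* variant accepts nominal p < 0.05 with no
   correction;
2. aggregation — non-human datasets and datasets under 2000 genes are
   excluded; fallback-listed (low-coverage) datasets enter only when
   nothing else survived; targets missing any retained feature are
   dropped; min-max scaling is fitted on training targets (fitting on all
   data would leak); redundancy across the aggregate is removed by greedy
   cosine grouping at r² ≥ 0.5 computed on training rows, with only
   between-dataset pairs eligible to group — within one dataset redundancy
   was already resolved by the kind-appropriate primary reduction, and the
   uncentered cosine of two min-max-scaled mid-range columns is inflated
   (~0.8 for any pair of positive-bulk vectors), which would otherwise
   merge a dataset's own mean/stdv summaries. Each group keeps the feature
   with the smallest training univariate p; ties break toward the larger
   absolute group difference on the min-max scale, the only scale on which
   features from different datasets are comparable;
3. incremental elimination — at each step both model types (logistic
   regression and random forest, class weights inversely proportional to
   class size) are scored by inner stratified 5-fold CV repeated 20 times
   (desk-scale runs shrink folds/repetitions), and the feature with the
   lowest mean random-forest impurity importance is removed (ties: the
   later column). Candidates within 95% of both the maximum inner AUROC
   and maximum inner AUPR qualify; the qualifying logistic regression with
   fewest features wins, else the qualifying random forest with fewest
   features. The regularisation strength (C = 1) and forest size
   (100 trees by default) are package defaults recorded in the config —
   the source procedure states neither;
4. refit on the full training set; probabilities are emitted for test and
   unlabeled targets through the training-fitted scaling. A cycle whose
   univariate step selects nothing is recorded as a null model with empty
   predictions.

## Evaluation

Fold predictions are pooled per repetition before any statistic; the
confusion panel (TP…MCC) uses a 0.5 probability threshold — natural under
class-weighted training, and configurable. Percentile summaries report
the 2.5/50/97.5 points across repetitions. Unlabeled targets receive up
to one prediction per fold per repetition and are averaged to one value
per repetition before density and consistency analyses. For densities,
probabilities are clipped to [10⁻⁶, 1−10⁻⁶], transformed to log-odds,
smoothed with a Gaussian KDE under Silverman's rule, and mapped back with
pdf(x) = pdf(y)·1/(x(1−x)). Cutoff scans use the sorted unique observed
probabilities as the grid; PPV ties resolve toward the cutoff classifying
more targets positive, NPV ties toward more targets negative; the scan
also reports the fraction of repetitions whose NPV at the chosen cutoff
exceeds the historical 0.23 failure rate. Pairwise consistency counts
strict inequalities only, so frac(A,B) + frac(B,A) ≤ 1 with equality for
tie-free scores; pair counts are reported for both separation rules
(median difference ≥ 0.1; fold change ≥ 2) at both consistency thresholds
(0.95, 0.99). The two-feature projection averages, over cycles that
selected both features and kept their fitted model, the predicted success
probability on a grid spanning the min-max-scaled [0,1] plane (which maps
exactly to each feature's observed range), holding any other selected
features at the cycle's training medians; success/failure example
locations are extracted alongside.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *shape* of the study inputs: an asset table
whose filtering and scoring reproduce a configured 259/72 labeled sample
exactly (decoy records exercise every filter); gene × feature matrices of
the three value shapes (per-feature Gaussians for filled-in data, floored
at zero to stay expression-like; zero-inflated lognormals for sparse
data; Bernoulli for categorical data); correlated feature blocks whose
pairwise r² matches a configured value (factor loading `block_r2`^¼ gives
pairwise correlation √`block_r2`); an optional global co-expression
factor (`global_r2`) emulating the broad co-correlation of real tissue
atlases, which is what makes hundreds of tissue features collapse into a
handful of groups around the dataset mean; confounded classes with exact
success/failure composition; and outcome effects planted on a named
feature or on the row-mean/row-SD summaries. Planted effects are
expressed in column-standardized units — the units the downstream summary
features actually carry; a raw-scale row-SD effect would be swamped by
feature-location spread and vanish after standardization — and are
anchored to the realized baseline so the planted success-failure gap
equals δ pooled SDs exactly. Default effect size δ = 0.5 per summary
feature was chosen to match the order of the corrected p-values a screen
of ~330 targets reports for such features (≈10⁻³); the implied
cross-validated AUROC (~0.6) is accordingly modest.

Not emulated: real marginal distributions (expression data are far more
skewed), indication-level outcome structure, missingness patterns beyond
gene coverage, and any dependence between datasets beyond the planted
effects. Passing tests therefore demonstrate that the *procedures* behave
correctly under known truth — FDR control, confound discrimination,
recovery — not that real omics data carry the planted signal.

## Problem sizes and numerical choices

Analysis drivers and tests run scaled-down settings chosen as the package's
own desk-scale defaults: screens at 2×10³–2×10⁴ permutations, bootstraps
at 60–200 rounds, CV at 5 × 20 outer with 3–5-fold inner loops, calibration
at 200 null datasets; the full-scale figures (10⁵ permutations, 1000
bootstraps, 5 × 200 outer / 5 × 20 inner) remain the documented defaults of
the respective functions. Known limitations: the shared permutation
matrix couples p-values within a call (harmless for BY, but the
per-feature Monte-Carlo errors are not independent); enumeration switches
on only when the total labeling count fits in `n_perm`; and replication
probabilities at 60–200 bootstrap rounds carry sampling error of a few
percentage points, so pass/fail calls near the 0.8 threshold are tested
only where the design puts them far from it.
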