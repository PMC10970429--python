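# Methods

This note records the models, parameter choices and numerical
conventions behind `wpcna`, and what the synthetic benchmark does and
does not establish.

## Behavioral outcome

The learning index is the day-2 discrimination fraction `(CE−IE)/TE`
minus the day-1 fraction, so it lies in [−2, 2]; it is undefined (an
error, never silently 0) when a day has no entries. Only daily
aggregates are consumed — the fixed-ratio reward schedule and
within-day event timing carry no information for this statistic. The
categorical learning level bands the z-score of the index against the
cohort at −2, −1, 0, +1 SD, giving levels 1–5. The band edges are a
design choice: the convention guarantees level ≥ 4 exactly when the
index is at or above the cohort mean, which is the positive state the
ROC stage uses. Behavioral outliers are flagged from average-linkage
clustering of the index: an animal is an outlier when it is the last
singleton merged into the tree at a height strictly above every earlier
merge, a formalization of the usual visual call on the dendrogram.

## Network construction

The network is unsigned: similarity is |Pearson r| between peptide
rows, computed over pairwise-complete animals (missing-value policy:
pairs sharing fewer than 4 animals get similarity 0 and a log entry;
rows with fewer than 4 observations or zero variance are dropped
up front). Adjacency raises similarity to an integer power β ≥ 1.
Diagonals follow the WGCNA lineage: S, A and TOM have unit diagonal and
connectivity excludes self (`kᵢ = Σ_{j≠i} aᵢⱼ`).

The scale-free criterion bins connectivity into 10 equal-width bins and
regresses log10 per-bin frequency on log10 bin center over non-empty
bins. Because the regression lives in log–log space, each bin is
represented by the geometric mean of its edges (the log-scale center);
for an exact k⁻² law this representative makes the binned relation
exactly linear with slope −2, which an arithmetic midpoint or the
within-bin sample mean does not. The signed fit index is R² when the
slope is negative and −R² otherwise; `pick_soft_threshold` returns the
smallest power in the grid reaching R² ≥ 0.8 (default), else the argmax
with a warning. Fits using fewer than 3 bins are flagged unreliable.

Topological overlap is computed in matrix form,
`Σ_{u≠i,j} aᵢᵤaᵤⱼ = (A·A)ᵢⱼ − aᵢᵢaᵢⱼ − aᵢⱼaⱼⱼ`, clipped to [0, 1]
against floating-point excursions, and is tested against a
triple-nested-loop evaluation of the definition on random matrices.

## Module detection

Peptides are clustered by average linkage (complete linkage available)
on TOM dissimilarity. Three cuts are offered:

* **static** — one horizontal cut; clusters below `min_module_size`
  become grey.
* **dynamic tree** — a static pre-cut just below the tree top (99% of
  the maximum merge height by default) yields initial clusters, then
  each cluster's branch is recursively split wherever the merge-height
  profile shows a drop-then-rise fluctuation: a branch splits when the
  gap between its merge height and its taller child's internal height
  exceeds `τ = 0.9 − 0.2·deep_split` of the merge height and at least
  one child could form a module. The τ parameterization is this
  package's own; published descriptions of the adaptive cut are
  qualitative, and `deep_split ∈ {0..3}` spans "few large modules" to
  "resolve nested sub-blocks".
* **dynamic hybrid** — the dynamic cores plus a PAM-like stage: a grey
  peptide joins the module with the smallest average dissimilarity to
  its members when that distance is within the module's joining radius
  (the mean member-to-co-member average distance). The mean radius is
  deliberately conservative; a max radius was found to absorb background
  peptides into modules.

Module labels are colors assigned by decreasing size from the standard
palette (turquoise, blue, brown, …), so the largest module is always
"turquoise". `min_module_size` defaults to 20 — small enough that a
21-peptide module survives. Grey is never treated as a module
downstream.

Eigenpeptides: module rows are mean-imputed (per-peptide mean),
z-scored, and decomposed by SVD; the eigenpeptide is the leading right
singular vector (unit norm, zero mean across animals by construction),
sign-oriented to correlate positively with the module mean profile.
Variance explained is s₁²/Σs². A one-peptide module returns its
standardized profile with a warning. Classical (Torgerson) MDS embeds
TOM dissimilarity: double-center −D²/2, take top eigenvectors scaled by
√λ; negative eigenvalues (non-Euclidean input) are dropped with a
warning and requesting more dimensions than positive eigenvalues is an
error.

## Trait statistics and prediction

Peptide significance is signed Pearson r with the learning index
(p from the t distribution on n−2 df, reported for information only —
no multiple-testing correction is applied at the screening stage).
Screening keeps |r| ≥ 0.5 by default (with 1e−12 slack so exactly
collinear peptides survive a threshold of 1). Module significance is
the mean |r| of members. Network screening blends marginal and
module-level evidence,

```
NS_i = α·|cor(x_i, y)| + (1−α)·|cor(ME_m(i), y)|·|kME_i|,   α = 0.5
```

grey peptides keeping only the marginal term. The blend is a
reconstruction — the procedure is named in the WGCNA lineage but no
formula is fixed — so α is exposed and NS reduces to marginal screening
at α = 1 and a pure network score at α = 0.

ROC: AUC by Mann–Whitney pair counting (ties ½), Hanley–McNeil SE with
Q₁ = A/(2−A), Q₂ = 2A²/(1+A), 95% CI clipped to [0, 1], two-sided p
from a normal approximation with the null SE evaluated at A = 0.5, and
K-S = max over thresholds of |TPR − FPR| (equal to the two-sample
Kolmogorov–Smirnov statistic between class score samples). Exact
small-sample ROC inference is out of scope; the asymptotic machinery
matches the convention of standard statistical packages at n = 20. The
logistic fit of binary learning state on eigenpeptides is capped at 3
predictors near n = 20 and reports separation as a flag instead of
diverging.

## Candidates

Cumulative distance is the signed sum of a focal animal's intensity
minus three comparison-group means (blast-transgenic, sham-transgenic,
sham-non-carrier by default); the focal animal is excluded from its own
group's mean (configurable), since published group-size conventions for
this statistic are ambiguous. Candidates sort by |cumulative distance|
(the signed value and a direction column are kept) with lexicographic
tie-breaks. Group differential tests are pooled-variance two-sample
t-tests; the effect defaults to the difference of group means of log2
intensities, with the literal ratio of mean log2 intensities available
behind a flag. Zero-variance shifts are flagged with p = 0 rather than
propagating a degenerate t. The integrative rank sums, over five
genotype × exposure contrasts, the descending rank of |log2FC| and of
−log10 p (average ranks on ties; the p-rank depends only on the p-value
ordering). Five default contrasts cover blast-vs-sham within each
genotype and the three cross-genotype comparisons; the set is
configurable and a count other than five requires an explicit override.

## Synthetic data

Each planted module follows a single-factor Gaussian model:
`x = baseline + noise_sd·(√ρ·f + √(1−ρ)·ε)` with factor f ~ N(0,1) over
animals, so expected within-module correlation is ρ and the rank-1
eigenpeptide summary is exactly the estimand. Defaults define the
benchmark: 20 animals in groups (5, 5, 6, 4), 1000 peptides, three
modules of 120/60/40 at ρ = 0.6, the first module's factor correlated
0.7 with the learning index, log2 baselines ~ N(20, 2), noise SD 1,
2% missingness (completely at random, never blanking a whole row or
column). The learning index is mapped to mean 0.4 and SD 0.3 — a
plausible CognitionWall cohort — and entry logs are built by inverting
the per-day fraction (±index/2 on days 1/2, 200 entries/day), so
recomputing the index from counts reproduces the simulated value to
within rounding (≤ 2/TE).

What the generator does not emulate: heavy-tailed intensity
distributions, intensity-dependent missingness, correlated background
peptides, batch structure, or overlapping modules. Passing the planted
benchmark therefore shows the machinery is correct and calibrated under
a clean factor model, not that module recovery will reach the same ARI
on real phosphoproteomes.

## Problem sizes and determinism

The standard benchmark (20 studies of 1000 peptides × 20 animals) was
chosen so the full recovery analysis completes in seconds on one core
while leaving Monte-Carlo error on the reported rates near ±10 points;
oracle checks use 20 random matrices (sizes 10–100) and 50 random
modules. All simulation and analysis randomness flows through explicit
integer seeds; identical seeds give bit-identical studies, module
assignments and manifests. `scripts/acceptance.py` derives every stream
from its `--seed` argument.

## Known limitations

* The dynamic tree cut is a height-profile reconstruction, not a port
  of the reference implementation; on identical data the module
  boundaries can differ in detail even when both recover the planted
  partition.
* Pairwise-complete correlations can make S (hence TOM) slightly
  non-positive-definite at high missingness; downstream steps only
  require symmetry and [0, 1] entries.
* Screening, detection and ROC are fit in-sample on ~20 animals, as in
  the target study design; no cross-validation is offered, so reported
  AUCs are optimistic for prediction on new animals.
* An externally supplied eigenpeptide table can be re-scored with
  `wpcna.pipeline.reproduce_reported_prediction`; published per-animal
  appendix tables are not bundled and must be provided by the user.
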