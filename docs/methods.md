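# Methods

This note documents the statistical procedures implemented in `methclass`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-cohort generator does and does not emulate, and the design
choices made where the design was genuinely open.

## 1. Class discovery

**Panel selection.** Sites with missingness above `max_missing_frac`
(default 0.2) are dropped; the remaining sites are ranked by sample
variance of β (missing values ignored) and the top `fraction` (default
0.01) kept. Panel size is `round(fraction × n_evaluable)`; ties in
variance break by site id ascending so the panel is deterministic.
Variance on the β scale (rather than SD, MAD or M-values) is the simplest
reading of "most variable"; an M-value panel can be emulated by
transforming the matrix before construction.

**Consensus clustering.** Each of `n_resamples` (default 1,000) resamples
draws ⌈0.8·n⌉ samples without replacement, computes 1 − Pearson distance
between samples over the panel (pairwise-complete when values are
missing; undefined correlations map to distance 1), builds average-linkage
hierarchical clustering and cuts it at every candidate k. The consensus
matrix is the co-clustering count divided by the co-sampling count; it is
symmetric with unit diagonal by construction, and a sample pair that is
never co-sampled is an error rather than a silent zero. Final labels per k
come from average-linkage clustering of 1 − consensus. The only random
element is the per-resample index draw (one `choice` call per resample
from `default_rng(seed)`), which makes the resample stream replayable by
an independent oracle — the test suite exploits this.

**Choice of k.** For each k we compute the area under the empirical CDF
of off-diagonal consensus values and the relative delta-area
(A(k) − A(k−1))/A(k−1). Scanning k upward, the chosen k is the last one
before the first relative gain below `threshold` (default 0.025). Two
caveats discovered during development and handled explicitly:

* On data whose clusters contain internally *stable* sub-structure the
  delta-area keeps growing past the true k — this is a property of the
  criterion, not a bug; the delta-areas for all k are always reported so
  the curve can be inspected.
* On featureless data the consensus never sharpens and delta-areas remain
  large at every k. We therefore compute PAC (the fraction of consensus
  values in (0.1, 0.9)) at the delta-area choice; if PAC > 0.4 the run is
  flagged `weak_structure` and the smallest candidate k is returned, since
  no larger k is supported by stable co-clustering.

**Ordering and naming.** Clusters are ranked by mean β over the panel;
for k = 4 the ascending order is named DEM, LOW, INT, CIMP, otherwise
C1 < … < Ck. Ties in cluster means (within 1e−9) break by smallest member
sample id and are logged. The merged grouping is fixed:
{DEM, LOW} → DEM+LOW, {INT, CIMP} → INT+CIMP.

## 2. Transfer classification

The centroid model stores per-class mean β (missing ignored) over the
discovery panel; training requires at least two samples per class. A new
sample is assigned to the centroid with the smallest 1 − Pearson distance
over the shared non-missing panel sites, with the margin (second-best
minus best distance) reported as a confidence measure. Samples sharing
fewer than `min_shared_sites` sites (default: half the panel; pass an
absolute number to override) are returned as `unclassifiable` rather than
raising. Exact distance ties resolve to the lower-β class and are flagged
`tie`. The model serializes to versioned JSON and round-trips exactly.
Nearest-centroid with correlation distance was chosen because it is
robust to per-sample affine shifts in β (e.g. global purity effects) and
has no tuning parameters.

## 3. Methylation–expression integration

**Region aggregation.** Region β is the (optionally coverage-weighted)
mean of member-site β, missing ignored; regions with fewer than
`min_sites` informative members are missing. Membership uses 0-based
half-open intervals. When no promoter map is available, a TSS-window
builder (−1,500/+500 bp around the TSS, strand-aware) is provided; the
window is a stated convention, not a biological claim.

**Differential methylation.** One-vs-rest Wilcoxon rank-sum per region
with Δβ = mean(group) − mean(rest). Exact p-values are used for tie-free
groups of ≤ 12, the normal approximation otherwise; fully tied features
get p = 1 and a `degenerate` note; features with fewer than 3 non-missing
values on either side are skipped. Flags: `hypo` if Δβ ≤ −0.1 and BH
q ≤ 0.05, `hyper` symmetric. The Δβ threshold of 0.1 is a conventional
"visible on the β scale" effect floor and is configurable.

**Differential expression.** Welch t per gene on normalized (log-scale or
z-space) expression, plus a label-permutation p (exhaustive over all
distinct splits whenever that costs no more than `n_perm` evaluations,
Monte Carlo otherwise, default 10,000) and BH q. A gene is `significant`
only if p ≤ 0.001, q ≤ 0.01 and permutation p ≤ 0.01 simultaneously — a
deliberately strict three-criterion filter of the kind used for
upstream-regulator input lists; all three thresholds are parameters.

**Quadrants and over-representation.** Genes cross significant expression
direction with significant methylation flag into `up_hypo`, `down_hyper`,
`up_hyper`, `down_hypo` or `none`; a gene with several promoters uses the
most significant one (logged). Over-representation of a quadrant against
a gene-set collection is the one-sided hypergeometric tail
P(X ≥ overlap) with BH across sets; the category must be a subset of the
declared background (the tested gene universe, never "all genes ever").

## 4. Signature analytics

**Scores.** Expression is z-scored per gene *within the scoring cohort*
(cross-cohort z-scores are deliberately not supported — mixing cohorts
makes the median split meaningless). A signature score is the per-sample
median z over the signature genes present; signatures with fewer than
`min_genes` (default 3) present genes are skipped with an explicit
status, and missing genes are always reported. Median (not mean) makes
the score robust to a single extreme gene.

**Dichotomy and association.** HI/LO at the cohort median with ties → LO
(so LO is never the smaller side by construction). Class association is a
Pearson chi-square without continuity correction, df = (r−1)(c−1);
expected counts below 5 trigger a warning, empty classes are dropped.

**Preranked GSEA.** Genes are ordered by the ranking statistic descending
with ties broken by gene id, so ranks are unique and deterministic. ES is
the signed maximum deviation of the weighted Kolmogorov–Smirnov running
sum (hit increments |stat|^weight normalized within the set, miss
increments 1/(N − |set|)). The null resamples gene sets of the same size
from the ranked universe (exhaustively when cheaper than `n_perm` draws);
NES = ES / mean(|null ES| of the same sign) and the p-value is two-sided
over the full null. A gene-resampling null (rather than phenotype
permutation) is the only option compatible with consuming preranked
statistics; this divergence from sample-permutation GSEA is intentional
and means NES values are not directly comparable to tools that permute
phenotypes. The default ranking statistic is the Welch t.

**Upstream-regulator activation.** For a regulon (targets with expected
direction ±1) and a set of significant signed effects, a target is
consistent when observed × expected = +1 and
z = (n_consistent − n_inconsistent)/√(n_consistent + n_inconsistent).
This signed-consistency score is an *approximation* of commercial
activation-z tools — outputs are labeled `activation_z_approx` — and
regulators with fewer than 4 usable targets are "not scored". |z| = √n
when all targets agree and 0 on a perfect split.

**Correlation-filtered signatures.** To distill a coherent signature from
a candidate list using two cohorts: per cohort, all pairwise Spearman
correlations among candidates; per gene, the mean pairwise ρ and the
median of its pairwise p-values, BH-adjusted across genes; retained iff
mean ρ > 0 and adjusted p ≤ α in *both* cohorts. The gene-level
retention rule (mean ρ + median-p combination) is one reasonable
interpretation among several; it is isolated in a single function so an
alternative rule can be swapped in, and the full per-pair matrices are
emitted for audit.

## 5. Survival and progression

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
`lifelines` (events precede censorings at tied times; df = k − 1); the
test suite verifies both against hand product-limit and
observed-minus-expected/hypergeometric-variance oracles, and checks the
asymptotic log-rank p against an exact permutation p on small instances.
Median follow-up is the plain median of follow-up times with the range,
matching the usual "median (range)" reporting; a reverse-KM variant is
available. Units are patient-centric: a patient with lesions in different
classes is counted once under the worst (highest-β) class, logged — the
choice is a declared convention. The progression analysis is the
class × progressed/not-progressed contingency table (Pearson chi-square,
df = classes − 1), per-class progression percentages, each class's share
among non-progressors (sums to 100%), and a CNS breakdown counting final
stage IVM1D. Multivariable Cox modeling and competing risks are out of
scope.

## 6. The synthetic-cohort generator

The generator plants exactly the structure the pipeline is designed to
detect, with defaults chosen as the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| n_samples | 160 (40/class) | cohort size |
| n_sites | 20,000 | CpG sites (island_fraction 0.3) |
| n_informative_sites | 2,000 | island sites carrying class signal |
| class mean β (informative) | 0.05 / 0.15 / 0.35 / 0.60 | DEM / LOW / INT / CIMP |
| κ | 20 | Beta-distribution concentration |
| purity | U(0.6, 1.0) | linear mixing with normal profile (island 0.1, open-sea 0.8) |
| coupled genes | 500 of 5,000 | promoter-β ↔ expression anticorrelation |
| immune genes | 100 | +1 z-unit mean shift in LOW |
| hazard ratios vs LOW | DEM 1.8, INT 2.0, CIMP 2.8 | exponential, baseline median 60 months |
| progression probs | 0.80 / 0.62 / 0.75 / 0.83 | per class; CNS among progressors 0.31 / 0.15 / 0.23 / 0.32 |
| censoring | U(1.9, 194.3) months | administrative |

**Site architecture.** Pure-tumor mean β at informative site *i* in class
*c* is `hypo + span·σ(−t_i/τ + f_ic + b_c)` with a shared susceptibility
gradient t_i (τ = 0.15), independent per-class site fingerprints
f_ic ~ N(0, 2²) on the logit scale, and class propensities b_c solved by
root-finding so each class's mean over informative sites equals its
configured value *exactly*. The gradient makes the classes globally
ordered (the CpG-island hypermethylation gradient); the fingerprints give
each class a reproducible site profile, without which within-class
samples would share only a flat mean shift and correlation-based
clustering would — correctly — see nothing. Effect sizes are not
prescribed by any external source; they were chosen once to make class
recovery non-trivial but achievable, and the calibration tests pin them.

**Architecture vs cohort randomness.** Everything genomic (island/open-sea
status, t_i, fingerprints, promoter coordinates, coupled/immune gene
identity) derives from `architecture_seed` (a config field), while
per-sample draws derive from the `seed` argument. Two cohorts simulated
from the same config therefore share their genome — which is what makes
centroid transfer between cohorts meaningful — and class membership,
noise, purity and outcomes are cohort-specific.

**Expression.** Coupled genes get z = −(promoter β standardized) + noise
(sd 0.75), giving a median promoter–expression Spearman ρ ≈ −0.75;
non-coupled genes are standard normal (their null |ρ| against arbitrary
promoters has median ≈ 0.05 at n = 160, which the tests bound rather than
assert to zero). Purity is *not* applied to expression — a simplification;
real bulk expression is also a mixture.

**What it does not emulate.** Read-level sequencing noise and coverage
heterogeneity; batch effects; copy-number or mutational structure;
correlated missingness; immune-contexture deconvolution ground truth;
association between progression and survival (the two endpoints are
sampled independently per class — a documented simplification); relapse
endpoints for adjuvant cohorts. Passing tests on this generator therefore
demonstrates correctness of the statistical machinery and recoverability
of planted structure, not robustness to every artifact of real RRBS data.

**Calibration caveat.** Observed β is purity-mixed, so class means at
informative sites match the configured values only at purity 1; the
calibration tests set `purity_range=(1, 1)` for that reason, and the
default-purity cohort checks ordering rather than absolute levels.

## 7. Numerical and reproducibility choices

* Missing β is NaN everywhere, never 0; β = 0 is a valid measurement.
* Coordinates are 0-based half-open internally; Bismark coverage files
  (1-based inclusive) are converted on read, and β is always recomputed
  from counts, never trusted from the percentage column.
* All stochastic routines take an explicit seed; the pipeline derives
  every stage's randomness from the single config seed. TSV outputs use a
  fixed float format, so identical config + seed reproduces byte-identical
  files (verified by checksum in the run manifest; a cached stage whose
  output checksum changed raises an error naming the file).
* BH adjustment is used for all multiple testing, matching the FDR
  conventions of the field; Bonferroni is deliberately not offered.
* Test problem sizes: consensus clustering in the test suite uses 200
  resamples (1,000 in the library default) and the permutation tests use
  enumerable instances or 1,000 draws; these sizes were chosen so the
  whole suite completes in about a minute while keeping every check's
  Monte-Carlo error far below its assertion margin.
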