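# Methods

## The problem

Multi-cohort biomedical tables are *globally rich but locally deficient*:
pooled across cohorts the feature namespace is large, yet each cohort
measures only a subset of it. A feature absent from a cohort is
**structurally missing** there — unmeasured for every sample, unlike the
sporadic holes that ordinary missing-data methods assume. Naively
row-completing the merged table discards almost everything ("the more
seawater you drink, the thirstier you get"); imputing the structural blocks
manufactures artifacts (see below). The alternative implemented here is
pairwise: for each pair of features, use every sample from every cohort
that observes both, test the association with a statistic appropriate to
the two data types, and map all of those heterogeneous raw results onto one
calibrated p-value scale so that the whole pairwise screen can be ranked
and FDR-controlled as a single family.

## Raw tests and the type-pair mapping

Features are `numeric`, `ordinal`, `nominal` or `binary`. The ten
unordered type combinations are served by five classical tests:

| pair | test |
|---|---|
| numeric × numeric | Spearman rank correlation (tie-corrected t approximation) |
| numeric × ordinal | Spearman, ordinal integer-coded by declared level order |
| numeric × binary | Wilcoxon–Mann–Whitney rank sum |
| numeric × nominal | one-way location test across groups |
| ordinal × ordinal | linear-by-linear association, M² = (N−1)r², integer scores |
| ordinal × binary | linear-by-linear on the 2×L table |
| ordinal × nominal | one-way, ordinal integer-coded as the response |
| nominal × nominal | Pearson chi-square, no continuity correction |
| nominal × binary | chi-square |
| binary × binary | chi-square |

The mapping keeps ordering information wherever both features carry it and
is configurable (YAML override in the CLI, a dict in the library), since
reasonable alternatives exist for several cells.

Numerical conventions: ordinal scores are consecutive integers 0..L−1 in
declared level order; the binary positive level (declared, else the
lexicographically larger label) is coded 1. The "one-way test" is Welch's
variance-heterogeneity-robust F with Welch–Satterthwaite denominator
degrees of freedom (classic ANOVA available via `oneway_variant="classic"`);
the Mann–Whitney p uses the tie-corrected normal approximation without
continuity correction inside the unified engine, and the exact small-sample
distribution when called standalone on small untied samples. The
chi-square testability guard is the standard expected-count rule (all
E ≥ 1 and ≥ 80 % of cells with E ≥ 5); pairs failing it — like pairs with a
constant member, with under-sized groups (< 2 per group), or with fewer
pooled complete pairs than `min_n` (default 20) — are reported
**non-testable** rather than forced through an invalid approximation.

## The unified p-value

For a pooled pair with raw p-value `p_raw`:

1. score the observed result, `s_obs = Φ⁻¹(1 − p_raw)` (probit);
2. build a negative-control distribution by resampling: permute one margin
   of the pooled pair B times (default 1000), recompute the raw test each
   time with the same arithmetic, and score each permuted result the same
   way;
3. standardise: `z = (s_obs − mean(s_null)) / sd(s_null)`;
4. report the upper-tail normal probability `p = 1 − Φ(z)`.

Permutation of one margin breaks the association while preserving both
marginal distributions exactly, which is the canonical negative control
for a dependence test; bootstrap resampling with replacement is available
via `resample_scheme="bootstrap"` for sensitivity analysis.

**Why the probit score.** The Z-test in step 3 is only calibrated if the
null score distribution is approximately normal. Under the null, `p_raw`
is near-uniform, so `−log10 p` is near-exponential — standardising an
exponential and reading a normal tail misstates every quantile (the
implied type-I error at nominal 0.05 is ≈ 0.07, and the p-value ECDF sits
≈ 0.13 from uniform at the median). The probit transform makes the null
scores near-standard-normal by construction, so the same
score → moments → Z-test architecture yields a calibrated uniform unified
p-value, which the acceptance suite verifies for all ten type combinations
(empirical type-I at 0.05 within (0.03, 0.07), KS distance < 0.08 at
n = 200, B = 1000, 500 replicates). `neglog10_p` and raw-`statistic`
scores remain available as config options for sensitivity analysis, with
the caveat above.

Degenerate control distributions (sd = 0) yield p = 1 when the observed
score does not exceed the control, and the resampling floor 1/(B+1) when
it does. Raw p-values are clipped to [1e−300, 1 − 1e−9] before the probit
so that discrete tests attaining p = 1 keep a finite score. The normal
tail deliberately extrapolates beyond the 1/B resolution of the
permutation sample; that is what makes genome-scale FDR control at small
thresholds possible with a desk-scale B.

Reproducibility: each pair's resampling stream is derived from the master
seed plus the sorted feature-name pair (BLAKE2 digest), so results are
bitwise identical regardless of iteration order or thread count, and a
pair's result is invariant to which unrelated features sit in the
collection.

Multiple testing: Benjamini–Hochberg over all testable pairs of a run
(one family), via `statsmodels.stats.multitest`; non-testable pairs carry
no q-value.

## Polarity

When both features are orderable (numeric; ordinal by level order; binary
by positive level; 2-level nominal by sorted labels), the association sign
is the sign of the Spearman correlation of the coded values; an exactly
zero correlation is reported positive with a warning, for determinism.
Any nominal feature with more than two observed levels makes polarity
"not applicable" — there is no order to be monotone against.

## The dependency network and modules

Testable pairs with q below the threshold (default 0.01) become edges of
an undirected simple graph whose nodes are features; edges carry the sign
annotation. Signs and edge weights do not influence clustering — passing
edges are treated uniformly (a −log10 q weighted variant sits behind a
flag). Modules are found divisively (Girvan–Newman): repeatedly delete
the edge with the highest betweenness (recomputed after every deletion,
ties broken by the lexicographically smallest node pair), and across the
resulting dendrogram — from the initial connected components down to
singletons — keep the partition with maximal Newman–Girvan modularity Q
(earliest partition on ties). On graphs small enough to enumerate every
set partition, the returned partition agrees with the exhaustive Q
optimum whenever the dendrogram contains it. Isolated nodes are excluded
from the partition and reported separately, as modularity is undefined for
them.

Module significance is a permutation test against a degree-preserving
null: each of `n_perm` null graphs is produced by double-edge swaps
(10·|E| attempted swaps), re-clustered with the same procedure, and
p = (1 + #{Q_null ≥ Q_obs}) / (1 + n_perm). The default n_perm = 10 000
makes p-values down to 1e−4 attainable; tests and the acceptance script
use 999 for runtime. Graphs with fewer than two edges cannot be rewired
and return p = 1 with a warning.

### Indirect association via pivot features

When two features are never co-observed (no cohort covers both), their
direct association is non-testable. If both associate strongly with
shared "pivot" features that every cohort measures, module detection can
still place them together: the pivot edges hold the block together in the
graph even though the direct edge cannot exist. The
`synthetic.pivot_scenario` topology encodes exactly this situation (roles
U, P, V per block; U and V never co-observed) and the acceptance suite
requires the planted blocks to be recovered exactly (ARI = 1) in ≥ 95 % of
seeds at ρ = 0.6 with three cohorts of 300 samples.

## Synthetic data generator

All planted dependence flows through a latent Gaussian copula: one
multivariate normal draw per sample with a block-structured correlation
matrix (within-block ρ, optional cross-block ρ; positive definiteness is
checked before sampling). Rendering per type: numeric keeps the latent;
ordinal/binary threshold it at equiprobable normal quantiles (levels
ordered with the latent); nominal features let their latent compete with
k−1 independent standard normals and take the argmax as the level — the
block signal is carried with no induced order and each level keeps
marginal probability 1/k by symmetry. Structural missingness comes from
per-cohort covered-feature sets; an additional uniform missing rate thins
covered cells; an optional per-cohort latent mean shift (off by default)
emulates batch effects. Cohorts are sample-disjoint and drawn from
spawned seed streams, so a collection is reproducible from its spec alone.

What the generator does *not* emulate: realistic clinical marginals
(skewed sizes, rare categories), inter-feature dependence that is not
monotone-through-a-latent, informative missingness, record overlap across
cohorts, or cohort-specific measurement scales. Passing tests therefore
demonstrate the statistical machinery under controlled dependence, not
robustness to every pathology of real registry data.

## KNN-imputation comparison

`KNNCohortImputer` deliberately reproduces the standard workflow a
practitioner would apply to the merged table: stack all cohorts over the
union of numeric features, z-score each column, fill each missing cell
with the distance-weighted mean of the k nearest rows under nan-aware
Euclidean distance (sklearn's `KNNImputer`), and un-scale. Observed values
are never altered; categorical features are not imputed.

The stress scenario plants pairs (A, B) of mutually independent numeric
features that a donor cohort observes and a query cohort does not; the
query cohort shares only "carrier" features with the donors. Both members
of each pair are then reconstructed from the *same* donor neighbourhoods:
the imputed A and imputed B of a query sample are local averages over one
shared set of neighbours, i.e. two smooth functions of the same carrier
position, and two independent smooth functions sampled at many points are
spuriously correlated far in excess of 1/√n. The false-association rate
of the unified test at α = 0.01 inflates by an order of magnitude in this
scenario (≈ 0.7 % → ≈ 11 % at the default sizes), while testing only the
genuinely observed data keeps the nominal rate — the reason this pipeline
pools rather than imputes structural blocks.

## Default parameters

| parameter | default | role |
|---|---|---|
| `resamples` (B) | 1000 | control-distribution size; tail beyond 1/B via normal extrapolation |
| `min_n` | 20 complete pairs | guards the asymptotic raw tests |
| `score_transform` | `probit` | calibrated unified scale (see above) |
| `resample_scheme` | `permutation` | exact preservation of both marginals |
| `fdr_alpha` | 0.01 | edge threshold for the network |
| `min_group` | 2 | smallest group size for group-based tests |
| `n_perm` (modules) | 10 000 | resolution 1e−4 for module significance |
| KNN `k` | 10, distance-weighted | standard imputation practice |

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale study conditions: calibration at n = 200, B = 1000,
500 replicates per type combination; power curves at ρ ∈ {0.1, 0.3, 0.5},
n = 200, 100 replicates; pooling benefit with two cohorts of 150 at
ρ = 0.3; module recovery over 20 seeds of the two-block pivot topology
(ρ = 0.6, three cohorts of 300) with 999 rewiring permutations; the
imputation stress scenario with 150 null pairs (three seeds of 50). The
acceptance script re-runs the same computations at moderately reduced
replicate counts and reports the measured quantities; nothing it prints is
hard-coded.

## Known limitations

* The unified p-value calibration inherits the quality of each raw test's
  p-value at the pooled n; very sparse categorical pairs are excluded by
  the guards rather than rescued.
* Only unconditional pairwise dependence is measured — no partial
  correlations or conditional independence, so a module can be held
  together by a shared driver.
* Pooling assumes cohorts are sample-disjoint and exchangeable for each
  pair; cohort-specific measurement bias is not modelled (the optional
  latent shift in the generator exists to study it, not to correct it).
* Girvan–Newman recomputes exact edge betweenness after every removal
  (O(|V||E|) per removal), fine for feature networks of tens to hundreds
  of nodes, not for thousands; the dendrogram search is also restricted to
  partitions the divisive procedure visits.
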