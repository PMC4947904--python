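# bufam

Unified pairwise association screening across **heterogeneous, multi-cohort
feature tables**, and signed **relational dependency networks (RDN)** with
modularity-based module detection.

## The problem

Pooled biomedical data (research cohorts, registries, EMR extracts) is
globally feature-rich but locally deficient: each cohort measures only a
slice of the shared feature namespace, so features absent from a cohort are
*structurally missing* — unmeasured for every one of its samples. Merging
cohorts and keeping complete rows throws almost everything away; imputing
the structural blocks manufactures false associations. This package takes
the pairwise route instead:

* for every pair of features, pool the samples of **all** cohorts that
  observe both, and test with a statistic matched to the two data types
  (numeric / ordinal / nominal / binary → Spearman, Welch one-way,
  chi-square, Wilcoxon–Mann–Whitney, or linear-by-linear);
* re-express each raw result on one calibrated scale: score the observed
  p-value by its probit, build a negative-control score distribution by
  permuting one margin of the pooled pair B times, and report the
  upper-tail Z-test p-value
  `p = 1 − Φ((s_obs − mean(s_null)) / sd(s_null))`;
* Benjamini–Hochberg over all testable pairs, build the signed network
  from edges with q < 0.01, and detect modules by Girvan–Newman divisive
  clustering (max-modularity partition of the dendrogram), with module
  significance from a degree-preserving rewiring null.

Because the unified p-value lives on one scale for every data-type
combination and sample size, the whole screen can be ranked and
FDR-controlled as a single family — and module membership can link
features that *no cohort co-observes*, through shared "pivot" features.

For the model details, defaults and limitations see
[docs/methods.md](docs/methods.md).

## Worked example

A planted two-block scenario with the pivot coverage topology: 12 features
in two latent-correlation blocks (ρ = 0.6), three cohorts of 300 samples
whose coverage never co-observes the U and V members of a block:

```python
from bufam import BufamProfiler, build_rdn, girvan_newman_modules, module_significance
from bufam.synthetic import pivot_scenario

collection, truth, spec = pivot_scenario(rho=0.6, n_per_cohort=300, seed=1)
profiler = BufamProfiler(resamples=1000, seed=1).fit(collection)
print(profiler.frame_[["feature_a", "feature_b", "test", "n", "p_bufam", "q_fdr",
                       "direction", "testable"]])
```

The strongest pairs and two never-co-observed pairs look like:

```text
feature_a feature_b     test   n      p_bufam        q_fdr      direction  testable
      f08       f10 spearman 600 1.021602e-59 5.108008e-58       positive      True
      f02       f03 wilcoxon 900 4.325663e-57 1.081416e-55       positive      True
      f08       f09 wilcoxon 900 1.591273e-53 2.652122e-52       positive      True
      f02       f04 spearman 600 1.238518e-51 1.548148e-50       positive      True
      f00       f04 spearman   0          NaN          NaN not_applicable     False
      f00       f05   oneway   0          NaN          NaN not_applicable     False
```

50 of the 66 pairs are testable (the 16 gray pairs have no co-observing
cohort); `n` is the pooled supporting-sample count — 900 when all three
cohorts cover a pair, 600 or 300 otherwise. Network and modules:

```python
graph = build_rdn(profiler.results_, q_threshold=0.01, descriptors=collection.descriptors)
partition = girvan_newman_modules(graph)
p = module_significance(graph, partition.modularity_q, n_perm=999, seed=1)
print(partition.modules(), partition.modularity_q, p)
```

```text
[{'f00', 'f01', 'f02', 'f03', 'f04', 'f05'}, {'f06', 'f07', 'f08', 'f09', 'f10', 'f11'}]
Q = 0.5   module permutation p = 0.001
```

The 22 passing edges split into exactly the two planted blocks
(modularity Q = 0.5, rewiring-null p = 1/1000): module detection reunited
f00/f01 with f04/f05 although their direct association was never testable
— the pivot features f02/f03 carry the link.

The same pipeline is available from the shell:

```bash
bufam simulate  --spec spec.yaml --out-dir data/
bufam associate --cohorts data/c1.tsv --cohorts data/c2.tsv --cohorts data/c3.tsv \
                --meta data/metadata.tsv --out assoc.tsv --resamples 1000 --seed 1
bufam network   --associations assoc.tsv --fdr 0.01 --out-prefix net --meta data/metadata.tsv
bufam modules   --graph net.graphml --permutations 10000 --seed 1 --out-prefix modules
bufam evaluate  --scenario imputation --out artifact.tsv --seed 1
```

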