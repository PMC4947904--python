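"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from bufam.data_model import FeatureDescriptor, PairedSample


def make_pair(x, y, feature_a="a", feature_b="b", cohort="c1") -> PairedSample:
    x = np.asarray(list(x), dtype=object)
    y = np.asarray(list(y), dtype=object)
    return PairedSample(
        feature_a,
        feature_b,
        x,
        y,
        np.full(len(x), cohort, dtype=object),
        np.asarray([f"s{i}" for i in range(len(x))], dtype=object),
    )


@pytest.fixture
def numeric_desc():
    return FeatureDescriptor("a", "numeric"), FeatureDescriptor("b", "numeric")


# ---------------------------------------------------------------------------
# independent oracles


def bh_oracle(pvalues):
    """Benjamini-Hochberg q-values straight from the definition:
    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def mwu_exact_oracle(group1, group2):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled untied values to the two groups."""
    from scipy.stats import rankdata

    pooled = np.concatenate([group1, group2])
    n1 = len(group1)
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    total = 0
    extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum()
        total += 1
        if abs(r - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def modularity_oracle(graph, partition):
    """Newman-Girvan Q from its definition: sum over modules of
    (within-edge fraction) - (degree fraction / 2)^2."""
    m = graph.number_of_edges()
    q = 0.0
    for module in partition:
        within = sum(1 for u, v in graph.edges() if u in module and v in module)
        degree = sum(d for node, d in graph.degree() if node in module)
        q += within / m - (degree / (2 * m)) ** 2
    return q


def all_partitions(items):
    """Every set partition of ``items`` (exhaustive; only for tiny inputs)."""
    items = list(items)
    if not items:
        yield []
        return
    head, *rest = items
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] | {head}] + smaller[i + 1:]
        yield smaller + [{head}]
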