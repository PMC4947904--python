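"""Signed relational dependency network and modularity-based module detection.

Features are nodes; unified associations passing the FDR threshold are
undirected edges annotated with polarity ("+", "-", or "NA" when a nominal
feature is involved).  Modules are detected with the divisive Girvan-Newman
procedure: repeatedly remove the edge of maximal betweenness (recomputing
after each removal) and keep the dendrogram partition of maximal
Newman-Girvan modularity Q.  Module significance is assessed against a
degree-preserving rewired null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from sklearn.base import BaseEstimator

from .core import AssociationResult
from .data_model import FeatureDescriptor

__all__ = [
    "build_rdn",
    "girvan_newman_modules",
    "module_significance",
    "export_rdn",
    "import_rdn",
    "ModulePartition",
    "GirvanNewmanModules",
]

_SIGN = {"positive": "+", "negative": "-", "not_applicable": "NA"}


@dataclass
class ModulePartition:
    """A partition of the non-isolated nodes of an RDN into modules.

    ``assignment`` maps feature -> module id (0..k-1, modules numbered by
    their lexicographically smallest member).  ``isolated`` lists degree-0
    nodes, which are excluded from the partition (modularity is undefined
    for them).  ``p_perm``/``n_perm`` are filled by
    :func:`module_significance`.
    """

    assignment: dict[str, int]
    modularity_q: float
    isolated: tuple[str, ...] = ()
    p_perm: float | None = None
    n_perm: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, mid in self.assignment.items():
            out.setdefault(mid, set()).add(node)
        return [out[mid] for mid in sorted(out)]


def build_rdn(
    results: list[AssociationResult],
    q_threshold: float = 0.01,
    descriptors: tuple[FeatureDescriptor, ...] | None = None,
) -> nx.Graph:
    """Build the signed RDN from FDR-adjusted association results.

    Nodes are all features appearing in any testable result; edges are the
    testable results with ``q_fdr`` strictly below ``q_threshold``, carrying
    the association sign, the unified p-value and the q-value.
    """
    g = nx.Graph(q_threshold=float(q_threshold))
    dtypes = {d.name: d.dtype for d in descriptors} if descriptors else {}
    for r in results:
        if not r.testable:
            continue
        for name in (r.feature_a, r.feature_b):
            if name not in g:
                g.add_node(name, dtype=dtypes.get(name, ""))
        if r.q_fdr is not None and r.q_fdr < q_threshold:
            g.add_edge(
                r.feature_a,
                r.feature_b,
                sign=_SIGN.get(r.direction, "NA"),
                p_bufam=float(r.p_bufam),
                q_fdr=float(r.q_fdr),
            )
    return g


def _most_valuable_edge(g: nx.Graph, weight: str | None) -> tuple:
    bc = nx.edge_betweenness_centrality(g, weight=weight)
    best = max(bc.values())
    candidates = [tuple(sorted(e)) for e, v in bc.items() if v >= best - 1e-12]
    return min(candidates)


def _dendrogram_partitions(g: nx.Graph, weight: str | None):
    """Initial components followed by every Girvan-Newman split."""
    yield tuple(frozenset(c) for c in nx.connected_components(g))
    mve = lambda graph: _most_valuable_edge(graph, weight)
    for level in nx_community.girvan_newman(g, most_valuable_edge=mve):
        yield tuple(frozenset(c) for c in level)


def girvan_newman_modules(g: nx.Graph, weighted: bool = False) -> ModulePartition:
    """Divisive edge-betweenness module detection, keeping the max-Q partition.

    Ties in edge betweenness are broken by the lexicographically smallest
    (a, b) pair and ties in Q by the earliest (coarsest) partition, so the
    result is deterministic.  Isolated nodes are left out of the partition
    and reported separately.  Raises on edgeless graphs.
    """
    if g.number_of_edges() == 0:
        raise ValueError(
            "RDN has no edges; nothing to cluster (relax the FDR threshold upstream)"
        )
    isolated = tuple(sorted(n for n, d in g.degree() if d == 0))
    core = g.subgraph([n for n in g if n not in set(isolated)]).copy()
    weight = "weight" if weighted else None
    if weighted:
        for _, _, attrs in core.edges(data=True):
            attrs.setdefault("weight", -np.log10(max(attrs.get("q_fdr", 1.0), 1e-300)))
    best_partition = None
    best_q = -np.inf
    for partition in _dendrogram_partitions(core, weight):
        q = nx_community.modularity(core, partition, weight=weight)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = partition
    ordered = sorted((sorted(c) for c in best_partition), key=lambda c: c[0])
    assignment = {node: mid for mid, members in enumerate(ordered) for node in members}
    return ModulePartition(assignment=assignment, modularity_q=float(best_q), isolated=isolated)


def module_significance(
    g: nx.Graph,
    q_obs: float,
    n_perm: int = 10_000,
    seed: int = 0,
    weighted: bool = False,
) -> float:
    """Permutation p-value of the observed modularity against rewired nulls.

    Null graphs preserve the degree sequence via double-edge swaps (10 x |E|
    attempted swaps each); each null is re-clustered with the same
    Girvan-Newman procedure and p = (1 + #{Q_null >= Q_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    m = g.number_of_edges()
    if m < 2:
        warnings.warn("graph too small to rewire; p = 1")
        return 1.0
    rng = np.random.default_rng(seed)
    core = g.subgraph([n for n, d in g.degree() if d > 0]).copy()
    exceed = 0
    for _ in range(n_perm):
        null = core.copy()
        try:
            nx.double_edge_swap(
                null,
                nswap=10 * m,
                max_tries=200 * m,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except nx.NetworkXError:
            pass  # too few swappable configurations; use the graph as-is
        except nx.NetworkXAlgorithmError:
            pass  # max_tries exhausted mid-way; partial rewiring still a null draw
        try:
            q_null = girvan_newman_modules(null, weighted=weighted).modularity_q
        except ValueError:
            q_null = 0.0
        if q_null >= q_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def export_rdn(g: nx.Graph, partition: ModulePartition | None, prefix) -> dict[str, str]:
    """Write GraphML plus TSV edge/module tables; returns the paths written.

    Node attributes: dtype and (when a partition is given) module id; edge
    attributes: sign, p_bufam, q_fdr.  The GraphML round-trips losslessly
    through :func:`import_rdn`.
    """
    prefix = str(prefix)
    out = g.copy()
    if partition is not None:
        for node, mid in partition.assignment.items():
            out.nodes[node]["module"] = int(mid)
    paths = {
        "graphml": prefix + ".graphml",
        "edges": prefix + ".edges.tsv",
        "modules": prefix + ".modules.tsv",
    }
    nx.write_graphml(out, paths["graphml"])
    edges = pd.DataFrame(
        [
            {
                "feature_a": a,
                "feature_b": b,
                "sign": attrs.get("sign", "NA"),
                "p_bufam": attrs.get("p_bufam"),
                "q_fdr": attrs.get("q_fdr"),
            }
            for a, b, attrs in sorted(out.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
        columns=["feature_a", "feature_b", "sign", "p_bufam", "q_fdr"],
    )
    edges.to_csv(paths["edges"], sep="\t", index=False, na_rep="NA")
    module_rows = []
    if partition is not None:
        module_rows = [
            {"feature": node, "module_id": mid}
            for node, mid in sorted(partition.assignment.items())
        ] + [{"feature": node, "module_id": "isolated"} for node in partition.isolated]
    pd.DataFrame(module_rows, columns=["feature", "module_id"]).to_csv(
        paths["modules"], sep="\t", index=False
    )
    return paths


def import_rdn(path) -> nx.Graph:
    """Read a GraphML written by :func:`export_rdn`."""
    return nx.read_graphml(path)


class GirvanNewmanModules(BaseEstimator):
    """Girvan-Newman module detector as an sklearn-style estimator.

    ``fit(G)`` clusters an RDN graph; fitted attributes: ``assignment_``,
    ``modularity_q_``, ``isolated_``, ``partition_``.  ``significance`` runs
    the rewiring permutation test and stores ``p_perm_``.
    """

    def __init__(self, weighted: bool = False, n_perm: int = 10_000, seed: int = 0):
        self.weighted = weighted
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X: nx.Graph, y=None) -> "GirvanNewmanModules":
        self.partition_ = girvan_newman_modules(X, weighted=self.weighted)
        self.assignment_ = self.partition_.assignment
        self.modularity_q_ = self.partition_.modularity_q
        self.isolated_ = self.partition_.isolated
        self._graph = X
        return self

    def significance(self) -> float:
        p = module_significance(
            self._graph, self.modularity_q_, n_perm=self.n_perm,
            seed=self.seed, weighted=self.weighted,
        )
        self.partition_.p_perm = p
        self.partition_.n_perm = self.n_perm
        self.p_perm_ = p
        return p
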