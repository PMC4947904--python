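"""Synthetic multi-cohort generator with planted association structure.

Dependence is planted through a latent Gaussian copula: all features of a
sample are derived from one multivariate-normal draw whose correlation
matrix has block structure (within-block latent correlation rho, optional
cross-block correlation).  Each feature is then rendered in its declared
data type:

* numeric  — the latent value itself;
* ordinal  — the latent thresholded at equiprobable normal quantiles, levels
  ordered with the latent;
* binary   — a 2-level ordinal (median split by default);
* nominal  — the feature's latent competes with k-1 independent auxiliary
  standard normals and the argmax picks the level, so the block signal is
  carried without inducing any level order (each level keeps marginal
  probability 1/k by symmetry).

Cohorts are sample-disjoint draws from the same model; each covers only its
declared feature subset (structural missingness), and an optional random
missingness rate thins covered cells further.  An optional per-cohort shift
of the latent means emulates batch effects (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import CohortCollection, CohortTable, FeatureDescriptor

__all__ = ["SyntheticSpec", "generate", "block_truth", "pivot_scenario"]


@dataclass
class SyntheticSpec:
    """Declarative description of a planted multi-cohort dataset.

    ``blocks`` is a list of ``(feature_indices, rho)`` pairs; indices are
    into the feature namespace (0..n_features-1) and must be disjoint.
    ``dtypes[i]`` declares feature i's data type; level counts for
    ordinal/nominal features come from ``ordinal_levels``/``nominal_levels``
    (per-index dicts, with defaults 3).  ``cohort_specs`` is a list of
    ``(cohort_id, n_samples, covered_feature_indices)``.
    """

    n_features: int
    blocks: list[tuple[Sequence[int], float]] = field(default_factory=list)
    cross_block_rho: float = 0.0
    dtypes: list[str] | None = None
    ordinal_levels: dict[int, int] = field(default_factory=dict)
    nominal_levels: dict[int, int] = field(default_factory=dict)
    cohort_specs: list[tuple[str, int, Sequence[int]]] = field(default_factory=list)
    missing_rate: float = 0.0
    cohort_shift: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.dtypes is None:
            self.dtypes = ["numeric"] * self.n_features
        if len(self.dtypes) != self.n_features:
            raise ValueError("dtypes length must equal n_features")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        seen: set[int] = set()
        for idx, _rho in self.blocks:
            s = set(idx)
            if s & seen:
                raise ValueError("blocks must be disjoint")
            seen |= s
        if self.feature_names is None:
            self.feature_names = [f"f{i:02d}" for i in range(self.n_features)]
        if not self.cohort_specs:
            self.cohort_specs = [("cohort1", 200, list(range(self.n_features)))]

    # -- correlation model --------------------------------------------------

    def correlation(self) -> np.ndarray:
        c = np.full((self.n_features, self.n_features), self.cross_block_rho)
        for idx, rho in self.blocks:
            idx = np.asarray(list(idx))
            c[np.ix_(idx, idx)] = rho
        np.fill_diagonal(c, 1.0)
        return c

    def descriptors(self) -> tuple[FeatureDescriptor, ...]:
        out = []
        for i, (name, dt) in enumerate(zip(self.feature_names, self.dtypes)):
            if dt == "ordinal":
                k = self.ordinal_levels.get(i, 3)
                out.append(FeatureDescriptor(name, "ordinal",
                                             tuple(f"L{j + 1}" for j in range(k))))
            elif dt == "nominal":
                k = self.nominal_levels.get(i, 3)
                out.append(FeatureDescriptor(name, "nominal",
                                             tuple(f"C{j + 1}" for j in range(k))))
            elif dt == "binary":
                out.append(FeatureDescriptor(name, "binary", ("neg", "pos"),
                                             positive_level="pos"))
            else:
                out.append(FeatureDescriptor(name, "numeric"))
        return tuple(out)

    # -- (de)serialisation ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_features": self.n_features,
            "blocks": [[list(map(int, idx)), float(rho)] for idx, rho in self.blocks],
            "cross_block_rho": float(self.cross_block_rho),
            "dtypes": list(self.dtypes),
            "ordinal_levels": {int(k): int(v) for k, v in self.ordinal_levels.items()},
            "nominal_levels": {int(k): int(v) for k, v in self.nominal_levels.items()},
            "cohort_specs": [[cid, int(n), list(map(int, cov))]
                             for cid, n, cov in self.cohort_specs],
            "missing_rate": float(self.missing_rate),
            "cohort_shift": {k: float(v) for k, v in self.cohort_shift.items()},
            "seed": int(self.seed),
            "feature_names": list(self.feature_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["blocks"] = [(tuple(idx), float(rho)) for idx, rho in doc.get("blocks", [])]
        doc["cohort_specs"] = [(cid, int(n), tuple(cov))
                               for cid, n, cov in doc.get("cohort_specs", [])]
        doc["ordinal_levels"] = {int(k): int(v)
                                 for k, v in (doc.get("ordinal_levels") or {}).items()}
        doc["nominal_levels"] = {int(k): int(v)
                                 for k, v in (doc.get("nominal_levels") or {}).items()}
        return cls(**doc)


def block_truth(spec: SyntheticSpec) -> dict[str, int]:
    """Ground-truth block id per feature (-1 for features outside any block)."""
    truth = {name: -1 for name in spec.feature_names}
    for bid, (idx, _rho) in enumerate(spec.blocks):
        for i in idx:
            truth[spec.feature_names[i]] = bid
    return truth


def _render_feature(z: np.ndarray, desc: FeatureDescriptor, spec: SyntheticSpec,
                    index: int, rng: np.random.Generator):
    if desc.dtype == "numeric":
        return z
    if desc.dtype in ("ordinal", "binary"):
        levels = desc.levels
        k = len(levels)
        # equiprobable thresholds on the latent scale
        from scipy.stats import norm

        cuts = norm.ppf(np.arange(1, k) / k)
        codes = np.searchsorted(cuts, z)
        return np.asarray([levels[c] for c in codes], dtype=object)
    # nominal: feature latent vs k-1 independent auxiliaries, argmax -> level
    k = len(desc.levels)
    aux = rng.standard_normal((len(z), k - 1))
    stacked = np.column_stack([z, aux])
    codes = stacked.argmax(axis=1)
    return np.asarray([desc.levels[c] for c in codes], dtype=object)


def generate(spec: SyntheticSpec) -> CohortCollection:
    """Draw a :class:`CohortCollection` from a :class:`SyntheticSpec`.

    Deterministic per ``spec.seed``; raises before sampling if the implied
    latent correlation matrix is not positive definite.
    """
    corr = spec.correlation()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("latent correlation matrix is not positive definite") from None
    descriptors = spec.descriptors()
    root = np.random.SeedSequence(spec.seed)
    cohort_seeds = root.spawn(len(spec.cohort_specs))
    cohorts = []
    for (cohort_id, n_samples, covered_idx), seed_seq in zip(spec.cohort_specs, cohort_seeds):
        rng = np.random.default_rng(seed_seq)
        z = rng.standard_normal((n_samples, spec.n_features)) @ chol.T
        z = z + spec.cohort_shift.get(cohort_id, 0.0)
        covered_idx = sorted(int(i) for i in covered_idx)
        columns = {}
        for i in covered_idx:
            desc = descriptors[i]
            columns[desc.name] = _render_feature(z[:, i], desc, spec, i, rng)
        samples = [f"{cohort_id}-s{j:04d}" for j in range(n_samples)]
        frame = pd.DataFrame(columns, index=samples)
        if spec.missing_rate > 0:
            mask = rng.random(frame.shape) < spec.missing_rate
            frame = frame.mask(mask)
        cohorts.append(CohortTable(cohort_id=cohort_id, data=frame))
    return CohortCollection(descriptors, cohorts)


def pivot_scenario(
    rho: float = 0.6,
    n_per_cohort: int = 300,
    n_blocks: int = 2,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[CohortCollection, dict[str, int], SyntheticSpec]:
    """Structural-missingness topology where pivot features bridge a block.

    Each planted block of six features splits into roles U (2), P (2) and
    V (2).  Cohort ``c1`` covers U and P; cohorts ``c2``/``c3`` cover V and
    P.  No cohort co-observes any U feature with any V feature, so every
    U x V pair is non-testable directly — yet U, V and the shared "pivot"
    features P belong to one planted block, and module detection on the
    resulting network should reunite them.

    Role dtypes per block: U = (numeric, ordinal), P = (numeric, binary),
    V = (numeric, nominal), exercising all four data types end to end.

    Returns (collection, truth block assignment, spec).
    """
    role_dtypes = ["numeric", "ordinal", "numeric", "binary", "numeric", "nominal"]
    n_features = 6 * n_blocks
    dtypes = role_dtypes * n_blocks
    blocks = [(tuple(range(6 * b, 6 * b + 6)), rho) for b in range(n_blocks)]
    u_idx, p_idx, v_idx = [], [], []
    for b in range(n_blocks):
        base = 6 * b
        u_idx += [base, base + 1]
        p_idx += [base + 2, base + 3]
        v_idx += [base + 4, base + 5]
    spec = SyntheticSpec(
        n_features=n_features,
        blocks=blocks,
        dtypes=dtypes,
        cohort_specs=[
            ("c1", n_per_cohort, sorted(u_idx + p_idx)),
            ("c2", n_per_cohort, sorted(v_idx + p_idx)),
            ("c3", n_per_cohort, sorted(v_idx + p_idx)),
        ],
        missing_rate=missing_rate,
        seed=seed,
    )
    return generate(spec), block_truth(spec), spec
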