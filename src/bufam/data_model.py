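"""Domain model for multi-cohort, mixed-type feature tables.

A *cohort* is a samples x features table; several cohorts share one feature
namespace but each measures only a subset of it.  A feature absent from a
cohort's table is *structurally missing* there: every sample of that cohort
lacks it, as opposed to sporadic missing values within a covered feature.
Pairwise analysis pools, for a pair of features, the complete observations
from every cohort that covers both — the largest sample any direct test of
that pair can use.

Feature semantics are declared once, in a metadata table, as one of four
data types: ``numeric``, ``ordinal`` (ordered categories), ``nominal``
(unordered categories) and ``binary``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DTYPES",
    "FeatureDescriptor",
    "CohortTable",
    "CohortCollection",
    "PairedSample",
    "read_metadata",
    "write_metadata",
    "read_cohort",
    "write_cohort",
    "pool_pair",
    "jaccard",
    "DEFAULT_MISSING_TOKENS",
]

DTYPES = ("numeric", "ordinal", "nominal", "binary")

#: Tokens treated as missing when reading cohort tables.  No numeric
#: sentinel (e.g. -999) is ever interpreted as missing.
DEFAULT_MISSING_TOKENS = ("NA", "")


class SchemaError(ValueError):
    """A cohort table violates its declared feature metadata."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """Declared name, data type and level metadata of one feature.

    Parameters
    ----------
    name : str
        Unique feature identifier.
    dtype : {"numeric", "ordinal", "nominal", "binary"}
    levels : tuple of str, optional
        Ordered category labels.  Required (>= 2 labels) for ordinal
        features, where the order defines the integer scores used by
        order-aware tests; optional for nominal/binary.
    positive_level : str, optional
        Binary features only: the label coded 1 when computing polarity.
        If omitted, the lexicographically larger label is coded 1.
    """

    name: str
    dtype: str
    levels: tuple[str, ...] | None = None
    positive_level: str | None = None

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for feature {self.name!r}")
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for feature {self.name!r}")
        if self.dtype == "ordinal":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(
                    f"ordinal feature {self.name!r} needs an ordered list of >= 2 levels"
                )
        if self.dtype == "binary" and self.levels is not None and len(self.levels) > 2:
            raise ValueError(f"binary feature {self.name!r} declares > 2 levels")
        if self.positive_level is not None and self.dtype != "binary":
            raise ValueError(f"positive_level only applies to binary features ({self.name!r})")

    @property
    def is_categorical(self) -> bool:
        return self.dtype != "numeric"


@dataclass
class CohortTable:
    """One cohort's samples x covered-features table.

    ``data`` is indexed by sample id and holds only the cohort's covered
    features as columns; every feature of the global namespace absent from
    the columns is structurally missing for this cohort.  Missing values
    within covered features are NaN.
    """

    cohort_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids in cohort {self.cohort_id!r}: {dups}")
        if self.data.columns.has_duplicates:
            raise SchemaError(f"duplicate feature columns in cohort {self.cohort_id!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def covered_features(self) -> frozenset[str]:
        return frozenset(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def covers(self, *features: str) -> bool:
        return all(f in self.data.columns for f in features)


@dataclass
class CohortCollection:
    """A set of cohorts sharing one declared feature namespace."""

    descriptors: tuple[FeatureDescriptor, ...]
    cohorts: list[CohortTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.descriptors = tuple(self.descriptors)
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in descriptors")
        self._by_name = {d.name: d for d in self.descriptors}
        for cohort in self.cohorts:
            unknown = cohort.covered_features - set(names)
            if unknown:
                raise SchemaError(
                    f"cohort {cohort.cohort_id!r} covers undeclared features: {sorted(unknown)}"
                )
        self._validate_levels()

    def _validate_levels(self) -> None:
        for desc in self.descriptors:
            if desc.dtype == "numeric":
                continue
            observed: set[str] = set()
            for cohort in self.cohorts:
                if desc.name not in cohort.data.columns:
                    continue
                col = cohort.data[desc.name].dropna()
                observed.update(str(v) for v in col.unique())
            if desc.levels is not None:
                extra = observed - set(desc.levels)
                if extra:
                    raise SchemaError(
                        f"feature {desc.name!r}: observed values {sorted(extra)} "
                        f"outside declared levels {list(desc.levels)}"
                    )
            if desc.dtype == "binary" and len(observed) > 2:
                raise SchemaError(
                    f"binary feature {desc.name!r} has > 2 observed labels: {sorted(observed)}"
                )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.descriptors)

    def descriptor(self, name: str) -> FeatureDescriptor:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown feature {name!r}") from None

    def analyzable_features(self) -> tuple[str, ...]:
        """Features covered by at least one cohort."""
        covered: set[str] = set()
        for cohort in self.cohorts:
            covered |= cohort.covered_features
        return tuple(n for n in self.feature_names if n in covered)

    def coverage(self) -> pd.DataFrame:
        """Boolean cohorts x features coverage matrix."""
        return pd.DataFrame(
            {
                d.name: [d.name in c.covered_features for c in self.cohorts]
                for d in self.descriptors
            },
            index=[c.cohort_id for c in self.cohorts],
        )

    def subset_cohorts(self, cohort_ids: Iterable[str]) -> "CohortCollection":
        wanted = set(cohort_ids)
        kept = [c for c in self.cohorts if c.cohort_id in wanted]
        return CohortCollection(self.descriptors, kept)


@dataclass
class PairedSample:
    """Complete (x, y) observations for one feature pair, pooled over cohorts.

    Contains exactly the samples, from every cohort covering both features,
    where both values are observed; ``n`` is the pooled complete-pair count.
    """

    feature_a: str
    feature_b: str
    x: np.ndarray
    y: np.ndarray
    cohort_of: np.ndarray
    sample_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def cohorts_used(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.cohort_of:
            seen.setdefault(str(c))
        return tuple(seen)

    def swapped(self) -> "PairedSample":
        return PairedSample(
            self.feature_b, self.feature_a, self.y, self.x, self.cohort_of, self.sample_ids
        )


# ---------------------------------------------------------------------------
# metadata I/O


def read_metadata(path) -> tuple[FeatureDescriptor, ...]:
    """Read a feature-metadata TSV (columns: feature, dtype, levels, positive_level).

    ``levels`` is a pipe-separated ordered list; empty cells mean "not declared".
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"feature", "dtype"}
    if not required <= set(frame.columns):
        raise SchemaError(f"metadata must have columns {sorted(required)}; got {list(frame.columns)}")
    descriptors = []
    for _, row in frame.iterrows():
        levels_cell = str(row.get("levels", "") or "")
        levels = tuple(levels_cell.split("|")) if levels_cell else None
        positive = str(row.get("positive_level", "") or "") or None
        descriptors.append(
            FeatureDescriptor(
                name=str(row["feature"]),
                dtype=str(row["dtype"]),
                levels=levels,
                positive_level=positive,
            )
        )
    names = [d.name for d in descriptors]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate feature names in metadata")
    return tuple(descriptors)


def write_metadata(descriptors: Sequence[FeatureDescriptor], path) -> None:
    rows = [
        {
            "feature": d.name,
            "dtype": d.dtype,
            "levels": "|".join(d.levels) if d.levels else "",
            "positive_level": d.positive_level or "",
        }
        for d in descriptors
    ]
    pd.DataFrame(rows, columns=["feature", "dtype", "levels", "positive_level"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cohort table I/O


def _infer_sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cohort(
    path,
    metadata: Sequence[FeatureDescriptor],
    cohort_id: str,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
) -> CohortTable:
    """Read one cohort table (first column sample id, remaining columns features).

    Features absent from the header are recorded as structurally missing
    (they are simply not columns of the result).  Cells matching a missing
    token become NaN; numeric columns are parsed as floats, categorical
    columns kept as string labels and validated against declared levels.
    """
    by_name = {d.name: d for d in metadata}
    sep = sep or _infer_sep(path)
    frame = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        na_values=list(missing_tokens),
        keep_default_na=False,
        index_col=0,
    )
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample ids in {path}: {dups}")
    unknown = [c for c in frame.columns if c not in by_name]
    if unknown:
        raise SchemaError(f"unknown feature(s) in header of {path}: {unknown}")
    for col in frame.columns:
        desc = by_name[col]
        if desc.dtype == "numeric":
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"non-numeric value in numeric feature {col!r}: {exc}") from exc
        elif desc.levels is not None:
            bad = frame[col].dropna()[~frame[col].dropna().isin(desc.levels)]
            if len(bad):
                row_label = bad.index[0]
                raise SchemaError(
                    f"feature {col!r}, sample {row_label!r}: value {bad.iloc[0]!r} "
                    f"outside declared levels {list(desc.levels)}"
                )
    return CohortTable(cohort_id=cohort_id, data=frame)


def write_cohort(table: CohortTable, path, sep: str | None = None) -> None:
    """Write a cohort table; missing values serialized as "NA"."""
    sep = sep or _infer_sep(path)
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA")


# ---------------------------------------------------------------------------
# pairwise pooling


def pool_pair(collection: CohortCollection, a: str, b: str) -> PairedSample:
    """Pool complete (a, b) observations from every cohort covering both.

    The pooled count is the sum of per-cohort complete-pair counts; a pair
    covered by no cohort yields n = 0 (non-testable downstream).
    """
    if a == b:
        raise ValueError("pool_pair requires two distinct features")
    collection.descriptor(a)
    collection.descriptor(b)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    cohort_of: list[np.ndarray] = []
    sample_ids: list[np.ndarray] = []
    for cohort in collection.cohorts:
        if not cohort.covers(a, b):
            continue
        sub = cohort.data[[a, b]].dropna()
        if not len(sub):
            continue
        xs.append(sub[a].to_numpy())
        ys.append(sub[b].to_numpy())
        cohort_of.append(np.full(len(sub), cohort.cohort_id, dtype=object))
        sample_ids.append(sub.index.to_numpy(dtype=object))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        who = np.concatenate(cohort_of)
        sid = np.concatenate(sample_ids)
    else:
        x = np.empty(0, dtype=object)
        y = np.empty(0, dtype=object)
        who = np.empty(0, dtype=object)
        sid = np.empty(0, dtype=object)
    return PairedSample(a, b, x, y, who, sid)


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B|; defined as 1.0 when both empty."""
    sa, sb = set(set_a), set(set_b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)
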