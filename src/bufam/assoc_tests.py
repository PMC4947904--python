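"""Data-type-specific raw association tests and the type-pair -> test mapping.

Four feature data types give 10 unordered type combinations, each served by
one of five classical tests:

=============  =========================================================
test id        procedure
=============  =========================================================
``spearman``   Spearman rank correlation, tie-corrected t approximation
``oneway``     one-way location test across groups (Welch's
               heteroscedasticity-robust F by default)
``chisq``      Pearson chi-square on the contingency table, uncorrected
``wilcoxon``   Wilcoxon-Mann-Whitney rank-sum (normal approximation with
               tie correction; exact for small untied samples)
``lbl``        linear-by-linear association: M^2 = (N-1) r^2 with integer
               level scores, referred to chi-square(1)
=============  =========================================================

Every test also has a vectorised path that evaluates B permuted copies of
one margin at once; this is what the bootstrap-null machinery uses.  The
vectorised and scalar paths share the same arithmetic, and the test suite
cross-checks both against scipy / pingouin / brute-force enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .data_model import FeatureDescriptor, PairedSample

__all__ = [
    "TEST_IDS",
    "DEFAULT_MAPPING",
    "DegenerateInput",
    "RawTestResult",
    "select_test",
    "run_raw_test",
    "polarity",
    "encode_feature",
    "prepare_test",
    "PreparedTest",
]

TEST_IDS = ("spearman", "oneway", "chisq", "wilcoxon", "lbl")

P_FLOOR = 1e-300

#: Unordered type-pair -> test mapping.  The assignment uses exactly the
#: five tests above and keeps ordering information wherever both features
#: have it; it can be overridden per call (or via a YAML config in the CLI).
DEFAULT_MAPPING: dict[tuple[str, str], str] = {
    ("numeric", "numeric"): "spearman",
    ("numeric", "ordinal"): "spearman",
    ("binary", "numeric"): "wilcoxon",
    ("nominal", "numeric"): "oneway",
    ("ordinal", "ordinal"): "lbl",
    ("binary", "ordinal"): "lbl",
    ("nominal", "ordinal"): "oneway",
    ("nominal", "nominal"): "chisq",
    ("binary", "nominal"): "chisq",
    ("binary", "binary"): "chisq",
}


class DegenerateInput(ValueError):
    """The pooled pair cannot support the selected test (reported non-testable)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class RawTestResult:
    test_id: str
    statistic: float
    p_raw: float
    direction: str  # "positive" | "negative" | "not_applicable"


def select_test(
    dtype_a: str,
    dtype_b: str,
    mapping: dict[tuple[str, str], str] | None = None,
) -> str:
    """Return the raw test for an unordered data-type pair (symmetric, total)."""
    mapping = mapping if mapping is not None else DEFAULT_MAPPING
    key = tuple(sorted((dtype_a, dtype_b)))
    try:
        return mapping[key]  # type: ignore[index]
    except KeyError:
        raise KeyError(f"no test mapped for type pair {key}") from None


# ---------------------------------------------------------------------------
# encoding


def encode_feature(values: np.ndarray, desc: FeatureDescriptor) -> np.ndarray:
    """Code one feature's observed values as floats.

    numeric -> as-is; ordinal -> 0..L-1 by declared level order;
    binary -> 0/1 with the positive level (or lexicographically larger
    label) coded 1; nominal -> arbitrary-but-deterministic integer codes
    (declared order, else sorted labels).
    """
    if desc.dtype == "numeric":
        return np.asarray(values, dtype=float)
    labels = np.asarray([str(v) for v in values], dtype=object)
    if desc.levels is not None:
        level_order = list(desc.levels)
        if desc.dtype == "binary" and desc.positive_level is not None:
            others = [l for l in level_order if l != desc.positive_level]
            level_order = others + [desc.positive_level]
    else:
        level_order = sorted(set(labels))
    lut = {lab: i for i, lab in enumerate(level_order)}
    try:
        return np.asarray([lut[l] for l in labels], dtype=float)
    except KeyError as exc:
        raise DegenerateInput(f"value {exc.args[0]!r} outside levels of {desc.name!r}") from exc


def _n_observed_levels(codes: np.ndarray) -> int:
    return len(np.unique(codes))


def is_orderable(desc: FeatureDescriptor, codes: np.ndarray | None = None) -> bool:
    """Whether a feature carries an order usable for polarity.

    Nominal features with more than 2 observed levels have no order; a
    2-level nominal behaves like a binary feature.
    """
    if desc.dtype in ("numeric", "ordinal", "binary"):
        return True
    if codes is not None:
        return _n_observed_levels(codes) <= 2
    return desc.levels is not None and len(desc.levels) <= 2


# ---------------------------------------------------------------------------
# vectorised scorers: each takes (B, n) permuted rows of one margin and
# returns (statistic, p) arrays of length B.


def _rank_corr_scores(x_centered: np.ndarray, y_rows: np.ndarray, y_mean: float,
                      denom: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    # Pearson correlation of fixed x (centered) against each permuted row of y.
    num = y_rows @ x_centered  # sum((y - y_mean) * xc) since sum(xc) = 0
    r = np.clip(num / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return r, np.clip(p, P_FLOOR, 1.0)


def _lbl_scores(x_centered: np.ndarray, y_rows: np.ndarray, denom: float,
                n: int) -> tuple[np.ndarray, np.ndarray]:
    num = y_rows @ x_centered
    r = np.clip(num / denom, -1.0, 1.0)
    m2 = (n - 1) * r * r
    p = stats.chi2.sf(m2, 1)
    return m2, np.clip(p, P_FLOOR, 1.0)


def _mwu_scores(ranks: np.ndarray, indicator_rows: np.ndarray, n1: int, n2: int,
                tie_term: float) -> tuple[np.ndarray, np.ndarray]:
    n = n1 + n2
    r1 = indicator_rows @ ranks
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise DegenerateInput("all pooled values tied; rank-sum variance is zero")
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return u1, np.clip(p, P_FLOOR, 1.0)


def _chisq_scores(x_code: np.ndarray, y_rows: np.ndarray, kx: int, ky: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    n = x_code.shape[0]
    b = y_rows.shape[0]
    cells = kx * ky
    idx = x_code[None, :] * ky + y_rows.astype(np.int64)
    if b * n * cells <= 20_000_000:
        counts = (idx[:, :, None] == np.arange(cells)[None, None, :]).sum(axis=1)
    else:
        counts = np.empty((b, cells), dtype=np.int64)
        for i in range(b):
            counts[i] = np.bincount(idx[i], minlength=cells)
    counts = counts.reshape(b, kx, ky).astype(float)
    row_m = np.bincount(x_code, minlength=kx).astype(float)
    col_m = np.bincount(y_rows[0].astype(np.int64) % ky, minlength=ky).astype(float)
    # margins are identical across permutations of one margin
    expected = np.outer(row_m, col_m) / n
    stat = ((counts - expected) ** 2 / expected).sum(axis=(1, 2))
    df = (kx - 1) * (ky - 1)
    p = stats.chi2.sf(stat, df)
    return stat, np.clip(p, P_FLOOR, 1.0)


def _welch_scores(values: np.ndarray, group_rows: np.ndarray, k: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    b, n = group_rows.shape
    sums = np.empty((b, k))
    sumsq = np.empty((b, k))
    counts = np.bincount(group_rows[0].astype(np.int64), minlength=k).astype(float)
    v2 = values * values
    for g in range(k):
        mask = group_rows == g
        sums[:, g] = mask @ values
        sumsq[:, g] = mask @ v2
    means = sums / counts
    var = (sumsq - sums * sums / counts) / (counts - 1)
    var = np.maximum(var, 1e-12)  # guard rare all-tied permuted groups
    w = counts / var
    w_tot = w.sum(axis=1, keepdims=True)
    m_w = (w * means).sum(axis=1, keepdims=True) / w_tot
    a = (w * (means - m_w) ** 2).sum(axis=1) / (k - 1)
    h = ((1.0 - w / w_tot) ** 2 / (counts - 1)).sum(axis=1)
    lam = 3.0 * h / (k * k - 1)
    f = a / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    with np.errstate(divide="ignore"):
        df2 = np.where(lam > 0, 1.0 / lam, np.inf)
    p = stats.f.sf(f, k - 1, df2)
    return f, np.clip(p, P_FLOOR, 1.0)


def _anova_scores(values: np.ndarray, group_rows: np.ndarray, k: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    b, n = group_rows.shape
    counts = np.bincount(group_rows[0].astype(np.int64), minlength=k).astype(float)
    sums = np.empty((b, k))
    for g in range(k):
        sums[:, g] = (group_rows == g) @ values
    grand = values.sum()
    ss_between = (sums * sums / counts).sum(axis=1) - grand * grand / n
    ss_total = (values * values).sum() - grand * grand / n
    ss_within = np.maximum(ss_total - ss_between, 1e-300)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return f, np.clip(p, P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# preparation: role assignment, guards, and a uniform permutation interface


@dataclass
class PreparedTest:
    """A pair readied for (repeated) testing.

    ``base`` is the margin that permutation resampling shuffles; ``score``
    maps a (B, n) matrix of shuffled copies of ``base`` to (statistic, p)
    arrays.  The observed result is ``score(base[None, :])``.
    """

    test_id: str
    base: np.ndarray
    score: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    n: int

    def observed(self) -> tuple[float, float]:
        stat, p = self.score(self.base[None, :])
        return float(stat[0]), float(p[0])


def _check_constant(codes: np.ndarray, name: str) -> None:
    if _n_observed_levels(codes) < 2:
        raise DegenerateInput(f"feature {name!r} is constant in the pooled pairs")


def _chisq_guard(x_code: np.ndarray, y_code: np.ndarray, kx: int, ky: int) -> None:
    n = len(x_code)
    row_m = np.bincount(x_code, minlength=kx).astype(float)
    col_m = np.bincount(y_code, minlength=ky).astype(float)
    expected = np.outer(row_m[row_m > 0], col_m[col_m > 0]) / n
    if expected.min() < 1.0 or (expected >= 5.0).mean() < 0.8:
        raise DegenerateInput(
            "chi-square expected-count rule violated (needs all >= 1 and >= 80% of cells >= 5)"
        )


def _compress_codes(codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Map observed codes to 0..k-1 (preserving order); return codes and k."""
    uniq, inv = np.unique(codes, return_inverse=True)
    return inv.astype(np.int64), len(uniq)


def prepare_test(
    pair: PairedSample,
    test_id: str,
    desc_a: FeatureDescriptor,
    desc_b: FeatureDescriptor,
    oneway_variant: str = "welch",
    min_group: int = 2,
) -> PreparedTest:
    """Encode a pooled pair and assemble the vectorised scorer for ``test_id``.

    Raises :class:`DegenerateInput` when the pair cannot support the test
    (constant feature, too-small groups, expected-count rule, ...).
    """
    n = pair.n
    if n < 3:
        raise DegenerateInput(f"only {n} complete pairs")
    xa = encode_feature(pair.x, desc_a)
    xb = encode_feature(pair.y, desc_b)
    _check_constant(xa, desc_a.name)
    _check_constant(xb, desc_b.name)

    if test_id == "spearman":
        ra = stats.rankdata(xa)
        rb = stats.rankdata(xb)
        xc = ra - ra.mean()
        denom = np.sqrt((xc * xc).sum() * ((rb - rb.mean()) ** 2).sum())
        if denom == 0:
            raise DegenerateInput("zero rank variance")
        score = lambda rows, xc=xc, d=denom, m=rb.mean(), n=n: _rank_corr_scores(xc, rows, m, d, n)
        return PreparedTest("spearman", rb, score, n)

    if test_id == "lbl":
        xc = xa - xa.mean()
        denom = np.sqrt((xc * xc).sum() * ((xb - xb.mean()) ** 2).sum())
        if denom == 0:
            raise DegenerateInput("zero score variance")
        score = lambda rows, xc=xc, d=denom, n=n: _lbl_scores(xc, rows, d, n)
        return PreparedTest("lbl", xb, score, n)

    if test_id == "wilcoxon":
        # numeric values vs binary group indicator
        if desc_a.dtype == "numeric":
            values, groups = xa, xb
        else:
            values, groups = xb, xa
        g_codes, k = _compress_codes(groups)
        if k != 2:
            raise DegenerateInput(f"rank-sum test needs 2 groups, found {k}")
        n1 = int(g_codes.sum())
        n2 = n - n1
        if min(n1, n2) < min_group:
            raise DegenerateInput(f"group sizes ({n1}, {n2}) below minimum {min_group}")
        ranks = stats.rankdata(values)
        _, t_counts = np.unique(values, return_counts=True)
        tie_term = float((t_counts ** 3 - t_counts).sum())
        score = lambda rows, r=ranks, n1=n1, n2=n2, tt=tie_term: _mwu_scores(r, rows, n1, n2, tt)
        return PreparedTest("wilcoxon", g_codes.astype(float), score, n)

    if test_id == "oneway":
        # ordered response (numeric, or integer-coded ordinal) vs nominal groups
        if desc_a.dtype == "nominal":
            groups_raw, values = xa, xb
        else:
            groups_raw, values = xb, xa
        g_codes, k = _compress_codes(groups_raw)
        if k < 2:
            raise DegenerateInput("fewer than 2 groups")
        counts = np.bincount(g_codes, minlength=k)
        if counts.min() < max(min_group, 2):
            raise DegenerateInput(f"smallest group has {counts.min()} samples")
        if np.ptp(values) == 0:
            raise DegenerateInput("constant response")
        fn = _welch_scores if oneway_variant == "welch" else _anova_scores
        score = lambda rows, v=values, k=k, fn=fn: fn(v, rows.astype(np.int64), k)
        return PreparedTest("oneway", g_codes.astype(float), score, n)

    if test_id == "chisq":
        xc_codes, kx = _compress_codes(xa)
        yc_codes, ky = _compress_codes(xb)
        _chisq_guard(xc_codes, yc_codes, kx, ky)
        score = lambda rows, x=xc_codes, kx=kx, ky=ky: _chisq_scores(x, rows, kx, ky)
        return PreparedTest("chisq", yc_codes.astype(float), score, n)

    raise ValueError(f"unknown test id {test_id!r}")


# ---------------------------------------------------------------------------
# public scalar operations


def polarity(
    pair: PairedSample,
    desc_a: FeatureDescriptor,
    desc_b: FeatureDescriptor,
) -> str:
    """Association direction: sign of the Spearman correlation of coded values.

    "not_applicable" when either feature is nominal with > 2 observed levels;
    an exactly-zero correlation is reported as "positive" (with a warning)
    for determinism.
    """
    if pair.n < 3:
        raise ValueError("polarity needs at least 3 complete pairs")
    xa = encode_feature(pair.x, desc_a)
    xb = encode_feature(pair.y, desc_b)
    if not (is_orderable(desc_a, xa) and is_orderable(desc_b, xb)):
        return "not_applicable"
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return "not_applicable"
    rho = stats.spearmanr(xa, xb).statistic
    if np.isnan(rho):
        return "not_applicable"
    if rho == 0:
        warnings.warn("zero correlation; polarity reported positive by convention")
        return "positive"
    return "positive" if rho > 0 else "negative"


def run_raw_test(
    pair: PairedSample,
    test_id: str,
    desc_a: FeatureDescriptor,
    desc_b: FeatureDescriptor,
    oneway_variant: str = "welch",
    wilcoxon_method: str = "auto",
    min_group: int = 2,
) -> RawTestResult:
    """Run one raw test on a pooled pair.

    ``wilcoxon_method`` follows scipy's Mann-Whitney conventions: "auto"
    uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise; "asymptotic" (what the
    unified-score engine uses throughout) always takes the approximation,
    without continuity correction.
    """
    prepared = prepare_test(pair, test_id, desc_a, desc_b,
                            oneway_variant=oneway_variant, min_group=min_group)
    stat, p = prepared.observed()
    if test_id == "wilcoxon" and wilcoxon_method == "auto":
        values = encode_feature(pair.x, desc_a) if desc_a.dtype == "numeric" \
            else encode_feature(pair.y, desc_b)
        g = prepared.base.astype(int)
        res = stats.mannwhitneyu(values[g == 1], values[g == 0],
                                 alternative="two-sided", method="auto",
                                 use_continuity=False)
        stat, p = float(res.statistic), float(np.clip(res.pvalue, P_FLOOR, 1.0))
    try:
        direction = polarity(pair, desc_a, desc_b)
    except ValueError:
        direction = "not_applicable"
    return RawTestResult(test_id=test_id, statistic=stat, p_raw=p, direction=direction)
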