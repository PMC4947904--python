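"""Unified association measurement via a resampled negative-control null.

Raw tests for different data-type pairs produce statistics and p-values on
incomparable scales and with different sample-size behaviour.  To put every
pair on one scale, the observed raw result is converted to a *score*, a
negative-control distribution of the same score is built by resampling the
pooled pair (permuting one margin, which breaks the association while
preserving both marginals), and the observed score is expressed as an
upper-tail Z-test p-value against the moments of that control distribution.
All pairs, whatever their types, tests and pooled sample sizes, are then
ranked on this one unified p-value and FDR-adjusted together.

The default score is the probit of the raw p-value, Phi^-1(1 - p_raw): under
the null it is close to standard normal, so the Z-test against the resampled
moments is well calibrated.  A -log10(p) score and a raw-statistic score are
available for sensitivity analysis; both are heavier-tailed under the null,
which makes the normal-tail conversion conservative in one direction and
anti-conservative in the other (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import assoc_tests
from .assoc_tests import DegenerateInput, prepare_test, select_test
from .data_model import CohortCollection, PairedSample, pool_pair

__all__ = [
    "BufamConfig",
    "AssociationResult",
    "BufamProfiler",
    "bufam_pvalue",
    "profile_associations",
    "adjust_fdr",
    "results_to_frame",
    "write_results",
    "read_results",
]

SCORE_TRANSFORMS = ("probit", "neglog10_p", "statistic")
RESAMPLE_SCHEMES = ("permutation", "bootstrap")

# raw p-values are clipped into this range before transforming to scores,
# so that discrete tests yielding p == 1 keep a finite probit
_P_CLIP = (1e-300, 1.0 - 1e-9)


@dataclass(frozen=True)
class BufamConfig:
    """Engine settings for unified association profiling.

    Parameters
    ----------
    resamples : int
        Number B of negative-control resamples per pair (>= 100).
    min_n : int
        Minimum pooled complete-pair count for a pair to be testable (>= 5).
    seed : int
        Master seed; per-pair streams are derived from it and the sorted
        feature names, so results do not depend on iteration order.
    score_transform : {"probit", "neglog10_p", "statistic"}
        Scale on which observed and control results are compared.
    resample_scheme : {"permutation", "bootstrap"}
        Shuffle one margin without replacement (default; preserves both
        marginals exactly) or resample it with replacement.
    fdr_alpha : float
        FDR threshold downstream consumers use to build the network.
    mapping : dict, optional
        Override of the type-pair -> test table.
    oneway_variant : {"welch", "classic"}
    n_jobs : int
        Pairs are independent; > 1 parallelises over them (threads).
    """

    resamples: int = 1000
    min_n: int = 20
    seed: int = 0
    score_transform: str = "probit"
    resample_scheme: str = "permutation"
    fdr_alpha: float = 0.01
    mapping: dict | None = None
    oneway_variant: str = "welch"
    min_group: int = 2
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.resamples < 100:
            raise ValueError("resamples must be >= 100")
        if self.min_n < 5:
            raise ValueError("min_n must be >= 5")
        if self.score_transform not in SCORE_TRANSFORMS:
            raise ValueError(f"score_transform must be one of {SCORE_TRANSFORMS}")
        if self.resample_scheme not in RESAMPLE_SCHEMES:
            raise ValueError(f"resample_scheme must be one of {RESAMPLE_SCHEMES}")


@dataclass
class AssociationResult:
    """One pairwise record of the unified profiling."""

    feature_a: str
    feature_b: str
    test_id: str | None = None
    n_support: int = 0
    cohorts_used: tuple[str, ...] = ()
    statistic: float | None = None
    p_raw: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    z: float | None = None
    p_bufam: float | None = None
    q_fdr: float | None = None
    direction: str = "not_applicable"
    testable: bool = False
    reason: str | None = None


def _pair_seed(master_seed: int, a: str, b: str) -> np.random.SeedSequence:
    """Deterministic per-pair stream, independent of iteration order."""
    a, b = sorted((a, b))
    digest = hashlib.blake2b(f"{a}\x1f{b}".encode(), digest_size=8).digest()
    return np.random.SeedSequence([int(master_seed), int.from_bytes(digest, "big") >> 1])


def _scores(p: np.ndarray, stat: np.ndarray, transform: str) -> np.ndarray:
    if transform == "statistic":
        return np.asarray(stat, dtype=float)
    p = np.clip(p, *_P_CLIP)
    if transform == "probit":
        return stats.norm.isf(p)
    return -np.log10(p)  # neglog10_p


def _unify(s_obs: float, s_null: np.ndarray, n_resamples: int) -> tuple[float, float, float, float]:
    """Z-test of the observed score against the control moments.

    Returns (null_mean, null_sd, z, p).  A degenerate (zero-spread) control
    yields p = 1 when the observed score does not exceed it, and the
    resampling floor 1/(B+1) when it does.
    """
    mean = float(np.mean(s_null))
    sd = float(np.std(s_null, ddof=1))
    if sd > 0:
        z = (s_obs - mean) / sd
        return mean, sd, float(z), float(np.clip(stats.norm.sf(z), 1e-300, 1.0))
    if s_obs > s_null.max():
        return mean, sd, np.inf, 1.0 / (n_resamples + 1)
    return mean, sd, 0.0, 1.0


def bufam_pvalue(
    pair: PairedSample,
    test_id: str,
    cfg: BufamConfig,
    desc_a,
    desc_b,
    rng: np.random.Generator | None = None,
) -> AssociationResult:
    """Unified p-value for one pooled pair.

    Computes the observed raw test, resamples one margin ``cfg.resamples``
    times to build the negative-control score distribution, and converts
    the observed score to an upper-tail Z-test p-value.  Deterministic for
    a given configuration (the stream is derived from ``cfg.seed`` and the
    pair's sorted feature names unless an explicit ``rng`` is passed).
    """
    result = AssociationResult(
        feature_a=pair.feature_a,
        feature_b=pair.feature_b,
        test_id=test_id,
        n_support=pair.n,
        cohorts_used=pair.cohorts_used,
    )
    if pair.n == 0:
        result.reason = "no cohort covers both features"
        return result
    if pair.n < cfg.min_n:
        result.reason = f"pooled n={pair.n} below min_n={cfg.min_n}"
        return result
    try:
        prepared = prepare_test(
            pair, test_id, desc_a, desc_b,
            oneway_variant=cfg.oneway_variant, min_group=cfg.min_group,
        )
    except DegenerateInput as exc:
        result.reason = exc.reason
        return result

    if rng is None:
        rng = np.random.default_rng(_pair_seed(cfg.seed, pair.feature_a, pair.feature_b))
    base = prepared.base
    n = base.shape[0]
    if cfg.resample_scheme == "permutation":
        rows = rng.permuted(np.tile(base, (cfg.resamples, 1)), axis=1)
    else:
        rows = base[rng.integers(0, n, size=(cfg.resamples, n))]

    stat_obs, p_obs = prepared.observed()
    try:
        stat_null, p_null = prepared.score(rows)
    except DegenerateInput as exc:
        result.reason = exc.reason
        return result

    s_obs = float(_scores(np.array([p_obs]), np.array([stat_obs]), cfg.score_transform)[0])
    s_null = _scores(p_null, stat_null, cfg.score_transform)
    null_mean, null_sd, z, p_bufam = _unify(s_obs, s_null, cfg.resamples)

    result.statistic = stat_obs
    result.p_raw = p_obs
    result.null_mean = null_mean
    result.null_sd = null_sd
    result.z = z
    result.p_bufam = p_bufam
    result.testable = True
    try:
        result.direction = assoc_tests.polarity(pair, desc_a, desc_b)
    except ValueError:
        result.direction = "not_applicable"
    return result


def _profile_one(collection: CohortCollection, a: str, b: str, cfg: BufamConfig
                 ) -> AssociationResult:
    desc_a = collection.descriptor(a)
    desc_b = collection.descriptor(b)
    pair = pool_pair(collection, a, b)
    test_id = select_test(desc_a.dtype, desc_b.dtype, cfg.mapping)
    return bufam_pvalue(pair, test_id, cfg, desc_a, desc_b)


def profile_associations(
    collection: CohortCollection,
    cfg: BufamConfig | None = None,
    adjust: bool = True,
) -> list[AssociationResult]:
    """Unified profiling of every unordered feature pair in a collection.

    Pairs that fail the min-n or per-test guards appear in the output with
    ``testable=False`` and a skip reason.  Results are ordered by sorted
    feature-name pair and are bitwise reproducible for a fixed master seed,
    independent of ``n_jobs``.
    """
    cfg = cfg or BufamConfig()
    names = sorted(collection.analyzable_features())
    if len(names) < 2:
        raise ValueError("profiling needs at least 2 analyzable features")
    pairs = list(combinations(names, 2))
    if cfg.n_jobs and cfg.n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=cfg.n_jobs, prefer="threads")(
            delayed(_profile_one)(collection, a, b, cfg) for a, b in pairs
        )
    else:
        results = [_profile_one(collection, a, b, cfg) for a, b in pairs]
    if adjust:
        results = adjust_fdr(results)
    return results


def adjust_fdr(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """Benjamini-Hochberg q-values over the testable results (others untouched)."""
    results = list(results)
    idx = [i for i, r in enumerate(results) if r.testable and r.p_bufam is not None]
    if idx:
        ps = np.array([results[i].p_bufam for i in idx])
        q = multipletests(ps, method="fdr_bh")[1]
        for i, qi in zip(idx, q):
            results[i].q_fdr = float(qi)
    return results


# ---------------------------------------------------------------------------
# tabular round-trip

_COLUMNS = [
    "feature_a", "feature_b", "test", "n", "cohorts", "statistic", "p_raw",
    "null_mean", "null_sd", "z", "p_bufam", "q_fdr", "direction", "testable",
    "reason",
]


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "feature_a": r.feature_a,
            "feature_b": r.feature_b,
            "test": r.test_id,
            "n": r.n_support,
            "cohorts": ",".join(r.cohorts_used),
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "z": r.z,
            "p_bufam": r.p_bufam,
            "q_fdr": r.q_fdr,
            "direction": r.direction,
            "testable": r.testable,
            "reason": r.reason,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_results(results: Sequence[AssociationResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> list[AssociationResult]:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    out = []
    for _, row in frame.iterrows():
        def _f(v):
            return None if pd.isna(v) else float(v)

        out.append(
            AssociationResult(
                feature_a=str(row["feature_a"]),
                feature_b=str(row["feature_b"]),
                test_id=None if pd.isna(row["test"]) else str(row["test"]),
                n_support=int(row["n"]),
                cohorts_used=tuple(str(row["cohorts"]).split(",")) if row["cohorts"] else (),
                statistic=_f(row["statistic"]),
                p_raw=_f(row["p_raw"]),
                null_mean=_f(row["null_mean"]),
                null_sd=_f(row["null_sd"]),
                z=_f(row["z"]),
                p_bufam=_f(row["p_bufam"]),
                q_fdr=_f(row["q_fdr"]),
                direction=str(row["direction"]),
                testable=bool(row["testable"]),
                reason=None if pd.isna(row["reason"]) else str(row["reason"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# estimator facade


class BufamProfiler(BaseEstimator):
    """Unified pairwise association profiler (sklearn-style estimator).

    ``fit`` runs the full pairwise screen on a :class:`CohortCollection`
    and stores the per-pair records in ``results_`` plus a tidy table in
    ``frame_``.  Composes with sklearn tooling through get_params /
    set_params.

    Examples
    --------
    >>> profiler = BufamProfiler(resamples=1000, seed=7).fit(collection)
    >>> profiler.frame_.head()                              # doctest: +SKIP
    """

    def __init__(self, resamples: int = 1000, min_n: int = 20, seed: int = 0,
                 score_transform: str = "probit", resample_scheme: str = "permutation",
                 fdr_alpha: float = 0.01, mapping: dict | None = None,
                 oneway_variant: str = "welch", min_group: int = 2, n_jobs: int = 1):
        self.resamples = resamples
        self.min_n = min_n
        self.seed = seed
        self.score_transform = score_transform
        self.resample_scheme = resample_scheme
        self.fdr_alpha = fdr_alpha
        self.mapping = mapping
        self.oneway_variant = oneway_variant
        self.min_group = min_group
        self.n_jobs = n_jobs

    def _config(self) -> BufamConfig:
        return BufamConfig(
            resamples=self.resamples, min_n=self.min_n, seed=self.seed,
            score_transform=self.score_transform, resample_scheme=self.resample_scheme,
            fdr_alpha=self.fdr_alpha, mapping=self.mapping,
            oneway_variant=self.oneway_variant, min_group=self.min_group,
            n_jobs=self.n_jobs,
        )

    def fit(self, X: CohortCollection, y=None) -> "BufamProfiler":
        self.results_ = profile_associations(X, self._config())
        self.frame_ = results_to_frame(self.results_)
        self.n_testable_ = int(sum(r.testable for r in self.results_))
        return self

    def significant_(self, q_threshold: float | None = None) -> list[AssociationResult]:
        q = self.fdr_alpha if q_threshold is None else q_threshold
        return [r for r in self.results_ if r.testable and r.q_fdr is not None and r.q_fdr < q]
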