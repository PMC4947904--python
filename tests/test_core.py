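"""Unified p-value engine: null handling, determinism, profiling, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from bufam.core import (
    AssociationResult,
    BufamConfig,
    BufamProfiler,
    _unify,
    adjust_fdr,
    bufam_pvalue,
    profile_associations,
    read_results,
    results_to_frame,
    write_results,
)
from bufam.data_model import pool_pair
from bufam.synthetic import SyntheticSpec, generate


def _two_feature_collection(rho, n=200, dtypes=("numeric", "numeric"), seed=0):
    blocks = [((0, 1), rho)] if rho else []
    spec = SyntheticSpec(n_features=2, blocks=blocks, dtypes=list(dtypes),
                         cohort_specs=[("c1", n, [0, 1])], seed=seed)
    return generate(spec)


class TestUnify:
    def test_observed_equal_to_null_mean_gives_half(self):
        null = np.array([1.0, 2.0, 3.0])
        _, _, z, p = _unify(2.0, null, 100)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_zero_spread_null_below_observed_uses_resampling_floor(self):
        null = np.zeros(100)
        *_, p = _unify(1.0, null, 1000)
        assert p == pytest.approx(1 / 1001)

    def test_zero_spread_null_at_or_above_observed_gives_one(self):
        null = np.zeros(100)
        *_, p = _unify(0.0, null, 1000)
        assert p == 1.0


class TestBufamPvalue:
    def test_strong_planted_association_is_tiny(self):
        coll = _two_feature_collection(0.9, seed=1)
        cfg = BufamConfig(seed=3)
        res = bufam_pvalue(pool_pair(coll, "f00", "f01"), "spearman", cfg,
                           coll.descriptor("f00"), coll.descriptor("f01"))
        assert res.testable
        assert res.p_bufam < 1e-3
        assert res.direction == "positive"

    def test_below_min_n_reported_non_testable(self):
        coll = _two_feature_collection(0.0, n=10, seed=2)
        cfg = BufamConfig(seed=0, min_n=20)
        res = bufam_pvalue(pool_pair(coll, "f00", "f01"), "spearman", cfg,
                           coll.descriptor("f00"), coll.descriptor("f01"))
        assert not res.testable
        assert res.p_bufam is None
        assert "min_n" in res.reason

    def test_deterministic_given_config_seed(self):
        coll = _two_feature_collection(0.3, seed=4)
        cfg = BufamConfig(seed=9)
        args = (pool_pair(coll, "f00", "f01"), "spearman", cfg,
                coll.descriptor("f00"), coll.descriptor("f01"))
        assert bufam_pvalue(*args) == bufam_pvalue(*args)

    def test_bootstrap_scheme_runs_and_differs_from_permutation(self):
        coll = _two_feature_collection(0.3, seed=5)
        pair = pool_pair(coll, "f00", "f01")
        descs = (coll.descriptor("f00"), coll.descriptor("f01"))
        p_perm = bufam_pvalue(pair, "spearman", BufamConfig(seed=1), *descs)
        p_boot = bufam_pvalue(pair, "spearman",
                              BufamConfig(seed=1, resample_scheme="bootstrap"), *descs)
        assert p_boot.testable
        assert p_boot.null_sd != p_perm.null_sd

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BufamConfig(resamples=10)
        with pytest.raises(ValueError):
            BufamConfig(min_n=2)
        with pytest.raises(ValueError):
            BufamConfig(score_transform="nope")


class TestProfile:
    def _collection(self, seed=0):
        # 5 features, two cohorts with partial coverage: f00/f04 disjoint
        spec = SyntheticSpec(
            n_features=5, blocks=[((0, 1), 0.5)],
            dtypes=["numeric", "ordinal", "binary", "numeric", "numeric"],
            cohort_specs=[("c1", 120, [0, 1, 2, 3]), ("c2", 120, [1, 2, 3, 4])],
            seed=seed,
        )
        return generate(spec)

    def test_one_result_per_unordered_pair(self):
        results = profile_associations(self._collection(), BufamConfig(seed=1))
        assert len(results) == 10

    def test_disjoint_coverage_pair_present_but_non_testable(self):
        results = profile_associations(self._collection(), BufamConfig(seed=1))
        lookup = {(r.feature_a, r.feature_b): r for r in results}
        r = lookup[("f00", "f04")]
        assert not r.testable
        assert r.n_support == 0

    def test_same_seed_bitwise_identical_tables(self):
        coll = self._collection()
        frame1 = results_to_frame(profile_associations(coll, BufamConfig(seed=5)))
        frame2 = results_to_frame(profile_associations(coll, BufamConfig(seed=5)))
        pd.testing.assert_frame_equal(frame1, frame2, check_exact=True)

    def test_results_invariant_to_unrelated_features(self):
        coll = self._collection()
        results_all = profile_associations(coll, BufamConfig(seed=5))
        small = coll.subset_cohorts([c.cohort_id for c in coll.cohorts])
        # drop feature f04 entirely
        from bufam.data_model import CohortCollection, CohortTable

        descs = tuple(d for d in coll.descriptors if d.name != "f04")
        cohorts = [CohortTable(c.cohort_id,
                               c.data[[col for col in c.data.columns if col != "f04"]])
                   for c in coll.cohorts]
        results_small = profile_associations(CohortCollection(descs, cohorts),
                                             BufamConfig(seed=5))
        big = {(r.feature_a, r.feature_b): r for r in results_all}
        for r in results_small:
            ref = big[(r.feature_a, r.feature_b)]
            assert r.p_bufam == ref.p_bufam
            assert r.statistic == ref.statistic

    def test_profiler_estimator_facade(self):
        profiler = BufamProfiler(resamples=200, seed=2)
        assert profiler.get_params()["resamples"] == 200
        profiler.fit(self._collection())
        assert len(profiler.results_) == 10
        assert profiler.n_testable_ >= 1
        assert set(profiler.frame_.columns) >= {"feature_a", "p_bufam", "q_fdr"}

    def test_results_tsv_round_trip(self, tmp_path):
        results = profile_associations(self._collection(), BufamConfig(seed=1))
        path = tmp_path / "assoc.tsv"
        write_results(results, path)
        again = read_results(path)
        assert len(again) == len(results)
        for a, b in zip(results, again):
            assert a.feature_a == b.feature_a
            assert a.testable == b.testable
            if a.testable:
                assert a.p_bufam == pytest.approx(b.p_bufam)


def _mk(p):
    return AssociationResult("a", "b", testable=True, p_bufam=p)


class TestAdjustFdr:
    def test_worked_example(self):
        results = [_mk(p) for p in (0.01, 0.02, 0.03, 0.04)]
        qs = [r.q_fdr for r in adjust_fdr(results)]
        assert qs == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_fixed_point_and_single_p(self):
        assert adjust_fdr([_mk(1.0), _mk(1.0)])[0].q_fdr == 1.0
        assert adjust_fdr([_mk(0.037)])[0].q_fdr == pytest.approx(0.037)

    def test_non_testable_untouched(self):
        nt = AssociationResult("a", "b", testable=False)
        out = adjust_fdr([nt, _mk(0.5)])
        assert out[0].q_fdr is None

    @given(st_h.lists(st_h.floats(1e-8, 1.0), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_matches_exhaustive_definition(self, ps):
        from conftest import bh_oracle

        qs = [r.q_fdr for r in adjust_fdr([_mk(p) for p in ps])]
        np.testing.assert_allclose(qs, bh_oracle(ps), rtol=1e-12)
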