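"""Raw association tests: mapping, worked examples, oracles, invariants."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

from bufam.assoc_tests import (
    DEFAULT_MAPPING,
    DegenerateInput,
    encode_feature,
    polarity,
    prepare_test,
    run_raw_test,
    select_test,
)
from bufam.data_model import DTYPES, FeatureDescriptor

from conftest import make_pair, mwu_exact_oracle

NUM_A = FeatureDescriptor("a", "numeric")
NUM_B = FeatureDescriptor("b", "numeric")
BIN_B = FeatureDescriptor("b", "binary", ("g0", "g1"), positive_level="g1")
NOM_B = FeatureDescriptor("b", "nominal", ("k0", "k1", "k2"))
ORD_A = FeatureDescriptor("a", "ordinal", ("l0", "l1", "l2"))
ORD_B = FeatureDescriptor("b", "ordinal", ("m0", "m1", "m2"))


class TestSelectTest:
    def test_symmetric_and_total_over_all_ordered_type_pairs(self):
        for da, db in product(DTYPES, DTYPES):
            assert select_test(da, db) == select_test(db, da)

    @pytest.mark.parametrize(
        "da,db,expected",
        [
            ("numeric", "numeric", "spearman"),
            ("binary", "binary", "chisq"),
            ("ordinal", "ordinal", "lbl"),
            ("numeric", "binary", "wilcoxon"),
            ("numeric", "nominal", "oneway"),
            ("ordinal", "binary", "lbl"),
            ("ordinal", "nominal", "oneway"),
        ],
    )
    def test_default_mapping_entries(self, da, db, expected):
        assert select_test(da, db) == expected

    def test_mapping_override(self):
        mapping = dict(DEFAULT_MAPPING)
        mapping[("numeric", "numeric")] = "lbl"
        assert select_test("numeric", "numeric", mapping) == "lbl"


class TestWorkedExamples:
    def test_spearman_perfect_monotone(self):
        r = run_raw_test(make_pair([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]), "spearman",
                         NUM_A, NUM_B)
        assert r.statistic == pytest.approx(1.0)
        assert r.direction == "positive"

    def test_chisq_2x2_closed_form(self):
        # table [[10, 20], [20, 10]]: all expected counts 15, chi2 = 100/15
        x = ["x0"] * 30 + ["x1"] * 30
        y = ["g0"] * 10 + ["g1"] * 20 + ["g0"] * 20 + ["g1"] * 10
        r = run_raw_test(make_pair(x, y), "chisq",
                         FeatureDescriptor("a", "binary", ("x0", "x1")), BIN_B)
        assert r.statistic == pytest.approx(100 / 15)

    def test_wilcoxon_small_sample_exact_p(self):
        r = run_raw_test(make_pair([1, 2, 3, 4, 5, 6], ["g0"] * 3 + ["g1"] * 3),
                         "wilcoxon", NUM_A, BIN_B)
        assert r.p_raw == pytest.approx(2 / 20)

    def test_lbl_diagonal_2x2(self):
        x = ["l0"] * 10 + ["l1"] * 10
        y = ["m0"] * 10 + ["m1"] * 10
        r = run_raw_test(make_pair(x, y), "lbl",
                         FeatureDescriptor("a", "ordinal", ("l0", "l1")),
                         FeatureDescriptor("b", "ordinal", ("m0", "m1")))
        assert r.statistic == pytest.approx(19.0)

    def test_oneway_identical_groups_is_null(self):
        r = run_raw_test(make_pair([1, 2, 3] * 3, ["k0"] * 3 + ["k1"] * 3 + ["k2"] * 3),
                         "oneway", NUM_A, NOM_B)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)


class TestOracleAgreement:
    def test_spearman_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(10, 40)
            x = rng.integers(0, 8, n).astype(float)
            y = rng.integers(0, 8, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            r = run_raw_test(make_pair(x, y), "spearman", NUM_A, NUM_B)
            ref = stats.spearmanr(x, y)
            assert r.statistic == pytest.approx(ref.statistic)
            assert r.p_raw == pytest.approx(ref.pvalue)

    def test_wilcoxon_exact_matches_enumeration(self):
        rng = np.random.default_rng(12)
        done = 0
        while done < 15:
            n1 = int(rng.integers(3, 5))
            n2 = int(rng.integers(3, 6))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # untied
            g1, g2 = vals[:n1], vals[n1:]
            pair = make_pair(np.concatenate([g1, g2]),
                             ["g1"] * n1 + ["g0"] * n2)
            r = run_raw_test(pair, "wilcoxon", NUM_A, BIN_B)
            assert r.p_raw == pytest.approx(mwu_exact_oracle(g1, g2))
            done += 1

    def test_chisq_matches_scipy_contingency(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = 150
            x = rng.integers(0, 3, n)
            y = rng.integers(0, 3, n)
            pair = make_pair([f"k{v}" for v in x], [f"k{v}" for v in y])
            da = FeatureDescriptor("a", "nominal", ("k0", "k1", "k2"))
            db = FeatureDescriptor("b", "nominal", ("k0", "k1", "k2"))
            r = run_raw_test(pair, "chisq", da, db)
            import pandas as pd

            table = pd.crosstab(x, y).to_numpy()
            ref = stats.chi2_contingency(table, correction=False)
            assert r.statistic == pytest.approx(ref.statistic)
            assert r.p_raw == pytest.approx(ref.pvalue)

    def test_oneway_matches_pingouin_welch(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(14)
        for _ in range(10):
            n = 60
            vals = rng.normal(size=n)
            grp = rng.integers(0, 3, n)
            pair = make_pair(vals, [f"k{g}" for g in grp])
            r = run_raw_test(pair, "oneway", NUM_A, NOM_B)
            aov = pg.welch_anova(dv="v", between="g",
                                 data=pd.DataFrame({"v": vals, "g": grp}))
            assert r.statistic == pytest.approx(float(aov["F"][0]))
            assert r.p_raw == pytest.approx(float(aov["p_unc"][0]))

    def test_lbl_equals_n_minus_one_r_squared(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            n = 80
            x = rng.integers(0, 3, n)
            y = rng.integers(0, 3, n)
            pair = make_pair([f"l{v}" for v in x], [f"m{v}" for v in y])
            r = run_raw_test(pair, "lbl", ORD_A, ORD_B)
            rho = np.corrcoef(x, y)[0, 1]
            assert r.statistic == pytest.approx((n - 1) * rho**2)


class TestInvariants:
    def test_p_invariant_to_sample_order(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        pair = make_pair(x, [f"g{v}" for v in y])
        r1 = run_raw_test(pair, "wilcoxon", NUM_A, BIN_B)
        perm = rng.permutation(50)
        pair2 = make_pair(x[perm], [f"g{v}" for v in y[perm]])
        r2 = run_raw_test(pair2, "wilcoxon", NUM_A, BIN_B)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_2x2_lbl_chisq_algebraic_relation(self):
        # M^2 = chi2 * (N - 1) / N on any 2x2 table
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = 120
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            xa = FeatureDescriptor("a", "ordinal", ("l0", "l1"))
            yb = FeatureDescriptor("b", "ordinal", ("m0", "m1"))
            pair = make_pair([f"l{v}" for v in x], [f"m{v}" for v in y])
            m2 = run_raw_test(pair, "lbl", xa, yb).statistic
            chi = run_raw_test(
                make_pair([f"l{v}" for v in x], [f"m{v}" for v in y]), "chisq",
                FeatureDescriptor("a", "nominal", ("l0", "l1")),
                FeatureDescriptor("b", "nominal", ("m0", "m1"))).statistic
            assert m2 == pytest.approx(chi * (n - 1) / n)

    def test_vectorised_scorer_matches_scalar_on_permutations(self):
        from bufam.data_model import pool_pair
        from bufam.synthetic import SyntheticSpec, generate

        cases = [("spearman", "numeric", "numeric"), ("wilcoxon", "numeric", "binary"),
                 ("oneway", "numeric", "nominal"), ("chisq", "nominal", "binary"),
                 ("lbl", "ordinal", "ordinal")]
        for test_id, da, db in cases:
            spec = SyntheticSpec(n_features=2, dtypes=[da, db],
                                 cohort_specs=[("c", 80, [0, 1])], seed=7)
            coll = generate(spec)
            pair = pool_pair(coll, "f00", "f01")
            prep = prepare_test(pair, test_id, coll.descriptor("f00"),
                                coll.descriptor("f01"))
            rows = np.random.default_rng(1).permuted(
                np.tile(prep.base, (8, 1)), axis=1)
            sv, pv = prep.score(rows)
            for i in range(8):
                s1, p1 = prep.score(rows[i][None, :])
                assert sv[i] == pytest.approx(s1[0])
                assert pv[i] == pytest.approx(p1[0])

    def test_constant_feature_is_degenerate(self):
        with pytest.raises(DegenerateInput):
            run_raw_test(make_pair([1.0] * 30, list(range(30))), "spearman",
                         NUM_A, NUM_B)

    def test_sparse_contingency_table_fails_expected_count_guard(self):
        x = ["k0"] * 2 + ["k1"] * 2 + ["k2"] * 2
        y = ["g0", "g1"] * 3
        da = FeatureDescriptor("a", "nominal", ("k0", "k1", "k2"))
        with pytest.raises(DegenerateInput, match="expected"):
            run_raw_test(make_pair(x, y), "chisq", da, BIN_B)


class TestPolarity:
    def test_monotone_numeric_pairs(self):
        up = make_pair([1, 2, 3, 4], [2, 3, 5, 9])
        assert polarity(up, NUM_A, NUM_B) == "positive"
        down = make_pair([1, 2, 3, 4], [9, 5, 3, 2])
        assert polarity(down, NUM_A, NUM_B) == "negative"

    def test_nominal_participant_is_not_applicable(self):
        pair = make_pair([1, 2, 3, 4, 5, 6], ["k0", "k1", "k2"] * 2)
        assert polarity(pair, NUM_A, NOM_B) == "not_applicable"

    def test_binary_against_decreasing_numeric_is_negative(self):
        pair = make_pair([5, 4, 3, 2, 1, 0], ["g0"] * 3 + ["g1"] * 3)
        assert polarity(pair, NUM_A, BIN_B) == "negative"

    def test_positive_level_flip_flips_sign(self):
        flipped = FeatureDescriptor("b", "binary", ("g0", "g1"), positive_level="g0")
        pair = make_pair([5, 4, 3, 2, 1, 0], ["g0"] * 3 + ["g1"] * 3)
        assert polarity(pair, NUM_A, flipped) == "positive"

    def test_encoding_binary_positive_level(self):
        codes = encode_feature(np.array(["g0", "g1", "g0"], dtype=object), BIN_B)
        np.testing.assert_array_equal(codes, [0.0, 1.0, 0.0])
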