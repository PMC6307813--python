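import itertools

import numpy as np
import pandas as pd
import pytest

from adsexnet import (
    DataError,
    dichotomize_by_expression,
    km_curve,
    logrank_test,
    screen_traits,
)


class TestDichotomize:
    def test_median_split_even_n(self):
        labels = dichotomize_by_expression(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        )
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_n_median_goes_low(self):
        labels = dichotomize_by_expression(
            pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        )
        assert list(labels) == ["low", "low", "low", "high", "high"]

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            dichotomize_by_expression(pd.Series([2.0] * 6))

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            dichotomize_by_expression(pd.Series([1.0, 2.0, 3.0]))


class TestKMCurve:
    def test_no_censoring_equals_one_minus_ecdf(self):
        curve = km_curve([1.0, 2.0, 3.0])
        assert list(curve.times) == [1.0, 2.0, 3.0]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at(0.5) == 1.0
        assert curve.at(2.0) == pytest.approx(1 / 3)  # right-continuous

    def test_single_sample(self):
        curve = km_curve([4.2])
        assert list(curve.times) == [4.2]
        assert curve.survival == pytest.approx([0.0])

    def test_ties_drop_together(self):
        curve = km_curve([1.0, 1.0, 2.0, 2.0])
        assert curve.survival == pytest.approx([0.5, 0.0])

    def test_censoring_matches_hand_product_limit(self):
        # times 1,2,3,4,5 with events 1,0,1,1,0:
        # S = 4/5 at t=1; 4/5 * 2/3 at t=3; * 1/2 at t=4; censored times step nothing
        curve = km_curve([1, 2, 3, 4, 5], events=[True, False, True, True, False])
        assert list(curve.times) == [1.0, 3.0, 4.0]
        assert curve.survival == pytest.approx([4 / 5, 4 / 5 * 2 / 3, 4 / 5 * 2 / 3 / 2])

    def test_random_uncensored_matches_ecdf_everywhere(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 6, size=25).astype(float)  # heavy ties
        curve = km_curve(vals)
        for t in np.unique(vals):
            assert curve.at(t) == pytest.approx((vals > t).mean())


class TestLogrank:
    def test_identical_groups_null(self):
        res = logrank_test([1, 2, 3, 1, 2, 3], ["low"] * 3 + ["high"] * 3)
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_separated_groups(self):
        # groups (1,2,3) vs (4,5,6): O-E = 0.5+0.6+0.75, V = 0.25+0.24+0.1875
        res = logrank_test([1, 2, 3, 4, 5, 6], ["low"] * 3 + ["high"] * 3)
        o_minus_e = (1 - 3 / 6) + (1 - 2 / 5) + (1 - 1 / 4)
        variance = 9 / 36 + 6 / 25 + 3 / 16
        assert res.chi_square == pytest.approx(o_minus_e**2 / variance)

    def test_exhaustive_permutation_p(self):
        # the observed complete separation is the most extreme of all
        # C(6,3)=20 label assignments (2 of 20 reach the same statistic)
        values = [1, 2, 3, 4, 5, 6]
        obs = logrank_test(values, ["low"] * 3 + ["high"] * 3).chi_square
        stats = []
        for low_idx in itertools.combinations(range(6), 3):
            labels = ["high"] * 6
            for i in low_idx:
                labels[i] = "low"
            stats.append(logrank_test(values, labels).chi_square)
        p_perm = np.mean([s >= obs - 1e-12 for s in stats])
        assert p_perm == pytest.approx(2 / 20)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.gamma(2.0, 2.0, size=15)
            b = rng.gamma(2.0, 3.0, size=12)
            ours = logrank_test(
                np.concatenate([a, b]), ["low"] * 15 + ["high"] * 12
            )
            theirs = ll_logrank(a, b)
            assert ours.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 10, 20)
        labels = ["low"] * 10 + ["high"] * 10
        a = logrank_test(vals, labels).chi_square
        b = logrank_test(np.exp(vals / 3.0), labels).chi_square
        assert a == pytest.approx(b)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, 14)
        labels = np.array(["low"] * 7 + ["high"] * 7)
        flipped = np.where(labels == "low", "high", "low")
        assert logrank_test(vals, labels).chi_square == pytest.approx(
            logrank_test(vals, flipped).chi_square
        )

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            logrank_test([1, 2, 3], ["low"] * 3)


class TestScreenTraits:
    def test_driver_gene_hits_all_traits(self, demo_cohort):
        expr, meta, truth = demo_cohort
        results = screen_traits(expr, meta, [truth.trait_driver.gene],
                                ["braak_score", "plaque_density", "cerad_sum", "tangle_sum"])
        assert len(results) == 4
        assert all(r.p_value < 0.05 for r in results)

    def test_effect_free_gene_mostly_null(self, demo_cohort):
        expr, meta, _ = demo_cohort
        results = screen_traits(expr, meta, ["G0200"], ["braak_score"])
        assert results[0].p_value > 0.001  # no planted effect

    def test_missing_trait_named(self, demo_cohort):
        expr, meta, _ = demo_cohort
        meta_no = type(meta)(meta.table.drop(columns=["cerad_sum"]))
        with pytest.raises(DataError, match="cerad_sum"):
            screen_traits(expr, meta_no, ["GSK3B"], ["cerad_sum"])

    def test_empty_gene_list(self, demo_cohort):
        expr, meta, _ = demo_cohort
        assert screen_traits(expr, meta, [], ["braak_score"]) == []
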