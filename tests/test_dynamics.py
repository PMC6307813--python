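import numpy as np
import pytest
from hypothesis import given, strategies as st

from adsexnet import (
    DataError,
    compare_score_distributions,
    conserved_network,
    dynamic_score,
    score_from_counts,
    stage_networks,
)
from adsexnet.dynamics import DynamicScoreRecord
from adsexnet.network import CoexpressionNetwork, EdgeStats
from adsexnet.simulate import default_config, simulate_cohort


def _net(edges):
    return CoexpressionNetwork({tuple(sorted(e)): EdgeStats(0.95, 1e-4) for e in edges})


def _rec(region, sex, score):
    return DynamicScoreRecord(region, sex, {}, 100, int(round((1 - score) * 100)), score)


class TestScoreFromCounts:
    def test_full_overlap_scores_zero(self):
        assert score_from_counts(100, 100) == 0.0

    def test_empty_overlap_scores_one(self):
        assert score_from_counts(100, 0) == 1.0

    def test_zero_normal_undefined(self):
        with pytest.raises(DataError, match="undefined"):
            score_from_counts(0, 0)

    def test_overlap_exceeding_normal_rejected(self):
        with pytest.raises(DataError, match="invalid counts"):
            score_from_counts(10, 11)


class TestDynamicScore:
    def test_unavailable_stages_excluded_from_intersection(self):
        stage_map = {
            "normal": _net([("a", "b"), ("b", "c"), ("c", "d")]),
            "possible_AD": None,  # N/A: excluded, NOT treated as empty
            "probable_AD": _net([("a", "b"), ("b", "c")]),
            "definite_AD": _net([("a", "b")]),
        }
        rec = dynamic_score(stage_map, "frontal pole", "male")
        assert rec.overlap_num == 1
        assert rec.score == pytest.approx(1 - 1 / 3)
        assert rec.stage_edge_counts["possible_AD"] is None

    def test_missing_normal_stage_is_error(self):
        with pytest.raises(DataError, match="normal"):
            dynamic_score({"normal": None, "definite_AD": _net([("a", "b")])})

    def test_adding_stage_never_lowers_score(self):
        rng = np.random.default_rng(0)
        pool = [(f"g{i}", f"g{j}") for i in range(8) for j in range(i + 1, 8)]
        for _ in range(25):
            take = lambda: _net(
                [pool[k] for k in rng.choice(len(pool), rng.integers(1, 20), replace=False)]
            )
            base = {"normal": take(), "possible_AD": take()}
            more = dict(base)
            more["definite_AD"] = take()
            assert dynamic_score(more).score >= dynamic_score(base).score
            assert 0.0 <= dynamic_score(more).score <= 1.0

    def test_stage_rewiring_detected_in_synthetic_cohort(self):
        expr, meta, truth = simulate_cohort(
            default_config(seed=2, n_subjects_per_sex=80)
        )
        nets = stage_networks(expr, meta, "frontal pole", "male")
        assert nets["normal"] is not None
        definite = nets["definite_AD"]
        assert definite is not None
        rewired_present = truth.stage_rewired_edges & set(nets["normal"].edges)
        assert len(rewired_present) >= 0.9 * len(truth.stage_rewired_edges)
        assert not (truth.stage_rewired_edges & set(definite.edges))
        rec = dynamic_score(nets, "frontal pole", "male")
        assert rec.score > 0.0  # normal-only co-expression was lost


class TestStageNetworks:
    def test_sparse_stage_marked_unavailable(self, demo_cohort):
        expr, meta, _ = demo_cohort
        # shrink to 3 normal samples for this region/sex by dropping columns
        normals = meta.samples_where(sex="male", region="frontal pole", stage="normal")
        keep = [s for s in expr.sample_ids if s not in normals[3:]]
        sub_expr = type(expr)(expr.values.loc[:, keep])
        sub_meta = type(meta)(meta.table.loc[keep])
        nets = stage_networks(sub_expr, sub_meta, "frontal pole", "male", min_samples=4)
        assert nets["normal"] is None

    def test_all_stages_built_when_populated(self, demo_cohort):
        expr, meta, _ = demo_cohort
        nets = stage_networks(expr, meta, "frontal pole", "male")
        assert all(nets[s] is not None for s in nets)


class TestConservedNetwork:
    def test_identical_regions(self):
        net = _net([("a", "b"), ("b", "c")])
        cons = conserved_network({"r1": net, "r2": net, "r3": net})
        assert cons.edges == net.edge_set()

    def test_one_empty_region_empties_intersection(self):
        cons = conserved_network({"r1": _net([("a", "b")]), "r2": _net([])})
        assert cons.edges == frozenset()

    def test_shared_triangle_average_degree(self):
        tri = [("a", "b"), ("b", "c"), ("a", "c")]
        nets = {
            "r1": _net(tri + [("x", "y")]),
            "r2": _net(tri + [("p", "q")]),
            "r3": _net(tri),
        }
        cons = conserved_network(nets)
        assert cons.edges == frozenset(tri)
        assert cons.average_degree == pytest.approx(2.0)


class TestCompareScores:
    def test_identical_paired_scores(self):
        m = [_rec("frontal pole", "male", 0.9), _rec("putamen", "male", 0.8)]
        f = [_rec("frontal pole", "female", 0.9), _rec("putamen", "female", 0.8)]
        out = compare_score_distributions(m, f)
        assert out["p_value"] == 1.0

    def test_exact_wilcoxon_on_six_pairs(self):
        # uniform +0.1 shift over 6 pairs: exact two-sided p = 2/2^6 = 0.03125
        regions = ["frontal pole", "putamen", "hippocampus",
                   "temporal pole", "caudate nucleus", "anterior cingulate"]
        m = [_rec(r, "male", 0.8 + 0.01 * i + 0.1) for i, r in enumerate(regions)]
        f = [_rec(r, "female", 0.8 + 0.01 * i) for i, r in enumerate(regions)]
        out = compare_score_distributions(m, f)
        assert out["n_pairs"] == 6
        assert out["p_value"] == pytest.approx(2 / 64)

    def test_uniform_shift_17_pairs_significant(self):
        from adsexnet.core import REGIONS

        m = [_rec(r, "male", 0.8 + 0.005 * i + 0.1) for i, r in enumerate(REGIONS)]
        f = [_rec(r, "female", 0.8 + 0.005 * i) for i, r in enumerate(REGIONS)]
        out = compare_score_distributions(m, f)
        assert out["p_value"] < 0.001
        assert out["male_range"][0] > out["female_range"][0]

    def test_sign_test_alternative(self):
        regions = ["frontal pole", "putamen", "hippocampus", "temporal pole",
                   "caudate nucleus", "anterior cingulate"]
        m = [_rec(r, "male", 0.9) for r in regions]
        f = [_rec(r, "female", 0.8) for r in regions]
        out = compare_score_distributions(m, f, method="sign")
        assert out["p_value"] == pytest.approx(2 / 64)

    def test_unpaired_regions_listed(self):
        m = [_rec("frontal pole", "male", 0.9)]
        f = [_rec("putamen", "female", 0.8)]
        with pytest.raises(DataError, match="frontal pole"):
            compare_score_distributions(m, f)
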