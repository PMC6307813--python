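import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adsexnet import (
    DataError,
    build_network,
    correlation_pvalue,
    jaccard_edges,
    jaccard_from_counts,
    network_partition,
    pairwise_region_similarity,
)
from adsexnet.core import ExpressionMatrix
from adsexnet.network import CoexpressionNetwork, EdgeStats


def _net(edges):
    return CoexpressionNetwork(
        {tuple(sorted(e)): EdgeStats(0.95, 1e-4) for e in edges}
    )


class TestCorrelationPvalue:
    def test_zero_correlation_p_one(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_perfect_correlation_p_zero(self):
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            correlation_pvalue(0.5, 2)

    def test_matches_permutation_oracle(self):
        # one fixed vector pair with r ~ 0.9 at n = 10
        rng = np.random.default_rng(123)
        x = rng.normal(size=10)
        y = 0.9 * x + 0.45 * rng.normal(size=10)
        r_obs = np.corrcoef(x, y)[0, 1]
        p_analytic = correlation_pvalue(r_obs, 10)
        n_perm = 100_000
        xc, yc = x - x.mean(), y - y.mean()
        perms = np.argsort(rng.random((n_perm, 10)), axis=1)
        perm_rs = (yc[perms] @ xc) / (np.linalg.norm(xc) * np.linalg.norm(yc))
        p_perm = (np.abs(perm_rs) >= abs(r_obs)).mean()
        # Monte-Carlo error ~ sqrt(p/n); allow 4 sigma plus analytic slack
        tol = 4 * np.sqrt(max(p_perm, p_analytic) / n_perm) + 0.002
        assert p_analytic == pytest.approx(p_perm, abs=tol)


class TestBuildNetwork:
    def test_identical_genes_single_edge(self):
        rng = np.random.default_rng(5)
        g1 = rng.uniform(1, 100, 20)
        df = pd.DataFrame(
            {f"s{i}": [g1[i], 2 * g1[i], rng.uniform(1, 100)] for i in range(20)},
            index=["g1", "g2", "g3"],
        )
        net = build_network(ExpressionMatrix(df), log_transform=False)
        assert set(net.edges) == {("g1", "g2")}
        assert net.edges[("g1", "g2")].pcc == pytest.approx(1.0)

    def test_threshold_one_gives_empty_network(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.uniform(1, 100, size=(5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(30)],
        )
        assert build_network(ExpressionMatrix(df), r_threshold=1.0).n_edges == 0

    def test_signed_mode_drops_negative_correlations(self):
        n = 30
        rng = np.random.default_rng(8)
        x = rng.normal(8, 1, n)
        df = pd.DataFrame(
            np.exp2(np.vstack([x, -x + 16, x + rng.normal(0, 1e-3, n)])),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(n)],
        )
        unsigned = build_network(ExpressionMatrix(df), 0.9, 0.01)
        signed = build_network(ExpressionMatrix(df), 0.9, 0.01, signed=True)
        assert ("g1", "g2") in unsigned.edges and unsigned.edges[("g1", "g2")].pcc < 0
        assert ("g1", "g2") not in signed.edges
        assert ("g1", "g3") in signed.edges

    def test_planted_module_recovery(self):
        # 10-gene module, loading 0.95, noise 0.1, n=50:
        # theoretical PCC = 0.95^2/(0.95^2+0.1^2) ~ 0.989 >> 0.9
        rng = np.random.default_rng(9)
        n = 50
        factor = rng.normal(size=n)
        module = 8.0 + 0.95 * factor + rng.normal(0, 0.1, size=(10, n))
        noise = 8.0 + rng.normal(0, 0.1, size=(30, n))
        df = pd.DataFrame(
            np.exp2(np.vstack([module, noise])),
            index=[f"m{i:02d}" for i in range(10)] + [f"x{i:02d}" for i in range(30)],
            columns=[f"s{i}" for i in range(n)],
        )
        net = build_network(ExpressionMatrix(df), 0.9, 0.01)
        within = {e for e in net.edges if e[0].startswith("m") and e[1].startswith("m")}
        assert len(within) >= 40  # of 45 pairs
        assert len(net.edges) - len(within) <= 2  # essentially no background edges

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            rng.uniform(1, 50, size=(8, 25)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(25)],
        )
        df.iloc[1] = df.iloc[0] * 1.7
        df.iloc[5] = df.iloc[4] * 0.3
        net_a = build_network(ExpressionMatrix(df), 0.9, 0.01)
        shuffled = df.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        net_b = build_network(ExpressionMatrix(shuffled), 0.9, 0.01)
        assert net_a.edge_set() == net_b.edge_set()

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        base = rng.normal(8, 1, 40)
        data = np.exp2(base + rng.normal(0, 0.6, size=(15, 40)))
        expr = ExpressionMatrix(
            pd.DataFrame(data, index=[f"g{i}" for i in range(15)],
                         columns=[f"s{i}" for i in range(40)])
        )
        counts = [
            build_network(expr, r, alpha=0.5).n_edges for r in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zero_variance_genes_skipped(self):
        df = pd.DataFrame(
            {"s1": [1.0, 5.0, 2.0], "s2": [2.0, 5.0, 4.0], "s3": [3.0, 5.0, 6.0],
             "s4": [4.0, 5.0, 8.0]},
            index=["g1", "gflat", "g2"],
        )
        net = build_network(ExpressionMatrix(df), 0.9, 0.05, log_transform=False)
        assert net.provenance["n_zero_variance_skipped"] == 1
        assert "gflat" not in net.nodes


class TestPartition:
    def test_identical_networks(self):
        net = _net([("a", "b"), ("b", "c")])
        m_spec, f_spec, overlap = network_partition(net, net)
        assert m_spec.n_edges == f_spec.n_edges == 0
        assert overlap.edge_set() == net.edge_set()

    def test_disjoint_networks(self):
        m_spec, f_spec, overlap = network_partition(
            _net([("a", "b")]), _net([("c", "d")])
        )
        assert overlap.n_edges == 0
        assert m_spec.edge_set() == frozenset({("a", "b")})

    def test_three_way_enumeration(self):
        m_spec, f_spec, overlap = network_partition(
            _net([("a", "b"), ("b", "c")]), _net([("b", "c"), ("c", "d")])
        )
        assert m_spec.edge_set() == frozenset({("a", "b")})
        assert overlap.edge_set() == frozenset({("b", "c")})
        assert f_spec.edge_set() == frozenset({("c", "d")})

    def test_overlap_carries_both_pccs(self):
        net_m = CoexpressionNetwork({("a", "b"): EdgeStats(0.95, 1e-4)})
        net_f = CoexpressionNetwork({("a", "b"): EdgeStats(0.91, 1e-3)})
        _, _, overlap = network_partition(net_m, net_f)
        st_ = overlap.edges[("a", "b")]
        assert (st_.pcc, st_.pcc_other) == (0.95, 0.91)

    @given(
        st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)).filter(lambda t: t[0] < t[1]), max_size=15),
        st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)).filter(lambda t: t[0] < t[1]), max_size=15),
    )
    def test_partition_conserves_edge_counts(self, edges_a, edges_b):
        net_a = _net([(f"g{i}", f"g{j}") for i, j in edges_a])
        net_b = _net([(f"g{i}", f"g{j}") for i, j in edges_b])
        m_spec, f_spec, overlap = network_partition(net_a, net_b)
        assert m_spec.n_edges + overlap.n_edges == net_a.n_edges
        assert f_spec.n_edges + overlap.n_edges == net_b.n_edges


class TestJaccard:
    def test_equal_sets(self):
        edges = {("a", "b"), ("b", "c")}
        assert jaccard_edges(edges, edges).jaccard == 1.0

    def test_disjoint_sets(self):
        assert jaccard_edges({("a", "b")}, {("c", "d")}).jaccard == 0.0

    def test_both_empty_flagged(self):
        rec = jaccard_edges(set(), set())
        assert rec.jaccard == 0.0 and rec.both_empty

    def test_from_counts_inconsistent_rejected(self):
        with pytest.raises(DataError):
            jaccard_from_counts(10, 5, 7)

    @given(
        st.sets(st.integers(0, 20), max_size=15),
        st.sets(st.integers(0, 20), max_size=15),
    )
    def test_symmetry_and_identity(self, a, b):
        ea = {(f"g{i}", f"h{i}") for i in a}
        eb = {(f"g{i}", f"h{i}") for i in b}
        assert jaccard_edges(ea, eb).jaccard == jaccard_edges(eb, ea).jaccard
        assert (jaccard_edges(ea, eb).jaccard == 1.0) == (ea == eb != set())


class TestPairwiseSimilarity:
    def test_identical_networks_all_ones(self):
        net = _net([("a", "b"), ("b", "c")])
        mat, avg = pairwise_region_similarity({"r1": net, "r2": net, "r3": net})
        assert (mat.to_numpy() == 1.0).all()
        assert (avg == 1.0).all()

    def test_matches_brute_force_set_arithmetic(self):
        nets = {
            "r1": _net([("a", "b"), ("b", "c"), ("c", "d")]),
            "r2": _net([("b", "c"), ("d", "e")]),
            "r3": _net([("a", "b")]),
        }
        mat, _ = pairwise_region_similarity(nets)
        for x, y in itertools.combinations(nets, 2):
            ex, ey = set(nets[x].edges), set(nets[y].edges)
            assert mat.loc[x, y] == pytest.approx(len(ex & ey) / len(ex | ey))

    def test_permutation_consistency(self):
        nets = {
            "r1": _net([("a", "b")]),
            "r2": _net([("a", "b"), ("c", "d")]),
            "r3": _net([("e", "f")]),
        }
        mat1, _ = pairwise_region_similarity(nets)
        mat2, _ = pairwise_region_similarity(dict(reversed(list(nets.items()))))
        pd.testing.assert_frame_equal(
            mat1, mat2.loc[mat1.index, mat1.columns], check_like=False
        )
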