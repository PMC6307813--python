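"""Pearson-correlation co-expression networks and set-based comparisons.

An edge joins two genes whose expression profiles correlate with |PCC|
above a hard threshold (default 0.9) at a significance level (default
p < 0.01, two-sided t-transform). Both inequalities are strict. Networks
from male and female cohorts are partitioned into sex-specific and overlap
networks, and edge sets are compared with the Jaccard index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, ExpressionMatrix

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Unordered gene pair in canonical (sorted) order; self-edges rejected."""
    if a == b:
        raise DataError(f"self-edge on {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class EdgeStats:
    pcc: float
    p_value: float
    pcc_other: float | None = None  # second cohort's PCC on overlap edges


@dataclass
class CoexpressionNetwork:
    """Undirected gene network; nodes are exactly the edge endpoints."""

    edges: dict[Edge, EdgeStats]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a >= b:
                raise DataError(f"edge ({a!r}, {b!r}) not in canonical order")

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for (a, b), st in self.edges.items():
            g.add_edge(a, b, pcc=st.pcc, p_value=st.p_value)
        return g

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "pcc": st.pcc, "p_value": st.p_value}
            for (a, b), st in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "p_value"])


@dataclass(frozen=True)
class SimilarityRecord:
    """Jaccard similarity between two named sets (edges or genes)."""

    name_a: str
    name_b: str
    jaccard: float
    intersection: int
    union: int
    both_empty: bool = False


def correlation_pvalue(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p-value for a Pearson correlation of ``r`` over ``n`` samples.

    Uses the exact t-transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees
    of freedom; |r| = 1 maps to p = 0.
    """
    if n < 3:
        raise DataError(f"need at least 3 samples for a correlation p-value, got {n}")
    r_arr = np.asarray(r, dtype=float)
    if (np.abs(r_arr) > 1 + 1e-12).any():
        raise DataError("correlation outside [-1, 1]")
    r_clipped = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_clipped * np.sqrt((n - 2) / (1.0 - r_clipped**2))
    p = np.where(np.abs(r_clipped) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return float(p) if np.isscalar(r) or p.ndim == 0 else p


def build_network(
    expr: ExpressionMatrix,
    r_threshold: float = 0.9,
    alpha: float = 0.01,
    *,
    signed: bool = False,
    log_transform: bool = True,
    block_size: int = 2000,
    provenance: Mapping | None = None,
) -> CoexpressionNetwork:
    """All-pairs PCC network with strict |r| and p thresholds.

    Edge kept iff |pcc| > r_threshold and p < alpha (both strict); with
    ``signed=True`` only positive correlations qualify (pcc > r_threshold),
    the variant used for module detection at the 0.95 threshold.
    Zero-variance genes are skipped and counted in provenance. Correlations
    are computed on log2(value+1) unless ``log_transform`` is disabled.
    All-pairs PCC is evaluated blockwise so gene counts of 1-2x10^4 stay
    within desk memory.
    """
    n = expr.n_samples
    if n < 3:
        raise DataError(f"need at least 3 samples to build a network, got {n}")
    data = (expr.log2() if log_transform else expr.values).to_numpy(dtype=float)
    genes = np.asarray(expr.gene_ids)
    sd = data.std(axis=1)
    usable = sd > 0
    n_skipped = int((~usable).sum())
    data = data[usable]
    genes = [str(g) for g in genes[usable]]
    m = len(genes)
    edges: dict[Edge, EdgeStats] = {}
    if m >= 2:
        centered = data - data.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        unit = centered / norms[:, None]
        for i0 in range(0, m, block_size):
            i1 = min(i0 + block_size, m)
            block = unit[i0:i1] @ unit.T  # (i1-i0, m) correlation block
            for ii in range(i1 - i0):
                i = i0 + ii
                row = block[ii]
                if signed:
                    cand = np.nonzero(row > r_threshold)[0]
                else:
                    cand = np.nonzero(np.abs(row) > r_threshold)[0]
                cand = cand[cand > i]  # upper triangle only
                if cand.size == 0:
                    continue
                r_vals = np.clip(row[cand], -1.0, 1.0)
                p_vals = correlation_pvalue(r_vals, n)
                keep = p_vals < alpha
                for j, r_ij, p_ij in zip(cand[keep], r_vals[keep], np.atleast_1d(p_vals)[keep]):
                    edges[canonical_edge(genes[i], genes[j])] = EdgeStats(
                        float(r_ij), float(p_ij)
                    )
    prov = dict(provenance or {})
    prov.update(
        {
            "r_threshold": r_threshold,
            "alpha": alpha,
            "signed": signed,
            "log_transform": log_transform,
            "n_samples": n,
            "n_zero_variance_skipped": n_skipped,
        }
    )
    return CoexpressionNetwork(edges, prov)


def network_partition(
    net_m: CoexpressionNetwork, net_f: CoexpressionNetwork
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, CoexpressionNetwork]:
    """Split two sex networks into (male-specific, female-specific, overlap).

    Edge identity is the unordered gene pair; overlap edges carry both
    cohorts' correlation values (``pcc`` from the first network,
    ``pcc_other`` from the second).
    """
    em, ef = set(net_m.edges), set(net_f.edges)
    shared = em & ef
    m_spec = {e: net_m.edges[e] for e in em - shared}
    f_spec = {e: net_f.edges[e] for e in ef - shared}
    overlap = {
        e: EdgeStats(
            net_m.edges[e].pcc, net_m.edges[e].p_value, pcc_other=net_f.edges[e].pcc
        )
        for e in shared
    }
    mk = lambda edges, tag: CoexpressionNetwork(dict(edges), {"partition": tag})
    return mk(m_spec, "first_specific"), mk(f_spec, "second_specific"), mk(overlap, "overlap")


def jaccard_edges(
    set_a: Iterable[Edge], set_b: Iterable[Edge], name_a: str = "A", name_b: str = "B"
) -> SimilarityRecord:
    """Jaccard index |A∩B| / |A∪B| on canonicalized edge sets."""
    a, b = set(set_a), set(set_b)
    inter, union = len(a & b), len(a | b)
    if union == 0:
        return SimilarityRecord(name_a, name_b, 0.0, 0, 0, both_empty=True)
    return SimilarityRecord(name_a, name_b, inter / union, inter, union)


def jaccard_gene_sets(
    genes_a: Iterable[str], genes_b: Iterable[str], name_a: str = "A", name_b: str = "B"
) -> SimilarityRecord:
    """Jaccard index on gene (node) sets."""
    a, b = set(genes_a), set(genes_b)
    inter, union = len(a & b), len(a | b)
    if union == 0:
        return SimilarityRecord(name_a, name_b, 0.0, 0, 0, both_empty=True)
    return SimilarityRecord(name_a, name_b, inter / union, inter, union)


def jaccard_from_counts(size_a: int, size_b: int, intersection: int,
                        name_a: str = "A", name_b: str = "B") -> SimilarityRecord:
    """Jaccard index from reported set sizes and intersection size."""
    if intersection > min(size_a, size_b) or min(size_a, size_b, intersection) < 0:
        raise DataError("inconsistent set sizes")
    union = size_a + size_b - intersection
    if union == 0:
        return SimilarityRecord(name_a, name_b, 0.0, 0, 0, both_empty=True)
    return SimilarityRecord(name_a, name_b, intersection / union, intersection, union)


def pairwise_region_similarity(
    networks: Mapping[str, CoexpressionNetwork]
) -> tuple[pd.DataFrame, pd.Series]:
    """Symmetric Jaccard matrix over named networks plus per-network averages.

    Returns the matrix (diagonal 1) and each network's mean off-diagonal
    Jaccard, which flags outlier regions with atypical edge sets.
    """
    names = list(networks)
    if len(names) < 2:
        raise DataError("need at least 2 networks for pairwise similarity")
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        j = jaccard_edges(networks[a].edge_set(), networks[b].edge_set(), a, b).jaccard
        mat.loc[a, b] = mat.loc[b, a] = j
    avg = (mat.sum(axis=1) - 1.0) / (len(names) - 1)
    avg.name = "mean_offdiagonal_jaccard"
    return mat, avg
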