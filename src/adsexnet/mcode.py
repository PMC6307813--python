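"""Molecular Complex Detection (MCODE) on co-expression networks.

Dense-subgraph detection in three phases: (1) vertex weighting — each
node's weight is k * density of the highest k-core of its open
neighbourhood graph; (2) complex prediction — seed at the highest-weight
unvisited node and breadth-first include neighbours whose weight is at
least seed_weight * (1 - node_score_cutoff), each node joining at most one
complex; (3) post-processing — optional haircut (iteratively strip members
with fewer than two connections inside the complex) and fluff. Complexes
are scored density * node count and ranked deterministically. Defaults
match the Cytoscape plug-in (degree cutoff 2, node score cutoff 0.2,
k-core 2, haircut on, fluff off).

Module crosstalk between the two sexes' module lists is measured with the
Jaccard index on gene sets (node level), reporting the intersecting genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import DataError
from .network import CoexpressionNetwork, SimilarityRecord, jaccard_edges, jaccard_gene_sets


@dataclass(frozen=True)
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0:
            raise DataError("degree_cutoff must be >= 0")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise DataError("node_score_cutoff must lie in [0, 1]")
        if self.k_core < 1:
            raise DataError("k_core must be >= 1")
        if self.max_depth < 1:
            raise DataError("max_depth must be >= 1")


@dataclass(frozen=True)
class NetworkModule:
    module_id: str
    genes: frozenset
    edges: frozenset  # canonical gene pairs induced in the parent network
    score: float
    seed: str

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph, params: McodeParams = McodeParams()) -> dict[str, float]:
    """MCODE vertex weight: k_max * density of the highest k-core of N(v).

    Nodes with degree below ``degree_cutoff`` weigh 0; so do nodes whose
    neighbourhood graph has no edges (e.g. star centres, isolated nodes).
    """
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(graph.neighbors(v))  # open neighbourhood
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(nbhd)
        k_max = max(core_num.values())
        core = nbhd.subgraph([u for u, k in core_num.items() if k >= k_max])
        weights[v] = k_max * _density(core)
    return weights


def _haircut(g: nx.Graph) -> nx.Graph:
    """Iteratively remove vertices with degree < 2; idempotent by construction."""
    g = g.copy()
    while True:
        low = [v for v in g.nodes if g.degree(v) < 2]
        if not low:
            return g
        g.remove_nodes_from(low)


def find_complexes(
    net: CoexpressionNetwork | nx.Graph,
    params: McodeParams = McodeParams(),
    prefix: str = "C",
) -> list[NetworkModule]:
    """Ranked MCODE complexes of a network.

    Ranking is by score (density * node count) descending, ties broken by
    larger node count, then by lexicographically smallest seed gene, so
    output is reproducible. Complexes that lose all but one node (or lack a
    ``k_core``-core) are dropped; reported modules always have >= 2 genes.
    """
    graph = net.to_networkx() if isinstance(net, CoexpressionNetwork) else net
    weights = vertex_weights(graph, params)
    # seed order: weight desc, node id asc for determinism
    seeds = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    visited: set = set()
    raw: list[tuple[str, set]] = []
    for seed in seeds:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        examined = {seed}  # per-complex guard; rejected nodes stay seedable
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in graph.neighbors(u):
                    if w in visited or w in examined:
                        continue
                    examined.add(w)
                    if weights[w] >= threshold:
                        members.add(w)
                        visited.add(w)  # no node belongs to two complexes
                        nxt.append(w)
            frontier = nxt
            depth += 1
        raw.append((seed, members))

    modules = []
    for seed, members in raw:
        sub = graph.subgraph(members).copy()
        if params.haircut:
            sub = _haircut(sub)
        if params.fluff:
            extra = set()
            for v in list(sub.nodes):
                nbhd = graph.subgraph(set(graph.neighbors(v)) | {v})
                if _density(nbhd) > params.fluff_density_cutoff:
                    extra |= set(graph.neighbors(v)) - visited
            sub = graph.subgraph(set(sub.nodes) | extra).copy()
        if sub.number_of_nodes() < 2:
            continue
        core_num = nx.core_number(sub)
        if max(core_num.values(), default=0) < params.k_core:
            continue
        score = _density(sub) * sub.number_of_nodes()
        edges = frozenset(tuple(sorted(e)) for e in sub.edges)
        modules.append(NetworkModule("", frozenset(sub.nodes), edges, score, seed))

    modules.sort(key=lambda m: (-m.score, -m.n_genes, m.seed))
    return [
        NetworkModule(f"{prefix}{i + 1}", m.genes, m.edges, m.score, m.seed)
        for i, m in enumerate(modules)
    ]


def module_crosstalk(
    modules_a: Sequence[NetworkModule],
    modules_b: Sequence[NetworkModule],
    level: str = "gene",
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[str]]]:
    """Jaccard similarity between two module lists (e.g. male vs female).

    ``level='gene'`` (default) compares gene sets, matching the reporting
    of intersecting genes between sex-specific modules; ``level='edge'``
    compares induced edge sets. Returns the similarity matrix (rows =
    modules_a, columns = modules_b) and the per-pair intersection lists.
    """
    for m in list(modules_a) + list(modules_b):
        if not m.genes:
            raise DataError(f"module {m.module_id} has an empty gene set")
    mat = pd.DataFrame(
        0.0,
        index=[m.module_id for m in modules_a],
        columns=[m.module_id for m in modules_b],
    )
    inter: dict[tuple[str, str], list[str]] = {}
    for ma in modules_a:
        for mb in modules_b:
            if level == "gene":
                rec = jaccard_gene_sets(ma.genes, mb.genes, ma.module_id, mb.module_id)
                inter[(ma.module_id, mb.module_id)] = sorted(ma.genes & mb.genes)
            elif level == "edge":
                rec = jaccard_edges(ma.edges, mb.edges, ma.module_id, mb.module_id)
                inter[(ma.module_id, mb.module_id)] = sorted(
                    f"{a}--{b}" for a, b in ma.edges & mb.edges
                )
            else:
                raise DataError(f"unknown crosstalk level {level!r}")
            mat.loc[ma.module_id, mb.module_id] = rec.jaccard
    return mat, inter


def modules_to_table(modules: Iterable[NetworkModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "rank": i + 1,
                "score": m.score,
                "n_genes": m.n_genes,
                "genes": ";".join(sorted(m.genes)),
            }
            for i, m in enumerate(modules)
        ],
        columns=["module_id", "rank", "score", "n_genes", "genes"],
    )
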