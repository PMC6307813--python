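"""Straight-line MCODE reimplementation used as an independent test oracle.

Same pseudocode as adsexnet.mcode but written directly on adjacency dicts
with its own k-core and BFS code, sharing nothing with the implementation
under test.
"""

from __future__ import annotations


def _kcore_numbers(nodes: list, adj: dict) -> dict:
    """Core number per node by iterative minimum-degree removal."""
    alive = set(nodes)
    deg = {v: len(adj[v] & alive) for v in alive}
    core = {v: 0 for v in alive}
    k = 0
    while alive:
        v = min(alive, key=lambda u: (deg[u], str(u)))
        k = max(k, deg[v])
        core[v] = k
        alive.discard(v)
        for u in adj[v]:
            if u in alive:
                deg[u] -= 1
    return core


def _density(nodes: set, adj: dict) -> float:
    n = len(nodes)
    if n < 2:
        return 0.0
    m = sum(len(adj[v] & nodes) for v in nodes) // 2
    return 2.0 * m / (n * (n - 1))


def oracle_weights(adj: dict, degree_cutoff: int = 2) -> dict:
    weights = {}
    for v in adj:
        if len(adj[v]) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = set(adj[v])
        sub = {u: adj[u] & nbhd for u in nbhd}
        if all(len(s) == 0 for s in sub.values()):
            weights[v] = 0.0
            continue
        core = _kcore_numbers(list(nbhd), sub)
        kmax = max(core.values())
        core_nodes = {u for u, c in core.items() if c >= kmax}
        weights[v] = kmax * _density(core_nodes, sub)
    return weights


def oracle_complexes(
    adj: dict,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
) -> list[tuple[frozenset, float]]:
    """Ranked (gene set, score) pairs; same contract as find_complexes."""
    weights = oracle_weights(adj, degree_cutoff)
    visited = set()
    raw = []
    for seed in sorted(adj, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        visited.add(seed)
        examined = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(adj[u], key=str):
                    if w in visited or w in examined:
                        continue
                    examined.add(w)
                    if weights[w] >= threshold:
                        members.add(w)
                        visited.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        raw.append((seed, members))

    out = []
    for seed, members in raw:
        sub = set(members)
        if haircut:
            while True:
                low = [v for v in sub if len(adj[v] & sub) < 2]
                if not low:
                    break
                sub -= set(low)
        if len(sub) < 2:
            continue
        sub_adj = {v: adj[v] & sub for v in sub}
        core = _kcore_numbers(list(sub), sub_adj)
        if max(core.values(), default=0) < k_core:
            continue
        score = _density(sub, adj) * len(sub)
        out.append((frozenset(sub), score, len(sub), seed))
    out.sort(key=lambda t: (-t[1], -t[2], str(t[3])))
    return [(genes, score) for genes, score, _, _ in out]
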