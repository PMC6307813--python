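"""Local over-representation analysis against user-supplied gene sets.

A one-sided upper-tail hypergeometric test per gene set (the classic
over-representation p-value: P[X >= k] for k query hits in a set of size K
drawn from a universe of N with a query of size n). Collections come from
standard GMT files. The default background is the analysed expression
matrix's gene universe. Both the 0.01 and 0.05 significance conventions
are surfaced as flags rather than reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .core import DataError


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, frozenset]
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    n: int  # query size
    K: int  # set size (after universe intersection)
    N: int  # universe size
    p_value: float
    q_value: float | None = None


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, genes...); duplicates deduped."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                raise DataError(
                    f"malformed GMT line {lineno}: need name, description and >=1 gene"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"duplicate gene-set name {name!r} at line {lineno}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets[name] = genes
    if not sets:
        raise DataError(f"no gene sets in {path}")
    return GeneSetCollection(sets)


def hypergeometric_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise DataError(f"inconsistent counts k={k}, N={N}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each collection set, sorted by p.

    Query genes outside the universe are dropped (with an error only if
    nothing survives); each gene set is intersected with the universe
    before testing so N, K, n, k are mutually consistent.
    """
    uni = frozenset(universe)
    if collection.universe is not None:
        uni = uni & collection.universe if uni else collection.universe
    if not uni:
        raise DataError("empty background universe")
    q = frozenset(query) & uni
    if not q:
        raise DataError("query is empty after intersection with the universe")
    N, n = len(uni), len(q)
    results = []
    for name, genes in collection.sets.items():
        gs = genes & uni
        if not gs:
            continue
        k = len(q & gs)
        results.append(
            EnrichmentResult(name, k, n, len(gs), N, hypergeometric_pvalue(k, N, len(gs), n))
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    if adjust and results:
        from statsmodels.stats.multitest import multipletests

        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.set_name, r.k, r.n, r.K, r.N, r.p_value, float(qv))
            for r, qv in zip(results, qvals)
        ]
    return results


def results_to_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ],
        columns=["set", "k", "n", "K", "N", "p_value", "q_value"],
    )
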