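"""Stage-wise network rewiring: the dynamic score and conserved networks.

For each region x sex stratum, a co-expression network is built per
neuropathological stage (normal, possible AD, probable AD, definite AD),
skipping stages with fewer than ``min_samples`` (default 4) samples. The
dynamic score is

    score = 1 - overlapNum / normalNum

where overlapNum counts edges present in every AVAILABLE stage network and
normalNum counts the normal-stage edges. A score near 1 means almost no
normal-stage co-expression survives across disease progression. Stages
marked unavailable are excluded from the intersection rather than treated
as empty. Conserved cross-region networks intersect one stage's networks
across regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import DataError, ExpressionMatrix, CohortMetadata, STAGES
from .network import CoexpressionNetwork, Edge, build_network


@dataclass(frozen=True)
class DynamicScoreRecord:
    region: str
    sex: str
    stage_edge_counts: dict  # stage -> edge count, or None when unavailable
    normal_num: int
    overlap_num: int
    score: float
    valid: bool = True


@dataclass(frozen=True)
class ConservedNetwork:
    stage: str
    sex: str
    edges: frozenset

    @property
    def nodes(self) -> frozenset:
        return frozenset(g for e in self.edges for g in e)

    @property
    def average_degree(self) -> float:
        return 2.0 * len(self.edges) / len(self.nodes) if self.nodes else 0.0


def stage_networks(
    expr: ExpressionMatrix,
    meta: CohortMetadata,
    region: str,
    sex: str,
    min_samples: int = 4,
    r_threshold: float = 0.9,
    alpha: float = 0.01,
    **network_kwargs,
) -> dict[str, CoexpressionNetwork | None]:
    """Per-stage networks for one region x sex; sparse stages map to None."""
    out: dict[str, CoexpressionNetwork | None] = {}
    for stage in STAGES:
        samples = [
            s
            for s in expr.sample_ids
            if s in meta.table.index
            and meta.table.loc[s, "sex"] == sex
            and meta.table.loc[s, "region"] == region
            and meta.table.loc[s, "stage"] == stage
        ]
        if len(samples) < min_samples:
            out[stage] = None
            continue
        sub = ExpressionMatrix(expr.values.loc[:, samples])
        out[stage] = build_network(
            sub,
            r_threshold=r_threshold,
            alpha=alpha,
            provenance={"region": region, "sex": sex, "stage": stage},
            **network_kwargs,
        )
    return out


def score_from_counts(normal_num: int, overlap_num: int) -> float:
    """The dynamic score 1 - overlapNum/normalNum from raw edge counts."""
    if normal_num <= 0:
        raise DataError("dynamic score undefined: normal-stage network has no edges")
    if overlap_num < 0 or overlap_num > normal_num:
        raise DataError(
            f"invalid counts: overlapNum {overlap_num} outside [0, normalNum={normal_num}]"
        )
    return 1.0 - overlap_num / normal_num


def dynamic_score(
    stage_map: Mapping[str, CoexpressionNetwork | None],
    region: str = "",
    sex: str = "",
) -> DynamicScoreRecord:
    """Dynamic score of one region x sex from its per-stage networks.

    The normal-stage network must be available and non-empty; unavailable
    stages (None) are excluded from the cross-stage intersection.
    """
    if stage_map.get("normal") is None:
        raise DataError(f"normal-stage network unavailable for {region}/{sex}")
    available = {s: net for s, net in stage_map.items() if net is not None}
    counts = {s: (net.n_edges if net is not None else None) for s, net in stage_map.items()}
    normal_num = available["normal"].n_edges
    overlap: set[Edge] = set(available["normal"].edges)
    for net in available.values():
        overlap &= set(net.edges)
    score = score_from_counts(normal_num, len(overlap))
    return DynamicScoreRecord(
        region=region,
        sex=sex,
        stage_edge_counts=counts,
        normal_num=normal_num,
        overlap_num=len(overlap),
        score=score,
    )


def conserved_network(
    region_networks: Mapping[str, CoexpressionNetwork],
    stage: str = "",
    sex: str = "",
) -> ConservedNetwork:
    """Edge-set intersection of one stage's networks across regions."""
    if len(region_networks) < 2:
        raise DataError("need at least 2 region networks to intersect")
    nets = list(region_networks.values())
    edges = set(nets[0].edges)
    for net in nets[1:]:
        edges &= set(net.edges)
    return ConservedNetwork(stage=stage, sex=sex, edges=frozenset(edges))


def compare_score_distributions(
    male_records: Sequence[DynamicScoreRecord],
    female_records: Sequence[DynamicScoreRecord],
    method: str = "wilcoxon",
) -> dict:
    """Paired two-sided comparison of male vs female scores across regions.

    Default is the exact Wilcoxon signed-rank test; ``method='sign'`` runs
    an exact sign test. Records are paired by region; unpaired regions are
    an error. Also reports each sex's score range.
    """
    m = {r.region: r.score for r in male_records}
    f = {r.region: r.score for r in female_records}
    unpaired = sorted(set(m) ^ set(f))
    if unpaired:
        raise DataError(f"regions present in only one sex: {unpaired}")
    regions = sorted(m)
    x = np.array([m[r] for r in regions])
    y = np.array([f[r] for r in regions])
    diffs = x - y
    if method == "wilcoxon":
        if np.allclose(diffs, 0.0):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
            statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "sign":
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            statistic, p = 0.0, 1.0
        else:
            wins = int((nonzero > 0).sum())
            res = stats.binomtest(wins, nonzero.size, 0.5, alternative="two-sided")
            statistic, p = float(wins), float(res.pvalue)
    else:
        raise DataError(f"unknown method {method!r}")
    return {
        "method": method,
        "statistic": statistic,
        "p_value": p,
        "n_pairs": len(regions),
        "male_range": (float(x.min()), float(x.max())),
        "female_range": (float(y.min()), float(y.max())),
    }
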