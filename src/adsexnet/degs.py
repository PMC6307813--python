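"""Two-group differential expression and cross-region sharing.

A gene is called differentially expressed when its group-mean intensity
ratio exceeds 1.5 (or falls below 2/3) AND the two-group test gives
p < 0.05; all inequalities are strict. Fold change is taken on the
intensity scale (the 1.5 / 2/3 bounds are ratio-style); the test runs on
log2(value+1). The default statistic is Welch's t; Student's t and the
Wilcoxon rank-sum test are available alternatives. No multiplicity
correction is applied by default (matching the raw-p usage of the source
analysis); Benjamini-Hochberg q-values are available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, ExpressionMatrix

FC_HI_DEFAULT = 1.5
FC_LO_DEFAULT = 2.0 / 3.0
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class DegRecord:
    gene: str
    region: str
    fold_change: float
    p_value: float
    direction: str  # "up" iff fold_change > 1

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise DataError(f"fold change must be positive, got {self.fold_change}")
        expected = "up" if self.fold_change > 1 else "down"
        if self.direction != expected:
            raise DataError(
                f"direction {self.direction!r} inconsistent with FC {self.fold_change}"
            )


def _split_groups(
    expr: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if len(group_a) == 0 or len(group_b) == 0:
        raise DataError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise DataError("groups overlap")
    a = expr.values.loc[:, list(group_a)].to_numpy(dtype=float)
    b = expr.values.loc[:, list(group_b)].to_numpy(dtype=float)
    return a, b


def fold_change(
    expr: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Per-gene ratio of group_a mean intensity to group_b mean intensity.

    Genes whose group_b mean is zero get +inf (or NaN when both means are 0).
    """
    a, b = _split_groups(expr, group_a, group_b)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    fc = np.where((mean_b == 0) & (mean_a > 0), np.inf, fc)
    return pd.Series(fc, index=expr.gene_ids, name="fold_change")


def deg_test(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = "welch",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sided p-values, with a flag for zero-variance genes.

    Genes with zero variance in both groups cannot be tested and are
    assigned p = 1 with ``degenerate=True``. Returns a DataFrame with
    columns ``p_value`` and ``degenerate``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each group needs at least 2 samples")
    a, b = _split_groups(expr, group_a, group_b)
    if log_transform:
        a, b = np.log2(a + 1.0), np.log2(b + 1.0)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p = np.ones(expr.n_genes)
    ok = ~degenerate
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            if method == "welch":
                res = stats.ttest_ind(a[ok], b[ok], axis=1, equal_var=False)
            elif method == "student":
                res = stats.ttest_ind(a[ok], b[ok], axis=1, equal_var=True)
            elif method == "wilcoxon":
                res = stats.mannwhitneyu(a[ok], b[ok], axis=1, alternative="two-sided")
            else:
                raise DataError(f"unknown test method {method!r}")
        p[ok] = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    return pd.DataFrame(
        {"p_value": p, "degenerate": degenerate}, index=expr.gene_ids
    )


def call_degs(
    fc: pd.Series,
    p: pd.Series | pd.DataFrame,
    region: str = "",
    fc_hi: float = FC_HI_DEFAULT,
    fc_lo: float = FC_LO_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> list[DegRecord]:
    """Call genes with (fc > fc_hi or fc < fc_lo) and p < alpha, all strict."""
    if isinstance(p, pd.DataFrame):
        p = p["p_value"]
    if set(fc.index) != set(p.index):
        raise DataError("fold-change and p-value tables cover different gene sets")
    records = []
    for gene in fc.index:
        f, pv = float(fc[gene]), float(p[gene])
        if (f > fc_hi or f < fc_lo) and pv < alpha:
            records.append(
                DegRecord(gene, region, f, pv, "up" if f > 1 else "down")
            )
    return records


def adjust_bh(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted q-values (optional; off by default)."""
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p.to_numpy(), method="fdr_bh")[1]
    return pd.Series(q, index=p.index, name="q_value")


@dataclass(frozen=True)
class SharingTable:
    """Per-gene count of regions in which the gene is differentially expressed."""

    regions_of: Mapping[str, tuple[str, ...]]

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(rs) for g, rs in self.regions_of.items()}

    def genes_in_at_least(self, k: int) -> list[str]:
        return sorted(g for g, rs in self.regions_of.items() if len(rs) >= k)

    def genes_in_exactly(self, k: int) -> list[str]:
        return sorted(g for g, rs in self.regions_of.items() if len(rs) == k)


def cross_region_sharing(per_region: Mapping[str, Iterable[str]]) -> SharingTable:
    """Count, for every gene, the regions whose DEG list contains it.

    Raises on a duplicate gene within a single region's list.
    """
    regions_of: dict[str, list[str]] = {}
    for region, genes in per_region.items():
        genes = list(genes)
        dup = [g for g, c in Counter(genes).items() if c > 1]
        if dup:
            raise DataError(f"duplicate genes in region {region!r}: {sorted(dup)}")
        for g in genes:
            regions_of.setdefault(g, []).append(region)
    return SharingTable({g: tuple(sorted(rs)) for g, rs in regions_of.items()})


def degs_to_table(records: Iterable[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "region": r.region,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=["gene", "region", "fold_change", "p_value", "direction"],
    )
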