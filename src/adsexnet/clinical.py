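"""Trait-adapted Kaplan-Meier / log-rank screening.

Neuropathological trait scores (Braak score, plaque density, CERAD and
tangle-density sums) play the role of event times: samples are split into
low/high groups at the median expression of a gene of interest, each
group's trait distribution is summarised with the product-limit estimator,
and separation is tested with the two-group log-rank statistic (grouped
ties, hypergeometric variance). Traits are ordinal severity scores, so no
censoring mechanism exists; all events are treated as observed, though the
estimator retains censoring support for generality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, ExpressionMatrix, CohortMetadata


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit step function."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each time

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"trait_value": self.times, "surviving_fraction": self.survival})


@dataclass(frozen=True)
class TraitAssociationResult:
    gene: str
    trait: str
    n_low: int
    n_high: int
    chi_square: float
    p_value: float
    curve_low: KMCurve
    curve_high: KMCurve


def dichotomize_by_expression(values: pd.Series, quantile: float = 0.5) -> pd.Series:
    """Split samples at the ``quantile`` of expression; ties go to 'low'.

    Samples with value <= the split point are labelled ``low``, the rest
    ``high``. Raises if fewer than 4 samples or if the split leaves either
    group empty (e.g. a constant vector).
    """
    if len(values) < 4:
        raise DataError(f"need at least 4 samples to dichotomize, got {len(values)}")
    cut = float(values.quantile(quantile))
    labels = pd.Series(np.where(values <= cut, "low", "high"), index=values.index)
    if (labels == "low").all() or (labels == "high").all():
        raise DataError("degenerate split: all samples on one side of the cut")
    return labels


def km_curve(
    trait_values: Sequence[float], events: Sequence[bool] | None = None
) -> KMCurve:
    """Product-limit estimator over trait values treated as event times.

    With ``events`` omitted (no censoring) this equals 1 - ECDF with the
    right-continuous convention.
    """
    t = np.asarray(trait_values, dtype=float)
    if t.size == 0:
        raise DataError("no trait values")
    if not np.isfinite(t).all():
        raise DataError("non-finite trait values")
    e = np.ones(t.size, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times, surv = [], []
    s = 1.0
    n_at_risk = t.size
    for value in np.unique(t):
        here = t == value
        d = int((e & here).sum())  # events at this value
        if d > 0:
            s *= 1.0 - d / n_at_risk
            times.append(value)
            surv.append(s)
        n_at_risk -= int(here.sum())
    return KMCurve(np.asarray(times), np.asarray(surv))


def logrank_test(
    trait_values: Sequence[float],
    group_labels: Sequence[str],
    gene: str = "",
    trait: str = "",
) -> TraitAssociationResult:
    """Two-group log-rank test with the grouped-ties (hypergeometric) variance.

    At each distinct trait value the observed group-1 events are compared
    with their expectation under the risk-set hypergeometric; the statistic
    is (O - E)^2 / V on 1 df. Identical group value-multisets give
    chi-square 0, p 1.
    """
    t = np.asarray(trait_values, dtype=float)
    g = np.asarray(group_labels)
    groups = sorted(set(g.tolist()))
    if len(groups) != 2:
        raise DataError(f"log-rank needs exactly 2 groups, got {groups}")
    n1_tot, n2_tot = int((g == groups[0]).sum()), int((g == groups[1]).sum())
    if n1_tot == 0 or n2_tot == 0:
        raise DataError("one group is empty")
    o_minus_e = 0.0
    variance = 0.0
    for value in np.unique(t):
        at_risk = t >= value
        here = t == value
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == groups[0])).sum())
        d = int(here.sum())
        d1 = int((here & (g == groups[0])).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / variance
        p = float(stats.chi2.sf(chi2, df=1))
    low_mask = g == "low" if "low" in groups else g == groups[0]
    return TraitAssociationResult(
        gene=gene,
        trait=trait,
        n_low=int(low_mask.sum()),
        n_high=int((~low_mask).sum()),
        chi_square=float(chi2),
        p_value=p,
        curve_low=km_curve(t[low_mask]),
        curve_high=km_curve(t[~low_mask]),
    )


def screen_traits(
    expr: ExpressionMatrix,
    meta: CohortMetadata,
    genes: Iterable[str],
    traits: Iterable[str],
    quantile: float = 0.5,
) -> list[TraitAssociationResult]:
    """Log-rank screen of every gene x trait pair; no multiplicity correction.

    For each gene, samples are dichotomized at the median of its expression
    (log2 scale irrelevant: the split is rank-based) and each trait's
    distribution is compared between the two groups. Samples lacking a
    trait value are dropped for that trait.
    """
    traits = list(traits)
    for trait in traits:
        if trait not in meta.table.columns:
            raise DataError(f"trait column '{trait}' not present in metadata")
    results = []
    for gene in genes:
        if gene not in expr.values.index:
            raise DataError(f"gene {gene!r} not in expression matrix")
        values = expr.values.loc[gene, expr.sample_ids]
        labels = dichotomize_by_expression(values, quantile=quantile)
        for trait in traits:
            tv = meta.table.loc[labels.index, trait].astype(float)
            ok = tv.notna()
            res = logrank_test(tv[ok].to_numpy(), labels[ok].to_numpy(), gene, trait)
            results.append(res)
    return results


def results_to_table(results: Iterable[TraitAssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "trait": r.trait,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "chi_square": r.chi_square,
                "p_value": r.p_value,
            }
            for r in results
        ],
        columns=["gene", "trait", "n_low", "n_high", "chi_square", "p_value"],
    )
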