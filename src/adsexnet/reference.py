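"""Bundled reference tables from the published GSE84422 sex-difference analysis.

Two small plain-text tables ship with the package:

* ``region_deg_table.tsv`` — the sex-difference DEG list per cortical
  region (one gene-region pair per row), used for the cross-region
  sharing analysis.
* ``stage_edge_counts.tsv`` — per region x sex, the reported edge counts
  of the four stage networks (NA where a stage had fewer than four
  samples), the cross-stage overlap count, and the reported dynamic
  score. Three female rows (middle temporal gyrus, precentral gyrus,
  putamen) are internally inconsistent in the source table: the score
  printed there does not equal 1 - overlap/normal for the printed counts.
  ``check_stage_scores`` flags them rather than hiding them.

Overall-network summary counts (edge totals of the pan-cortical male and
female networks and their intersection) are exposed as constants.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

from .degs import SharingTable, cross_region_sharing
from .dynamics import score_from_counts
from .network import SimilarityRecord, jaccard_from_counts

#: Reported pan-cortical network sizes: male edges, female edges, shared edges.
OVERALL_MALE_EDGES = 80739
OVERALL_FEMALE_EDGES = 25772
OVERALL_SHARED_EDGES = 21984


def _data_path(name: str):
    return resources.files("adsexnet.data").joinpath(name)


def load_region_deg_table() -> dict[str, list[str]]:
    """Region -> DEG gene list, from the bundled reference table."""
    df = pd.read_csv(_data_path("region_deg_table.tsv"), sep="\t")
    return {
        region: list(sub["gene"]) for region, sub in df.groupby("region", sort=True)
    }


def region_deg_sharing() -> SharingTable:
    """Cross-region sharing structure of the bundled DEG lists."""
    return cross_region_sharing(load_region_deg_table())


def load_stage_edge_counts() -> pd.DataFrame:
    """Per region x sex stage edge counts, overlap and reported score."""
    return pd.read_csv(
        _data_path("stage_edge_counts.tsv"),
        sep="\t",
        na_values=["NA"],
        dtype={"score_printed": str},
    )


def load_cross_region_overlap() -> pd.DataFrame:
    """Edges conserved across all 17 regions, per stage and sex."""
    return pd.read_csv(_data_path("cross_region_overlap.tsv"), sep="\t")


def overall_jaccard() -> SimilarityRecord:
    """Jaccard index of the reported pan-cortical male and female edge sets."""
    return jaccard_from_counts(
        OVERALL_MALE_EDGES,
        OVERALL_FEMALE_EDGES,
        OVERALL_SHARED_EDGES,
        "male_overall",
        "female_overall",
    )


def check_stage_scores() -> pd.DataFrame:
    """Recompute 1 - overlap/normal per row and compare to the reported score.

    Returns the table with ``score_recomputed`` (rounded to the reported
    precision) and a boolean ``consistent`` column. 31 of the 34 rows
    reproduce exactly; the three known-inconsistent female rows fail.
    """
    df = load_stage_edge_counts().copy()
    recomputed, consistent = [], []
    for _, row in df.iterrows():
        score = score_from_counts(int(row["normal"]), int(row["overlap"]))
        decimals = len(row["score_printed"].split(".")[1])
        rounded = round(score, decimals)
        recomputed.append(rounded)
        consistent.append(abs(rounded - float(row["score_printed"])) < 10 ** -(decimals + 3))
    df["score_recomputed"] = recomputed
    df["consistent"] = consistent
    return df
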