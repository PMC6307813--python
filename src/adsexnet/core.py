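"""Core domain types and ingestion for cortical expression cohorts.

The pipeline operates on MAS5-style non-negative intensity matrices
(genes x samples) with per-sample annotations: subject, sex, one of 17
cortical regions, a four-level neuropathological stage, and four clinical
trait scores. Probe-level matrices are collapsed to gene level by dropping
multi-gene probes and averaging the remaining probes per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

#: The 17 cortical regions retained in the cohort (amygdala and nucleus
#: accumbens are absent from the source data and excluded).
REGIONS: tuple[str, ...] = (
    "anterior cingulate",
    "caudate nucleus",
    "dorsolateral prefrontal cortex",
    "frontal pole",
    "hippocampus",
    "inferior frontal gyrus",
    "inferior temporal gyrus",
    "middle temporal gyrus",
    "occipital visual cortex",
    "parahippocampal gyrus",
    "posterior cingulate cortex",
    "precentral gyrus",
    "prefrontal cortex",
    "putamen",
    "superior parietal lobule",
    "superior temporal gyrus",
    "temporal pole",
)

#: Ordered neuropathological stages.
STAGES: tuple[str, ...] = ("normal", "possible_AD", "probable_AD", "definite_AD")

SEXES: tuple[str, ...] = ("male", "female")

#: Clinical trait columns carried in metadata: Braak neurofibrillary tangle
#: score, average neuritic plaque density, sum of CERAD rating scores across
#: brain regions, and sum of neurofibrillary tangle density across regions.
TRAITS: tuple[str, ...] = (
    "braak_score",
    "plaque_density",
    "cerad_sum",
    "tangle_sum",
)

METADATA_COLUMNS = ("sample_id", "subject_id", "sex", "region", "stage") + TRAITS


class DataError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative expression intensities.

    Parameters
    ----------
    values
        DataFrame with unique gene identifiers as index and unique sample
        identifiers as columns; entries finite and >= 0.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise DataError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise DataError(f"duplicate sample identifiers: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise DataError(
                f"matrix must have >=2 genes and >=2 samples, got {df.shape}"
            )
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise DataError("non-finite expression values present")
        if (arr < 0).any():
            raise DataError("negative expression values present")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> pd.DataFrame:
        """Return log2(value + 1), the default scale for tests/correlations."""
        return np.log2(self.values + 1.0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise DataError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[:, ids])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class CohortMetadata:
    """Per-sample annotations keyed to expression-matrix columns."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise DataError(f"duplicate sample identifiers in metadata: {dups}")
        for col in ("subject_id", "sex", "region", "stage"):
            if col not in df.columns:
                raise DataError(f"metadata missing required column '{col}'")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise DataError(f"unknown sex values: {sorted(bad_sex)}")
        bad_region = set(df["region"]) - set(REGIONS)
        if bad_region:
            raise DataError(f"unknown regions: {sorted(bad_region)}")
        bad_stage = set(df["stage"]) - set(STAGES)
        if bad_stage:
            raise DataError(f"unknown stages: {sorted(bad_stage)}")
        for trait in TRAITS:
            if trait in df.columns:
                vals = df[trait].dropna().to_numpy(dtype=float)
                if not np.isfinite(vals).all():
                    raise DataError(f"non-finite values in trait '{trait}'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_where(
        self,
        sex: str | None = None,
        region: str | None = None,
        stage: str | Iterable[str] | None = None,
    ) -> list[str]:
        """Sample ids matching the conjunction of the given criteria."""
        mask = pd.Series(True, index=self.table.index)
        if sex is not None:
            mask &= self.table["sex"] == sex
        if region is not None:
            mask &= self.table["region"] == region
        if stage is not None:
            stages = [stage] if isinstance(stage, str) else list(stage)
            mask &= self.table["stage"].isin(stages)
        return list(self.table.index[mask])

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.table.columns:
            raise DataError(f"trait column '{trait}' not present in metadata")
        return self.table[trait]


ProbeMap = Mapping[str, frozenset]


def load_expression(path: str | Path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Load a tab- or comma-separated expression table.

    The first column holds identifiers; remaining columns must be numeric.
    ``orientation`` is ``genes_in_rows`` (default) or ``samples_in_rows``;
    the returned matrix is always gene-by-sample.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"no genes in expression table {path}")
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise DataError(
                    f"non-numeric cell at row '{bad.index[0]}', column '{col}': "
                    f"{bad.iloc[0]!r}"
                )
        df = df.apply(pd.to_numeric)
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise DataError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def load_metadata(path: str | Path) -> CohortMetadata:
    """Load per-sample metadata (sample_id, subject_id, sex, region, stage, traits)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in df.columns:
        raise DataError("metadata must contain a 'sample_id' column")
    return CohortMetadata(df.set_index("sample_id"))


def load_probe_map(path: str | Path) -> dict[str, frozenset]:
    """Two-column table probe_id<TAB>gene_id; repeated probe rows mean multi-gene."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] != 2:
        raise DataError("probe map must have exactly two columns (probe_id, gene_id)")
    probe_col, gene_col = df.columns
    out: dict[str, set] = {}
    for probe, gene in zip(df[probe_col], df[gene_col]):
        out.setdefault(probe, set()).add(gene)
    return {p: frozenset(gs) for p, gs in out.items()}


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-by-sample matrix to gene level.

    Probes mapping to more than one gene are discarded before aggregation;
    each gene's value is the arithmetic mean of its surviving probes,
    computed per sample on the intensity scale.
    """
    missing = [p for p in probe_matrix.gene_ids if p not in probe_map]
    if missing:
        raise DataError(f"probes absent from probe map: {missing[:10]}")
    gene_of: dict[str, str] = {}
    for probe in probe_matrix.gene_ids:
        genes = probe_map[probe]
        if len(genes) == 0:
            raise DataError(f"probe {probe!r} maps to no gene")
        if len(genes) == 1:
            gene_of[probe] = next(iter(genes))
    if not gene_of:
        raise DataError("no single-gene probes survive multi-gene removal")
    kept = probe_matrix.values.loc[list(gene_of)]
    collapsed = kept.groupby([gene_of[p] for p in kept.index], sort=True).mean()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(collapsed)


def subset_cohort(
    expr: ExpressionMatrix,
    meta: CohortMetadata,
    predicate: Callable[[pd.Series], bool] | None = None,
    *,
    sex: str | None = None,
    region: str | None = None,
    stage: str | Iterable[str] | None = None,
) -> ExpressionMatrix:
    """Columns of ``expr`` whose metadata satisfy the filter, order preserved.

    Either pass keyword criteria (conjunctive) or an arbitrary per-row
    ``predicate`` over the metadata row. Raises if the matrix holds a sample
    missing from the metadata, or if the selection is empty.
    """
    absent = [s for s in expr.sample_ids if s not in meta.table.index]
    if absent:
        raise DataError(f"samples missing from metadata: {absent}")
    if predicate is not None:
        selected = [s for s in expr.sample_ids if predicate(meta.table.loc[s])]
    else:
        wanted = set(meta.samples_where(sex=sex, region=region, stage=stage))
        selected = [s for s in expr.sample_ids if s in wanted]
    if not selected:
        raise DataError("cohort filter matched 0 samples")
    return ExpressionMatrix(expr.values.loc[:, selected])
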