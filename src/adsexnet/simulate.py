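"""Synthetic cortical cohort generator with planted, recoverable structure.

The generator emulates the design the pipeline assumes: two sexes, a set
of cortical regions, a four-level neuropathological stage per subject, and
one sample per subject x region. Expression follows a latent-factor
Gaussian model on the log2 scale:

    log2(x_gs) = baseline + loading * f_ms  [gene g in module m active for s]
                 + log2FC                   [planted contrast matches s]
                 + eps_gs,   eps ~ N(0, noise_sd)

then exponentiated to the intensity scale. Within an active module the
theoretical pairwise PCC is loading^2 / (loading^2 + noise_sd^2) — with
the defaults (0.95, 0.1) about 0.989, comfortably above the 0.9 edge
threshold. Stage rewiring is planted by limiting a module's stage scope
(active in normal, silent in definite AD), the minimal mechanism that
makes the dynamic score separate groups. Clinical traits are a monotone
function of stage plus an effect of a standardized driver gene plus noise,
clamped at zero.

A single global seed governs all draws through deterministic substreams;
identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    REGIONS,
    SEXES,
    STAGES,
    TRAITS,
    CohortMetadata,
    DataError,
    ExpressionMatrix,
)
from .network import canonical_edge

AD_STAGES = ("probable_AD", "definite_AD")  # the planted-DEG contrast vs normal


@dataclass(frozen=True)
class PlantedModule:
    name: str
    genes: tuple[str, ...]
    loading: float  # latent-factor loading in (0, 1]
    sexes: tuple[str, ...] = SEXES
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not 0.0 < self.loading <= 1.0:
            raise DataError(f"module {self.name}: loading must lie in (0, 1]")
        if not set(self.sexes) <= set(SEXES) or not self.sexes:
            raise DataError(f"module {self.name}: invalid sex scope {self.sexes}")
        if not set(self.stages) <= set(STAGES) or not self.stages:
            raise DataError(f"module {self.name}: invalid stage scope {self.stages}")

    def edges(self) -> frozenset:
        return frozenset(
            canonical_edge(a, b)
            for i, a in enumerate(self.genes)
            for b in self.genes[i + 1 :]
        )


@dataclass(frozen=True)
class PlantedDeg:
    gene: str
    region: str
    log2_fc: float
    sexes: tuple[str, ...] = SEXES


@dataclass(frozen=True)
class TraitDriver:
    gene: str
    effects: Mapping[str, float]  # trait name -> effect in trait-SD units


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects_per_sex: int = 60
    regions: tuple[str, ...] = ("frontal pole", "superior temporal gyrus")
    stage_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_genes: int = 500
    planted_modules: tuple[PlantedModule, ...] = ()
    planted_degs: tuple[PlantedDeg, ...] = ()
    trait_driver: TraitDriver | None = None
    noise_sd: float = 0.1
    baseline_log2: float = 8.0
    trait_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if not set(self.regions) <= set(REGIONS):
            raise DataError(f"unknown regions: {set(self.regions) - set(REGIONS)}")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or min(self.stage_probs) < 0:
            raise DataError("stage_probs must be a probability vector over 4 stages")
        universe = set(self.gene_universe())
        for mod in self.planted_modules:
            outside = set(mod.genes) - universe
            if outside:
                raise DataError(f"module {mod.name}: genes outside universe: {sorted(outside)}")
        for deg in self.planted_degs:
            if deg.gene not in universe:
                raise DataError(f"planted DEG gene {deg.gene!r} outside universe")
            if deg.region not in self.regions:
                raise DataError(f"planted DEG region {deg.region!r} not simulated")
        if self.trait_driver is not None:
            if self.trait_driver.gene not in universe:
                raise DataError(f"trait driver {self.trait_driver.gene!r} outside universe")
            unknown = set(self.trait_driver.effects) - set(TRAITS)
            if unknown:
                raise DataError(f"unknown trait names: {sorted(unknown)}")

    def gene_universe(self) -> tuple[str, ...]:
        """G0001..G{n-1} plus GSK3B (the conventional trait-driver slot)."""
        return tuple(f"G{i:04d}" for i in range(1, self.n_genes)) + ("GSK3B",)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-shaped default: 60 subjects/sex, 2 regions, uniform stages,
    500 genes, three planted modules (shared, male-only, stage-rewired),
    ten planted DEGs at |log2FC| in {1.0, 1.58}, and GSK3B driving all four
    clinical traits at 1.5 trait-SD.
    """
    genes = tuple(f"G{i:04d}" for i in range(1, 500)) + ("GSK3B",)
    modules = (
        PlantedModule("shared", genes[0:12], 0.95),
        PlantedModule("male_only", genes[20:30], 0.95, sexes=("male",)),
        PlantedModule(
            "rewired",
            genes[40:55],
            0.95,
            stages=("normal", "possible_AD", "probable_AD"),  # silent in definite AD
        ),
    )
    region = "frontal pole"
    fcs = [1.58, 1.0, -1.0, -1.58, 1.0, -1.0, 1.58, -1.58, 1.0, -1.0]
    degs = tuple(
        PlantedDeg(genes[100 + i], region, fc) for i, fc in enumerate(fcs)
    )
    driver = TraitDriver("GSK3B", {t: 1.5 for t in TRAITS})
    cfg = SimulationConfig(
        planted_modules=modules, planted_degs=degs, trait_driver=driver, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class GroundTruth:
    config: SimulationConfig
    deg_table: pd.DataFrame  # gene, region, log2_fc, sexes
    module_genes: Mapping[str, tuple[str, ...]]
    sex_specific_edges: Mapping[str, frozenset]  # sex -> true edges unique to it
    stage_rewired_edges: frozenset  # edges absent in at least one stage's scope
    trait_driver: TraitDriver | None


def _subject_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        stages = rng.choice(len(STAGES), size=cfg.n_subjects_per_sex, p=cfg.stage_probs)
        for i, st in enumerate(stages):
            rows.append(
                {
                    "subject_id": f"subj_{sex[0]}{i:03d}",
                    "sex": sex,
                    "stage": STAGES[int(st)],
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CohortMetadata, GroundTruth]:
    """Generate (expression, metadata-with-traits, ground truth) for a config."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_subj, rng_expr, rng_factor, rng_trait = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    genes = list(cfg.gene_universe())
    gene_index = {g: i for i, g in enumerate(genes)}
    subjects = _subject_table(cfg, rng_subj)

    samples = []
    for _, subj in subjects.iterrows():
        for region in cfg.regions:
            samples.append(
                {
                    "sample_id": f"{subj.subject_id}.{region.replace(' ', '_')}",
                    "subject_id": subj.subject_id,
                    "sex": subj.sex,
                    "region": region,
                    "stage": subj.stage,
                }
            )
    meta_df = pd.DataFrame(samples).set_index("sample_id")
    n_samples = len(meta_df)

    log2m = cfg.baseline_log2 + rng_expr.normal(0.0, cfg.noise_sd, (len(genes), n_samples))

    # planted co-expression modules: one latent factor per active sample
    for mod in cfg.planted_modules:
        active = (
            meta_df["sex"].isin(mod.sexes) & meta_df["stage"].isin(mod.stages)
        ).to_numpy()
        factors = rng_factor.normal(0.0, 1.0, n_samples)  # fixed draw count per module
        rows = [gene_index[g] for g in mod.genes]
        log2m[np.ix_(rows, np.nonzero(active)[0])] += (
            mod.loading * factors[active][None, :]
        )

    # planted fold changes for the AD-vs-normal contrast within a region
    for deg in cfg.planted_degs:
        hit = (
            (meta_df["region"] == deg.region)
            & meta_df["sex"].isin(deg.sexes)
            & meta_df["stage"].isin(AD_STAGES)
        ).to_numpy()
        log2m[gene_index[deg.gene], hit] += deg.log2_fc

    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2m), index=genes, columns=meta_df.index)
    )

    meta = CohortMetadata(meta_df)
    if cfg.trait_driver is not None:
        driver_by_subject = (
            np.log2(expr.values.loc[cfg.trait_driver.gene] + 1.0)
            .groupby(meta_df["subject_id"])
            .mean()
        )
        meta = simulate_traits(
            meta,
            driver_by_subject,
            cfg.trait_driver.effects,
            rng=rng_trait,
            trait_noise_sd=cfg.trait_noise_sd,
        )
    else:
        meta = simulate_traits(
            meta, None, {t: 0.0 for t in TRAITS}, rng=rng_trait,
            trait_noise_sd=cfg.trait_noise_sd,
        )

    truth = GroundTruth(
        config=cfg,
        deg_table=pd.DataFrame(
            [
                {
                    "gene": d.gene,
                    "region": d.region,
                    "log2_fc": d.log2_fc,
                    "sexes": ",".join(d.sexes),
                }
                for d in cfg.planted_degs
            ],
            columns=["gene", "region", "log2_fc", "sexes"],
        ),
        module_genes={m.name: m.genes for m in cfg.planted_modules},
        sex_specific_edges={
            sex: frozenset().union(
                *(
                    m.edges()
                    for m in cfg.planted_modules
                    if m.sexes == (sex,)
                ),
                frozenset(),
            )
            for sex in SEXES
        },
        stage_rewired_edges=frozenset().union(
            *(m.edges() for m in cfg.planted_modules if set(m.stages) != set(STAGES)),
            frozenset(),
        ),
        trait_driver=cfg.trait_driver,
    )
    return expr, meta, truth


#: mean trait value per stage index; strictly increasing with severity
STAGE_TRAIT_BASE = (1.0, 3.0, 5.0, 7.0)


def simulate_traits(
    meta: CohortMetadata,
    driver_by_subject: pd.Series | None,
    effects: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
    trait_noise_sd: float = 1.0,
) -> CohortMetadata:
    """Fill metadata trait columns from stage, driver expression and noise.

    trait = base(stage) + effect * z(driver) + N(0, trait_noise_sd), clamped
    at 0; the driver term uses the subject's standardized driver expression
    and is shared by all of a subject's samples. ``effects`` keys must be
    known trait names.
    """
    unknown = set(effects) - set(TRAITS)
    if unknown:
        raise DataError(f"unknown trait names: {sorted(unknown)}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    df = meta.table.copy()
    subjects = df["subject_id"].unique()
    if driver_by_subject is not None:
        missing = [s for s in subjects if s not in driver_by_subject.index]
        if missing:
            raise DataError(f"driver values missing for subjects: {missing}")
        z = driver_by_subject.loc[subjects]
        sd = z.std(ddof=0)
        z = (z - z.mean()) / sd if sd > 0 else z * 0.0
    else:
        z = pd.Series(0.0, index=subjects)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    base_by_subject = (
        df.drop_duplicates("subject_id")
        .set_index("subject_id")["stage"]
        .map(lambda s: STAGE_TRAIT_BASE[stage_idx[s]])
        .loc[subjects]
    )
    for trait in TRAITS:
        effect = float(effects.get(trait, 0.0))
        noise = rng.normal(0.0, trait_noise_sd, len(subjects))
        vals = np.maximum(
            base_by_subject.to_numpy() + effect * z.to_numpy() + noise, 0.0
        )
        per_subject = pd.Series(vals, index=subjects)
        df[trait] = df["subject_id"].map(per_subject)
    return CohortMetadata(df)
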