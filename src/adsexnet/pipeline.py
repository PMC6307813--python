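"""End-to-end orchestration: simulate/load -> DEGs -> networks -> modules ->
trait screen -> stage dynamics -> enrichment, with a reproducible manifest.

The pipeline is a pure function of (inputs, config): every stochastic step
consumes the configured seed, and re-running with an identical config
reproduces identical output files. Each stage logs structured counts
(genes, edges, modules) that double as regression tripwires.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import reference
from .clinical import results_to_table as km_table, screen_traits
from .core import (
    REGIONS,
    SEXES,
    TRAITS,
    CohortMetadata,
    DataError,
    ExpressionMatrix,
    load_expression,
    load_metadata,
    load_probe_map,
    collapse_probes,
    subset_cohort,
)
from .degs import call_degs, cross_region_sharing, deg_test, degs_to_table, fold_change
from .dynamics import (
    compare_score_distributions,
    dynamic_score,
    stage_networks,
)
from .enrichment import hypergeometric_enrich, read_gmt
from .enrichment import results_to_table as enrich_table
from .mcode import McodeParams, find_complexes, module_crosstalk, modules_to_table
from .network import build_network, jaccard_edges, network_partition
from .simulate import AD_STAGES, default_config, simulate_cohort

log = logging.getLogger("adsexnet")


@dataclass(frozen=True)
class PipelineConfig:
    # paths; all None means "simulate a synthetic cohort"
    expression_path: str | None = None
    metadata_path: str | None = None
    probe_map_path: str | None = None
    gmt_path: str | None = None
    output_dir: str = "adsexnet_run"
    # thresholds
    fc_hi: float = 1.5
    fc_lo: float = 2.0 / 3.0
    deg_alpha: float = 0.05
    pcc_r: float = 0.9
    pcc_alpha: float = 0.01
    module_r: float = 0.95
    min_stage_samples: int = 4
    mcode: McodeParams = field(default_factory=McodeParams)
    km_genes: tuple[str, ...] = ("GSK3B",)
    seed: int = 0
    # stage toggles
    run_degs: bool = True
    run_networks: bool = True
    run_modules: bool = True
    run_km: bool = True
    run_dynamics: bool = True
    run_enrichment: bool = True

    def __post_init__(self) -> None:
        for name in ("pcc_r", "module_r"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DataError(f"{name} must lie in (0, 1], got {v}")
        for name in ("deg_alpha", "pcc_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"{name} must lie in (0, 1), got {v}")
        if not (self.fc_hi > 1.0 and 0.0 < self.fc_lo < 1.0):
            raise DataError("need fc_hi > 1 and 0 < fc_lo < 1")
        if self.min_stage_samples < 3:
            raise DataError("min_stage_samples must be >= 3 (correlation needs n >= 3)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mcode" in raw and isinstance(raw["mcode"], dict):
            raw["mcode"] = McodeParams(**raw["mcode"])
        if "km_genes" in raw:
            raw["km_genes"] = tuple(raw["km_genes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["km_genes"] = list(self.km_genes)
        return d

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_cohort(cfg: PipelineConfig) -> tuple[ExpressionMatrix, CohortMetadata]:
    if cfg.expression_path is None:
        expr, meta, _ = simulate_cohort(default_config(seed=cfg.seed))
        return expr, meta
    if cfg.metadata_path is None:
        raise DataError("metadata_path required when expression_path is given")
    expr = load_expression(cfg.expression_path)
    if cfg.probe_map_path is not None:
        expr = collapse_probes(expr, load_probe_map(cfg.probe_map_path))
    return expr, load_metadata(cfg.metadata_path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; write artifacts + manifest under output_dir.

    Returns the result bundle as a dict (tables as DataFrames plus the
    manifest). Raises with the failing stage named; artifacts written
    before the failure are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.sha256(),
        "seed": cfg.seed,
        "counts": {},
    }
    stage = "load_cohort"
    try:
        t0 = time.perf_counter()
        expr, meta = _load_cohort(cfg)
        regions = sorted(set(meta.table["region"]))
        log.info(
            "stage=%s wall=%.2fs genes=%d samples=%d regions=%d",
            stage, time.perf_counter() - t0, expr.n_genes, expr.n_samples, len(regions),
        )
        manifest["counts"]["genes"] = expr.n_genes
        manifest["counts"]["samples"] = expr.n_samples
        bundle["expression"], bundle["metadata"] = expr, meta

        if cfg.run_degs:
            stage = "degs"
            t0 = time.perf_counter()
            records = []
            for region in regions:
                normal = meta.samples_where(region=region, stage="normal")
                ad = meta.samples_where(region=region, stage=list(AD_STAGES))
                if len(normal) < 2 or len(ad) < 2:
                    continue
                fc = fold_change(expr, ad, normal)
                p = deg_test(expr, ad, normal)
                records.extend(
                    call_degs(fc, p["p_value"], region, cfg.fc_hi, cfg.fc_lo, cfg.deg_alpha)
                )
            deg_df = degs_to_table(records)
            deg_df.to_csv(out / "degs.tsv", sep="\t", index=False)
            per_region = {
                r: list(sub["gene"]) for r, sub in deg_df.groupby("region")
            }
            sharing = cross_region_sharing(per_region) if per_region else None
            if sharing is not None:
                pd.DataFrame(
                    [
                        {"gene": g, "n_regions": len(rs), "regions": ";".join(rs)}
                        for g, rs in sorted(sharing.regions_of.items())
                    ]
                ).to_csv(out / "deg_sharing.tsv", sep="\t", index=False)
            log.info("stage=%s wall=%.2fs degs=%d", stage, time.perf_counter() - t0, len(records))
            manifest["counts"]["degs"] = len(records)
            bundle["degs"], bundle["sharing"] = deg_df, sharing

        sex_nets = {}
        if cfg.run_networks:
            stage = "networks"
            t0 = time.perf_counter()
            for sex in SEXES:
                samples = meta.samples_where(sex=sex, stage=list(AD_STAGES))
                sub = subset_cohort(expr, meta, sex=sex, stage=list(AD_STAGES))
                sex_nets[sex] = build_network(
                    sub, cfg.pcc_r, cfg.pcc_alpha, provenance={"sex": sex, "stages": list(AD_STAGES)}
                )
                sex_nets[sex].to_edge_table().to_csv(
                    out / f"network_{sex}_edges.tsv", sep="\t", index=False
                )
            m_spec, f_spec, overlap = network_partition(sex_nets["male"], sex_nets["female"])
            jac = jaccard_edges(
                sex_nets["male"].edge_set(), sex_nets["female"].edge_set(), "male", "female"
            )
            pd.DataFrame(
                [
                    {"network": "male", "edges": sex_nets["male"].n_edges},
                    {"network": "female", "edges": sex_nets["female"].n_edges},
                    {"network": "male_specific", "edges": m_spec.n_edges},
                    {"network": "female_specific", "edges": f_spec.n_edges},
                    {"network": "overlap", "edges": overlap.n_edges},
                    {"network": "jaccard", "edges": jac.jaccard},
                ]
            ).to_csv(out / "network_summary.tsv", sep="\t", index=False)
            log.info(
                "stage=%s wall=%.2fs male_edges=%d female_edges=%d jaccard=%.4f",
                stage, time.perf_counter() - t0,
                sex_nets["male"].n_edges, sex_nets["female"].n_edges, jac.jaccard,
            )
            manifest["counts"]["male_edges"] = sex_nets["male"].n_edges
            manifest["counts"]["female_edges"] = sex_nets["female"].n_edges
            manifest["counts"]["overlap_edges"] = overlap.n_edges
            bundle["networks"] = {
                "male": sex_nets["male"], "female": sex_nets["female"],
                "male_specific": m_spec, "female_specific": f_spec, "overlap": overlap,
                "jaccard": jac,
            }

        if cfg.run_modules:
            stage = "modules"
            t0 = time.perf_counter()
            modules = {}
            for sex, prefix in (("male", "M"), ("female", "F")):
                sub = subset_cohort(expr, meta, sex=sex, stage=list(AD_STAGES))
                strict = build_network(
                    sub, cfg.module_r, cfg.pcc_alpha, signed=True,
                    provenance={"sex": sex, "signed": True},
                )
                modules[sex] = find_complexes(strict, cfg.mcode, prefix=prefix)
                modules_to_table(modules[sex]).to_csv(
                    out / f"modules_{sex}.tsv", sep="\t", index=False
                )
            if modules["male"] and modules["female"]:
                crosstalk, inter = module_crosstalk(modules["male"], modules["female"])
                crosstalk.to_csv(out / "module_crosstalk.tsv", sep="\t")
                bundle["crosstalk"] = (crosstalk, inter)
            log.info(
                "stage=%s wall=%.2fs male_modules=%d female_modules=%d",
                stage, time.perf_counter() - t0, len(modules["male"]), len(modules["female"]),
            )
            manifest["counts"]["male_modules"] = len(modules["male"])
            manifest["counts"]["female_modules"] = len(modules["female"])
            bundle["modules"] = modules

        if cfg.run_km:
            stage = "km_screen"
            t0 = time.perf_counter()
            genes = [g for g in cfg.km_genes if g in expr.values.index]
            traits = [t for t in TRAITS if t in meta.table.columns]
            if genes and traits:
                results = screen_traits(expr, meta, genes, traits)
                km_df = km_table(results)
                km_df.to_csv(out / "km_screen.tsv", sep="\t", index=False)
                bundle["km"] = results
                manifest["counts"]["km_tests"] = len(results)
            log.info("stage=%s wall=%.2fs tests=%d", stage, time.perf_counter() - t0,
                     manifest["counts"].get("km_tests", 0))

        if cfg.run_dynamics:
            stage = "dynamics"
            t0 = time.perf_counter()
            records = {"male": [], "female": []}
            for sex in SEXES:
                for region in regions:
                    nets = stage_networks(
                        expr, meta, region, sex,
                        min_samples=cfg.min_stage_samples,
                        r_threshold=cfg.pcc_r, alpha=cfg.pcc_alpha,
                    )
                    if nets.get("normal") is None or nets["normal"].n_edges == 0:
                        log.info("dynamics: %s/%s skipped (no usable normal network)",
                                 region, sex)
                        continue
                    records[sex].append(dynamic_score(nets, region, sex))
            rows = [
                {
                    "region": r.region, "sex": r.sex,
                    **{f"edges_{s}": c for s, c in r.stage_edge_counts.items()},
                    "overlap": r.overlap_num, "score": r.score,
                }
                for sex in SEXES for r in records[sex]
            ]
            pd.DataFrame(rows).to_csv(out / "dynamic_scores.tsv", sep="\t", index=False)
            paired = set(r.region for r in records["male"]) & set(
                r.region for r in records["female"]
            )
            if len(paired) >= 2:
                comparison = compare_score_distributions(
                    [r for r in records["male"] if r.region in paired],
                    [r for r in records["female"] if r.region in paired],
                )
                bundle["score_comparison"] = comparison
            log.info("stage=%s wall=%.2fs records=%d", stage, time.perf_counter() - t0,
                     len(rows))
            manifest["counts"]["dynamic_records"] = len(rows)
            bundle["dynamics"] = records

        if cfg.run_enrichment and cfg.gmt_path is not None:
            stage = "enrichment"
            t0 = time.perf_counter()
            collection = read_gmt(cfg.gmt_path)
            query = (
                sorted(set(bundle["degs"]["gene"])) if bundle.get("degs") is not None
                and len(bundle["degs"]) else []
            )
            if query:
                results = hypergeometric_enrich(query, collection, expr.gene_ids)
                enrich_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
                bundle["enrichment"] = results
                manifest["counts"]["enriched_sets"] = len(results)
            log.info("stage=%s wall=%.2fs sets=%d", stage, time.perf_counter() - t0,
                     manifest["counts"].get("enriched_sets", 0))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle


def fixtures_check() -> dict:
    """Recompute every in-table acceptance quantity from the bundled fixtures.

    Returns {check_name: {"value": ..., "expected": ..., "passed": bool}}.
    The three known-inconsistent stage-score rows are reported as failures
    (the source table's internal inconsistency, not a fixture defect).
    """
    report: dict = {}
    sharing = reference.region_deg_sharing()
    sizes = {r: len(g) for r, g in reference.load_region_deg_table().items()}
    jac = reference.overall_jaccard()
    checks = [
        ("overall_jaccard", round(jac.jaccard, 2), 0.26),
        ("genes_in_3plus_regions", len(sharing.genes_in_at_least(3)), 17),
        ("genes_in_4_regions", sorted(sharing.genes_in_exactly(4)),
         ["ASPA", "ESRRB", "GRM2", "KIF26B"]),
        ("min_region_deg_count", min(sizes.values()), 7),
        ("max_region_deg_count", max(sizes.values()), 46),
    ]
    for name, value, expected in checks:
        report[name] = {"value": value, "expected": expected, "passed": value == expected}
    scores = reference.check_stage_scores()
    for _, row in scores.iterrows():
        name = f"stage_score[{row['region']}/{row['sex']}]"
        report[name] = {
            "value": row["score_recomputed"],
            "expected": float(row["score_printed"]),
            "passed": bool(row["consistent"]),
        }
    return report
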