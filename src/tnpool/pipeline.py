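"""Config-driven end-to-end runs: simulate -> design -> decode -> annotate
-> essentiality -> mgwa -> enrich, with a machine-readable run report.

A :class:`RunConfig` holds every stage toggle and parameter; a single master
seed deterministically derives per-stage seeds, so two runs with equal
configs produce byte-identical outputs. The report counts what each stage
produced (mutants simulated, sites decoded per status, genes hit,
zero-insertion genes, pathways tested, OGs tested, top hits).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate, decode, design as design_mod, enrichment, io as tio, mgwa, synth

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "decode", "annotate", "essentiality", "mgwa", "loads")


@dataclass
class RunConfig:
    """All pipeline parameters; serializes losslessly to/from YAML."""

    outdir: str = "tnpool_run"
    master_seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))

    # design
    n_plates: int = 10
    n_pools: int = 24
    weights: list[int] = field(default_factory=lambda: [10, 12, 14])
    subset_free: bool = False
    min_distance: int | None = None

    # simulation
    n_genes: int = 500
    genome_length: int = 1_000_000
    n_pathways: int = 8
    pathway_size: int = 20
    n_essential: int = 50
    n_mutants: int = 900
    intergenic_fraction: float = 0.15
    sister_clone_rate: float = 0.02
    mean_depth: float = 200.0
    dropout_p: float = 0.0
    spurious_site_rate: float = 0.0

    # decode
    threshold: int = 50

    # annotate / essentiality
    rarefaction_permutations: int = 100
    B: int = 2000
    min_count: int = 4

    # mgwa
    n_strains: int = 41
    n_ogs: int = 50
    effect_ogs: dict[str, float] = field(default_factory=dict)
    mgwa_cutoff: float = 0.001

    # loads
    treatments: list[str] = field(default_factory=lambda: ["WT", "lpxB", "lpxC", "gmhD", "lpxK"])
    true_deltas: dict[str, float] = field(default_factory=dict)
    control_treatment: str = "WT"

    # external inputs (used when the corresponding stage's simulation is off)
    counts_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the master seed (stable, < 2**31)."""
        ss = np.random.SeedSequence([self.master_seed, _STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    enabled = set(config.stages)
    unknown = enabled - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    pooling = annotation = library = matrix = decoded = hit_table = None

    if config.design_path:
        pooling = tio.read_design(config.design_path)
    elif enabled & {"simulate", "decode"}:
        logger.info("stage design: building pooling design (%d plates)", config.n_plates)
        pooling = design_mod.build_design(
            n_plates=config.n_plates,
            n_pools=config.n_pools,
            weights=set(config.weights),
            subset_free=config.subset_free,
            min_distance=config.min_distance,
            seed=config.stage_seed("simulate"),
        )
        tio.write_design(pooling, outdir / "design.tsv")

    if config.annotation_path:
        annotation = tio.read_annotation(config.annotation_path)

    if "simulate" in enabled:
        seed = config.stage_seed("simulate")
        logger.info("stage simulate: %d genes, %d mutants", config.n_genes, config.n_mutants)
        if annotation is None:
            annotation = synth.gen_annotation(
                n_genes=config.n_genes,
                genome_length=config.genome_length,
                pathway_sizes={
                    f"ko{i + 1:05d}": config.pathway_size for i in range(config.n_pathways)
                },
                seed=seed,
            )
            tio.write_annotation_tsv(annotation, outdir / "annotation.tsv")
            tio.write_annotation_gff3(annotation, outdir / "annotation.gff3")
        rng = np.random.default_rng(seed)
        essential = set(
            rng.choice(annotation.gene_ids, size=min(config.n_essential, annotation.n_genes), replace=False)
        )
        library = synth.gen_library(
            annotation,
            n_mutants=config.n_mutants,
            essential_genes=essential,
            intergenic_fraction=config.intergenic_fraction,
            sister_clone_rate=config.sister_clone_rate,
            seed=seed,
        )
        tio.write_library(library, outdir / "true_library.tsv")
        (outdir / "true_essential_genes.tsv").write_text(
            "gene_id\n" + "\n".join(sorted(essential)) + "\n"
        )
        matrix = synth.gen_pool_reads(
            library,
            pooling,
            mean_depth=config.mean_depth,
            dropout_p=config.dropout_p,
            spurious_site_rate=config.spurious_site_rate,
            seed=seed,
        )
        tio.write_counts(matrix, outdir / "counts.tsv")
        report["stages"]["simulate"] = {
            "mutants_simulated": len(library.records),
            "unique_sites": len(library.unique_sites()),
            "essential_genes": len(essential),
        }

    if "decode" in enabled:
        if matrix is None:
            if not config.counts_path:
                raise FileNotFoundError("decode stage needs simulated data or counts_path")
            matrix = tio.read_counts(config.counts_path)
        if pooling is None:
            raise FileNotFoundError("decode stage needs a design (simulated or design_path)")
        decoded = decode.decode_library(matrix, pooling, threshold=config.threshold)
        tio.write_decoded(decoded, outdir / "decoded.tsv", n_pools=pooling.n_pools)
        hist = decode.pool_count_histogram(decoded, n_pools=pooling.n_pools)
        (outdir / "pool_count_histogram.tsv").write_text(
            "weight\tsites\n" + "\n".join(f"{w}\t{c}" for w, c in enumerate(hist)) + "\n"
        )
        report["stages"]["decode"] = {
            "sites": len(decoded.records),
            "mapped_count": decoded.mapped_count,
            "status_counts": decoded.summary,
        }

    if "annotate" in enabled:
        if decoded is None or annotation is None:
            raise FileNotFoundError("annotate stage needs decoded data and an annotation")
        hit_table = annotate.assign_insertions(decoded, annotation)
        curve = annotate.rarefaction(
            hit_table.per_mutant_genes,
            n_permutations=config.rarefaction_permutations,
            seed=config.stage_seed("annotate"),
        )
        pd_frame = hit_table.gene_counts.rename("insertions").rename_axis("gene_id").reset_index()
        tio._write_tsv(pd_frame, outdir / "gene_hits.tsv", "per-gene insertion counts")
        (outdir / "rarefaction.tsv").write_text(
            "mutants\tmean_distinct_genes\n"
            + "\n".join(f"{k + 1}\t{v:.4f}" for k, v in enumerate(curve))
            + "\n"
        )
        report["stages"]["annotate"] = {
            "mapped_mutants": hit_table.mapped_mutants,
            "mutants_in_orfs": hit_table.mutants_in_orfs,
            "genes_hit": hit_table.genes_hit,
            "genes_total": hit_table.genes_total,
        }

    if "essentiality" in enabled:
        if hit_table is None or annotation is None:
            raise FileNotFoundError("essentiality stage needs the annotate stage")
        zero = annotate.zero_insertion_genes(hit_table, annotation)
        results = annotate.pathway_essentiality_enrichment(
            zero,
            annotation,
            B=config.B,
            min_count=config.min_count,
            seed=config.stage_seed("essentiality"),
        )
        tio._write_tsv(
            enrichment.results_to_frame(results),
            outdir / "essentiality.tsv",
            f"pathway essentiality enrichment, B={config.B}, min_count={config.min_count}",
        )
        report["stages"]["essentiality"] = {
            "zero_insertion_genes": len(zero),
            "pathways_tested": len(results),
        }

    if "mgwa" in enabled:
        seed = config.stage_seed("mgwa")
        panel = synth.gen_strain_panel(
            n_strains=config.n_strains,
            n_ogs=config.n_ogs,
            effect_ogs=config.effect_ogs,
            seed=seed,
        )
        tio.write_strain_panel(panel, outdir / "og_presence.tsv", outdir / "phenotypes.tsv")
        results, top = mgwa.run_mgwa(panel, cutoff=config.mgwa_cutoff)
        tio._write_tsv(
            mgwa.mgwa_results_to_frame(results),
            outdir / "mgwa_results.tsv",
            f"per-OG mixed-model association, cutoff={config.mgwa_cutoff}",
        )
        report["stages"]["mgwa"] = {
            "ogs_tested": sum(r.status == "tested" for r in results),
            "ogs_monomorphic": sum(r.status == "monomorphic" for r in results),
            "ogs_failed": sum(r.status == "failed" for r in results),
            "top_hits": len(top),
        }

    if "loads" in enabled:
        seed = config.stage_seed("loads")
        loads = synth.gen_load_table(
            treatments=config.treatments,
            true_deltas=config.true_deltas,
            control=config.control_treatment,
            seed=seed,
        )
        tio.write_load_table(loads, outdir / "loads.tsv")
        comparisons = mgwa.compare_loads(loads)
        lines = ["treatment\teffect\tp_value\tsignificant"]
        for c in comparisons:
            lines.append(f"{c.treatment}\t{c.effect:.4f}\t{'' if c.p is None else f'{c.p:.4g}'}\t{c.significant}")
        (outdir / "load_comparison.tsv").write_text("\n".join(lines) + "\n")
        report["stages"]["loads"] = {
            "treatments": len(config.treatments),
            "significant": sum(c.significant for c in comparisons),
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    summary = ", ".join(
        f"{stage}: {info}" for stage, info in report["stages"].items()
    )
    logger.info("pipeline complete: %s", summary)
    return report
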