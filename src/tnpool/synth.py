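"""Synthetic data with known ground truth for the pooled-library pipeline.

Generates every input the pipeline consumes: a bacterial genome annotation,
an arrayed transposon-insertion library with known well assignments (and
optional sister clones), the pooled read-count matrix the decoder sees, a
strain panel (orthologous-group presence/absence plus replicate CFU loads)
for association testing, and replicate CFU load tables for mutant-vs-control
comparisons.

The generators emulate the statistical structure of the real experiment:

* insertions land uniformly per base pair in non-essential gene space or
  intergenic space, never inside a designated essential gene;
* sister clones (one transposant picked into two wells) share a site whose
  pooled signal is the sum of both wells' pool patterns;
* pools truly containing a mutant draw negative-binomial read depths
  (overdispersion typical of pooled sequencing) with independent per-pool
  dropout; absent pools draw low Poisson noise (index bleed); spurious
  sites from sequencing error light up only 1-2 pools;
* log CFU loads decompose into a baseline, fixed genotype effects, and
  independent zero-mean experiment / strain random effects plus residual
  noise, the variance structure the association model assumes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decode import ReadCountMatrix, Site
from .design import WELLS_PER_PLATE, PoolingDesign

__all__ = [
    "GenomeAnnotation",
    "TrueLibrary",
    "LibraryRecord",
    "StrainPanel",
    "LoadTable",
    "SizingError",
    "gen_annotation",
    "gen_library",
    "gen_pool_reads",
    "gen_strain_panel",
    "gen_load_table",
]


class SizingError(ValueError):
    """A generator request that cannot fit in the available space."""


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene coordinates (1-based, inclusive) with pathway labels."""

    genes: pd.DataFrame  # columns: gene_id, contig, start, end, strand
    pathway_labels: dict[str, set[str]]  # gene_id -> set of pathway ids
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        if len(g) and not (g["start"] <= g["end"]).all():
            raise ValueError("gene start must be <= end")
        if g["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for contig, sub in g.groupby("contig"):
            length = self.contig_lengths.get(contig)
            if length is None or (sub["end"] > length).any():
                raise ValueError(f"genes extend past contig {contig} length")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def pathway_sizes(self) -> pd.Series:
        counts: dict[str, int] = {}
        for labels in self.pathway_labels.values():
            for p in labels:
                counts[p] = counts.get(p, 0) + 1
        return pd.Series(counts, dtype=int).sort_index()


@dataclass(frozen=True)
class LibraryRecord:
    mutant_id: str
    plate: int
    well: int
    insertion_site: Site
    is_sister_clone: bool = False
    sister_group_id: int | None = None


@dataclass(frozen=True)
class TrueLibrary:
    """Ground-truth arrayed library: one record per occupied well."""

    records: list[LibraryRecord]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wells = [(r.plate, r.well) for r in self.records]
        if len(set(wells)) != len(wells):
            raise ValueError("(plate, well) must be unique across records")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    mutant_id=r.mutant_id,
                    plate=r.plate,
                    well=r.well,
                    contig=r.insertion_site[0],
                    position=r.insertion_site[1],
                    strand=r.insertion_site[2],
                    is_sister_clone=r.is_sister_clone,
                    sister_group_id=r.sister_group_id,
                )
                for r in self.records
            ]
        )

    def unique_sites(self) -> list[Site]:
        seen: dict[Site, None] = {}
        for r in self.records:
            seen.setdefault(r.insertion_site)
        return list(seen)


@dataclass(frozen=True)
class StrainPanel:
    """OG presence/absence across strains plus replicate CFU phenotypes."""

    og_presence: pd.DataFrame  # strains x OGs, 0/1, index = strain ids
    phenotypes: pd.DataFrame  # columns: strain_id, experiment_id, replicate_id, cfu_count
    true_effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.phenotypes["strain_id"]) - set(self.og_presence.index)
        if missing:
            raise ValueError(f"phenotype strains absent from presence matrix: {sorted(missing)}")
        if (self.phenotypes["cfu_count"] < 0).any():
            raise ValueError("cfu_count must be >= 0")

    @property
    def og_ids(self) -> list[str]:
        return list(self.og_presence.columns)


@dataclass(frozen=True)
class LoadTable:
    """Replicate CFU loads per bacterial treatment per experiment."""

    rows: pd.DataFrame  # columns: treatment_id, experiment_id, replicate_id, cfu_count
    control_treatment: str

    def __post_init__(self) -> None:
        if self.control_treatment not in set(self.rows["treatment_id"]):
            raise ValueError(f"control treatment {self.control_treatment!r} absent from table")
        if (self.rows["cfu_count"] < 0).any():
            raise ValueError("cfu_count must be >= 0")


def gen_annotation(
    n_genes: int,
    genome_length: int,
    pathway_sizes: dict[str, int] | None = None,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 1500),
    contig: str = "contig_1",
) -> GenomeAnnotation:
    """Place ``n_genes`` non-overlapping genes on one contig and label pathways.

    Gene lengths are uniform over ``gene_length_range`` (default 300-1500 bp,
    a typical bacterial ORF-length spread) and the leftover sequence is
    distributed multinomially among the intergenic gaps. Each pathway's
    members are drawn without replacement from the gene list; a gene may
    belong to several pathways.
    """
    pathway_sizes = pathway_sizes or {}
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        genes = pd.DataFrame(columns=["gene_id", "contig", "start", "end", "strand"])
        return GenomeAnnotation(genes=genes, pathway_labels={}, contig_lengths={contig: genome_length})
    lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_genes)
    total = int(lengths.sum())
    if total > genome_length:
        raise SizingError(
            f"{n_genes} genes need {total} bp but genome is {genome_length} bp"
        )
    for p, k in pathway_sizes.items():
        if k > n_genes:
            raise SizingError(f"pathway {p!r} wants {k} genes but only {n_genes} exist")
    slack = genome_length - total
    gaps = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])]) + 1
    ends = starts + lengths - 1
    width = len(str(n_genes))
    genes = pd.DataFrame(
        dict(
            gene_id=[f"gene_{i + 1:0{width}d}" for i in range(n_genes)],
            contig=contig,
            start=starts.astype(int),
            end=ends.astype(int),
            strand=rng.choice(["+", "-"], size=n_genes),
        )
    )
    labels: dict[str, set[str]] = {}
    for pathway in sorted(pathway_sizes):
        members = rng.choice(genes["gene_id"], size=pathway_sizes[pathway], replace=False)
        for gid in members:
            labels.setdefault(str(gid), set()).add(pathway)
    return GenomeAnnotation(
        genes=genes, pathway_labels=labels, contig_lengths={contig: genome_length}
    )


def _interval_space(intervals: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(starts, cumulative lengths) for uniform per-bp sampling over spans."""
    starts = intervals["start"].to_numpy()
    lengths = (intervals["end"] - intervals["start"] + 1).to_numpy()
    return starts, np.cumsum(lengths)


def _sample_positions(rng, starts: np.ndarray, cum: np.ndarray, k: int) -> np.ndarray:
    total = int(cum[-1]) if len(cum) else 0
    if total == 0:
        raise SizingError("no base pairs available in the requested target space")
    offsets = rng.integers(0, total, size=k)
    idx = np.searchsorted(cum, offsets, side="right")
    prev = np.concatenate([[0], cum[:-1]])
    return starts[idx] + (offsets - prev[idx])


def _intergenic_intervals(annotation: GenomeAnnotation, contig: str) -> pd.DataFrame:
    length = annotation.contig_lengths[contig]
    sub = annotation.genes[annotation.genes["contig"] == contig].sort_values("start")
    spans = []
    cursor = 1
    for _, g in sub.iterrows():
        if g["start"] > cursor:
            spans.append((cursor, g["start"] - 1))
        cursor = max(cursor, g["end"] + 1)
    if cursor <= length:
        spans.append((cursor, length))
    return pd.DataFrame(spans, columns=["start", "end"])


def gen_library(
    annotation: GenomeAnnotation,
    n_mutants: int,
    essential_genes: set[str] | frozenset[str] = frozenset(),
    intergenic_fraction: float = 0.15,
    sister_clone_rate: float = 0.02,
    seed: int = 0,
) -> TrueLibrary:
    """Array ``n_mutants`` transposants into 96-well plates with known sites.

    Insertions never fall inside an essential gene: each mutant is intergenic
    with probability ``intergenic_fraction``, otherwise uniform per-bp over
    non-essential gene space. With probability ``sister_clone_rate`` a mutant
    is a sister clone of an earlier one (same insertion site, distinct well).
    Wells are filled plate by plate in row-major A1..H12 order.
    """
    if not 0 <= intergenic_fraction <= 1 or not 0 <= sister_clone_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    unknown = set(essential_genes) - set(annotation.gene_ids)
    if unknown:
        raise ValueError(f"essential genes not in annotation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    contig = next(iter(annotation.contig_lengths))
    genic = annotation.genes[
        (annotation.genes["contig"] == contig)
        & ~annotation.genes["gene_id"].isin(essential_genes)
    ]
    inter = _intergenic_intervals(annotation, contig)
    genic_bp = int((genic["end"] - genic["start"] + 1).sum())
    inter_bp = int((inter["end"] - inter["start"] + 1).sum())
    if n_mutants > 0:
        if intergenic_fraction < 1 and genic_bp == 0:
            raise SizingError("no non-essential gene space available for insertions")
        if intergenic_fraction > 0 and inter_bp == 0:
            raise SizingError("no intergenic space available for insertions")

    records: list[LibraryRecord] = []
    unique_sites: list[Site] = []
    sister_groups: dict[Site, int] = {}
    g_starts, g_cum = _interval_space(genic) if len(genic) else (np.array([]), np.array([]))
    i_starts, i_cum = _interval_space(inter) if len(inter) else (np.array([]), np.array([]))
    used_positions: set[int] = set()
    width = len(str(max(n_mutants, 1)))
    for m in range(n_mutants):
        plate, well = m // WELLS_PER_PLATE + 1, m % WELLS_PER_PLATE
        is_sister = bool(unique_sites) and rng.random() < sister_clone_rate
        if is_sister:
            site = unique_sites[int(rng.integers(len(unique_sites)))]
            group = sister_groups.setdefault(site, len(sister_groups))
            records.append(
                LibraryRecord(
                    mutant_id=f"mut_{m + 1:0{width}d}",
                    plate=plate,
                    well=well,
                    insertion_site=site,
                    is_sister_clone=True,
                    sister_group_id=group,
                )
            )
            continue
        for _ in range(1000):  # rejection: keep unique sites distinct
            if rng.random() < intergenic_fraction:
                pos = int(_sample_positions(rng, i_starts, i_cum, 1)[0])
            else:
                pos = int(_sample_positions(rng, g_starts, g_cum, 1)[0])
            if pos not in used_positions:
                break
        else:
            raise SizingError("could not place a unique insertion site; target space too small")
        used_positions.add(pos)
        site = (contig, pos, str(rng.choice(["+", "-"])))
        unique_sites.append(site)
        records.append(
            LibraryRecord(
                mutant_id=f"mut_{m + 1:0{width}d}",
                plate=plate,
                well=well,
                insertion_site=site,
            )
        )
    return TrueLibrary(records=records, contig_lengths=dict(annotation.contig_lengths))


def _nb_draws(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + dispersion*mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def gen_pool_reads(
    library: TrueLibrary,
    design: PoolingDesign,
    mean_depth: float = 200.0,
    dropout_p: float = 0.0,
    spurious_site_rate: float = 0.0,
    seed: int = 0,
    dispersion: float = 0.3,
    noise_mean: float = 0.5,
) -> ReadCountMatrix:
    """Simulate the pooled sequencing run for an arrayed library.

    For every well holding a mutant, the pools flagged in that well's
    codeword receive negative-binomial read counts centred on ``mean_depth``
    (independently zeroed with probability ``dropout_p``); a site shared by
    sister clones accumulates the sum over its wells. Pools outside a site's
    union pattern receive Poisson(``noise_mean``) background. Spurious sites
    (sequencing artifacts) are added at Poisson(``spurious_site_rate`` x
    number of true sites) and light up 1-2 random pools at full depth.
    """
    rng = np.random.default_rng(seed)
    n_pools = design.n_pools
    site_index: dict[Site, int] = {}
    for r in library.records:
        site_index.setdefault(r.insertion_site, len(site_index))
        if (r.plate, r.well) not in design.assignments:
            raise ValueError(f"well (plate={r.plate}, well={r.well}) absent from design")
    sites = list(site_index)
    counts = np.zeros((len(sites), n_pools), dtype=np.int64)
    present = np.zeros((len(sites), n_pools), dtype=bool)
    for r in library.records:
        i = site_index[r.insertion_site]
        cw = design.assign(r.plate, r.well)
        pools = [p for p in range(n_pools) if cw >> p & 1]
        depths = _nb_draws(rng, mean_depth, dispersion, len(pools))
        if dropout_p > 0:
            depths = np.where(rng.random(len(pools)) < dropout_p, 0, depths)
        counts[i, pools] += depths
        present[i, pools] = True
    if noise_mean > 0 and counts.size:
        absent = ~present
        counts[absent] += rng.poisson(noise_mean, size=int(absent.sum()))

    if spurious_site_rate > 0:
        contig = next(iter(library.contig_lengths)) if library.contig_lengths else "contig_1"
        length = library.contig_lengths.get(contig, 10**6)
        taken = {s[1] for s in sites if s[0] == contig}
        n_spur = rng.poisson(spurious_site_rate * max(len(sites), 1))
        spur_rows = []
        for _ in range(n_spur):
            while True:
                pos = int(rng.integers(1, length + 1))
                if pos not in taken:
                    taken.add(pos)
                    break
            sites.append((contig, pos, str(rng.choice(["+", "-"]))))
            row = np.zeros(n_pools, dtype=np.int64)
            k = int(rng.integers(1, 3))  # sequencing artifacts hit 1-2 pools
            pools = rng.choice(n_pools, size=k, replace=False)
            row[pools] = _nb_draws(rng, mean_depth, dispersion, k)
            spur_rows.append(row)
        if spur_rows:
            counts = np.vstack([counts, np.array(spur_rows)])
    return ReadCountMatrix(sites=sites, counts=counts)


def gen_strain_panel(
    n_strains: int = 41,
    n_ogs: int = 200,
    effect_ogs: dict[str, float] | None = None,
    n_experiments: int = 3,
    reps_per_cell: int = 3,
    sd_experiment: float = 0.5,
    sd_strain: float = 0.8,
    sd_residual: float = 0.7,
    baseline_log_cfu: float = 11.5,
    seed: int = 0,
    presence: pd.DataFrame | None = None,
) -> StrainPanel:
    """Simulate an OG presence panel with replicate CFU phenotypes.

    log CFU = baseline + sum of effects of OGs present + experiment effect
    ~ N(0, sd_experiment^2) + strain effect ~ N(0, sd_strain^2) + residual
    ~ N(0, sd_residual^2); the reported count is round(exp(log CFU)).
    Presence is Bernoulli(0.5) per cell unless a matrix is supplied. The
    defaults mirror a 41-strain monoassociation survey read out in 3
    experiments x 3 replicates with loads around e^11.5 ~ 1e5 CFU.
    """
    effect_ogs = effect_ogs or {}
    for sd in (sd_experiment, sd_strain, sd_residual):
        if sd < 0:
            raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    og_ids = [f"OG_{i + 1:04d}" for i in range(n_ogs)]
    strain_ids = [f"strain_{i + 1:02d}" for i in range(n_strains)]
    if presence is None:
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(n_strains, n_ogs)), index=strain_ids, columns=og_ids
        )
    else:
        strain_ids, og_ids = list(presence.index), list(presence.columns)
        n_strains, n_ogs = presence.shape
    unknown = set(effect_ogs) - set(og_ids)
    if unknown:
        raise ValueError(f"effect OGs not in panel: {sorted(unknown)}")

    genetic = np.zeros(n_strains)
    for og, eff in effect_ogs.items():
        genetic += presence[og].to_numpy() * eff
    exp_eff = rng.normal(0, sd_experiment, size=n_experiments)
    strain_eff = rng.normal(0, sd_strain, size=n_strains)
    rows = []
    for s, sid in enumerate(strain_ids):
        for e in range(n_experiments):
            resid = rng.normal(0, sd_residual, size=reps_per_cell)
            log_cfu = baseline_log_cfu + genetic[s] + exp_eff[e] + strain_eff[s] + resid
            for rep, lc in enumerate(log_cfu):
                rows.append(
                    dict(
                        strain_id=sid,
                        experiment_id=f"exp_{e + 1}",
                        replicate_id=rep + 1,
                        cfu_count=int(max(round(np.exp(lc)), 0)),
                    )
                )
    phenotypes = pd.DataFrame(rows)
    return StrainPanel(
        og_presence=presence, phenotypes=phenotypes, true_effect=dict(effect_ogs)
    )


def gen_load_table(
    treatments: list[str],
    true_deltas: dict[str, float] | None = None,
    control: str | None = None,
    n_experiments: int = 3,
    reps: int = 3,
    sd_experiment: float = 0.5,
    sd_residual: float = 0.7,
    baseline_log_cfu: float = 11.5,
    seed: int = 0,
) -> LoadTable:
    """Simulate a mutant-vs-control CFU load experiment.

    Same mixed structure as :func:`gen_strain_panel` with per-treatment fixed
    shifts on log CFU (control shift 0); by default three experiments each in
    triplicate, the replication of the validation experiments this emulates.
    """
    true_deltas = true_deltas or {}
    control = control if control is not None else treatments[0]
    if control not in treatments:
        raise ValueError(f"control {control!r} not among treatments")
    if true_deltas.get(control, 0.0) != 0.0:
        raise ValueError("control treatment must have delta 0")
    unknown = set(true_deltas) - set(treatments)
    if unknown:
        raise ValueError(f"deltas given for unknown treatments: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    exp_eff = rng.normal(0, sd_experiment, size=n_experiments)
    rows = []
    for t in treatments:
        delta = true_deltas.get(t, 0.0)
        for e in range(n_experiments):
            resid = rng.normal(0, sd_residual, size=reps)
            log_cfu = baseline_log_cfu + delta + exp_eff[e] + resid
            for rep, lc in enumerate(log_cfu):
                rows.append(
                    dict(
                        treatment_id=t,
                        experiment_id=f"exp_{e + 1}",
                        replicate_id=rep + 1,
                        cfu_count=int(max(round(np.exp(lc)), 0)),
                    )
                )
    return LoadTable(rows=pd.DataFrame(rows), control_treatment=control)
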