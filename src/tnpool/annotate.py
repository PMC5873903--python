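"""Insertion-to-gene assignment, saturation analysis, essentiality enrichment.

Once insertions are decoded to wells, each mapped site is assigned to the
gene(s) whose span contains its position (1-based, inclusive on both ends,
strand-agnostic) or called intergenic. Saturation of the library is
quantified by a rarefaction curve — the expected number of distinct genes
hit as mutants are added in random order. Genes with zero insertions in a
near-saturated library are candidate essential genes; pathway-level
enrichment of the zero-insertion set against the genome background (a
Monte-Carlo chi-square per pathway, BH-FDR across pathways) yields
pathway essentiality predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decode import DecodedLibrary, Site, Status
from .enrichment import (
    DEFAULT_B,
    DEFAULT_MIN_COUNT,
    EnrichmentResult,
    enrichment_scan,
)
from .synth import GenomeAnnotation

__all__ = [
    "GeneHitTable",
    "assign_insertions",
    "rarefaction",
    "zero_insertion_genes",
    "pathway_essentiality_enrichment",
]

INTERGENIC = "__intergenic__"


@dataclass(frozen=True)
class GeneHitTable:
    """Per-gene insertion counts for the mapped portion of a library.

    A site inside two overlapping genes increments both genes' hit counts
    but contributes once to ``mutants_in_orfs``; gene-level saturation, not
    double counting, is the quantity of interest.
    """

    gene_counts: pd.Series  # index: all gene_ids, value: insertion count
    gene_sites: dict[str, list[Site]]
    intergenic_sites: list[Site]
    per_mutant_genes: list[str] = field(default_factory=list)  # gene id or INTERGENIC, one per mapped mutant

    @property
    def genes_total(self) -> int:
        return len(self.gene_counts)

    @property
    def genes_hit(self) -> int:
        return int((self.gene_counts > 0).sum())

    @property
    def mutants_in_orfs(self) -> int:
        return sum(g != INTERGENIC for g in self.per_mutant_genes)

    @property
    def mapped_mutants(self) -> int:
        return len(self.per_mutant_genes)


def assign_insertions(decoded: DecodedLibrary, annotation: GenomeAnnotation) -> GeneHitTable:
    """Assign each MAPPED insertion site to containing gene(s) or intergenic.

    Position p lies in gene g iff start_g <= p <= end_g on the same contig,
    regardless of strand. Sites on contigs absent from the annotation raise,
    listing the offenders.
    """
    mapped = [r.site for r in decoded.records if r.status is Status.MAPPED]
    unknown = sorted({s[0] for s in mapped} - set(annotation.contig_lengths))
    if unknown:
        raise ValueError(f"sites on contigs missing from annotation: {unknown}")

    genes = annotation.genes
    gene_counts = pd.Series(0, index=pd.Index(annotation.gene_ids, name="gene_id"), dtype=int)
    gene_sites: dict[str, list[Site]] = {}
    intergenic: list[Site] = []
    per_mutant: list[str] = []
    by_contig = {c: sub for c, sub in genes.groupby("contig")}
    for site in mapped:
        contig, pos, _ = site
        sub = by_contig.get(contig)
        hits = []
        if sub is not None:
            inside = (sub["start"] <= pos) & (sub["end"] >= pos)
            hits = list(sub.loc[inside, "gene_id"])
        if hits:
            for gid in hits:
                gene_counts[gid] += 1
                gene_sites.setdefault(gid, []).append(site)
            per_mutant.append(hits[0])
        else:
            intergenic.append(site)
            per_mutant.append(INTERGENIC)
    return GeneHitTable(
        gene_counts=gene_counts,
        gene_sites=gene_sites,
        intergenic_sites=intergenic,
        per_mutant_genes=per_mutant,
    )


def rarefaction(
    gene_hits: list[str],
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Mean cumulative number of distinct genes vs mutants added.

    ``gene_hits`` lists one gene id per mutant in arbitrary order (the
    INTERGENIC marker contributes no gene). The curve averages, over
    ``n_permutations`` random orderings, the number of distinct genes among
    the first k mutants; entry k-1 is the value at k mutants. The curve is
    nondecreasing and ends at the total number of distinct genes hit.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(gene_hits)
    if n == 0:
        return np.zeros(0)
    codes, _ = pd.factorize(np.asarray(gene_hits, dtype=object))
    is_gene = np.asarray([g != INTERGENIC for g in gene_hits])
    acc = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        c = codes[order]
        first = np.zeros(n, dtype=bool)
        _, first_idx = np.unique(c, return_index=True)
        first[first_idx] = True
        acc += np.cumsum(first & is_gene[order])
    return acc / n_permutations


def zero_insertion_genes(table: GeneHitTable, annotation: GenomeAnnotation) -> set[str]:
    """Genes with no recovered insertions: the candidate essential set."""
    hit = set(table.gene_counts.index[table.gene_counts > 0])
    return set(annotation.gene_ids) - hit


def pathway_essentiality_enrichment(
    zero_set: set[str],
    annotation: GenomeAnnotation,
    B: int = DEFAULT_B,
    min_count: int | None = DEFAULT_MIN_COUNT,
    seed: int = 0,
    direction_background: str = "annotated",
) -> list[EnrichmentResult]:
    """Per-pathway chi-square of zero-insertion genes vs the genome background.

    For each pathway the 2x2 table contrasts zero-insertion membership inside
    vs outside the pathway; a pathway whose zero-insertion fraction exceeds
    the baseline is called essential, otherwise nonessential. Pathways
    smaller than ``min_count`` genes are excluded before testing.

    ``direction_background`` picks the baseline for the essential call:
    "annotated" (default) uses the zero-insertion rate among
    pathway-annotated genes only, "genome" the genome-wide rate. Annotated
    genes skew toward well-characterized core functions whose zero-insertion
    rate can sit well below the genome-wide one, and pathways between the
    two rates flip label depending on this choice.
    """
    sizes = annotation.pathway_sizes()
    if sizes.empty:
        return []
    zero_in_path = {
        p: sum(1 for g in zero_set if p in annotation.pathway_labels.get(g, ()))
        for p in sizes.index
    }
    counts = pd.DataFrame(
        {"a": pd.Series(zero_in_path), "n_path": sizes}
    )
    if direction_background == "annotated":
        annotated = [g for g, labels in annotation.pathway_labels.items() if labels]
        rate = (
            sum(1 for g in annotated if g in zero_set) / len(annotated) if annotated else 0.0
        )
    elif direction_background == "genome":
        rate = None
    else:
        raise ValueError(f"unknown direction_background {direction_background!r}")
    return enrichment_scan(
        counts,
        focal_total=len(zero_set),
        universe_total=annotation.n_genes,
        B=B,
        min_count=min_count,
        min_count_on="n_path",
        directions=("essential", "nonessential"),
        seed=seed,
        background_rate=rate,
    )
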