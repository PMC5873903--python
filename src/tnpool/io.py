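"""Readers and writers for the pipeline's tabular formats.

Everything is plain text: TSV for designs, read counts, libraries, panels
and results; GFF3 for gene annotations. Site keys serialize as
``contig:position:strand``. Output TSVs carry a header comment recording
the package version and the writing function's parameters.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decode import DecodedLibrary, ReadCountMatrix
from .design import (
    PoolingDesign,
    codeword_to_string,
    string_to_codeword,
    well_index,
    well_name,
)
from .synth import GenomeAnnotation, LoadTable, StrainPanel, TrueLibrary

__all__ = [
    "write_design",
    "read_design",
    "write_counts",
    "read_counts",
    "write_annotation_gff3",
    "write_annotation_tsv",
    "read_annotation",
    "write_decoded",
    "write_library",
    "write_strain_panel",
    "read_strain_panel",
    "read_orthomcl_groups",
    "write_load_table",
    "read_load_table",
]


def _write_tsv(df: pd.DataFrame, path: str | Path, comment: str, index: bool = False) -> None:
    buf = _io.StringIO()
    buf.write(f"# tnpool {__version__}: {comment}\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def parse_site(key: str) -> tuple[str, int, str]:
    contig, pos, strand = key.rsplit(":", 2)
    return contig, int(pos), strand


# -- pooling design ---------------------------------------------------------

def write_design(design: PoolingDesign, path: str | Path) -> None:
    rows = [
        dict(plate=plate, well=well_name(well), codeword=codeword_to_string(cw, design.n_pools))
        for (plate, well), cw in sorted(design.assignments.items())
    ]
    _write_tsv(
        pd.DataFrame(rows),
        path,
        f"pooling design, n_pools={design.n_pools}, "
        f"weights={sorted(design.allowed_weights)}, batch_size={design.batch_size_plates}",
    )


def read_design(path: str | Path, batch_size_plates: int = 5) -> PoolingDesign:
    df = _read_tsv(path, dtype={"codeword": str})
    n_pools = len(df["codeword"].iloc[0])
    assignments = {
        (int(r.plate), well_index(r.well)): string_to_codeword(r.codeword)
        for r in df.itertuples()
    }
    weights = frozenset(int(cw).bit_count() for cw in assignments.values())
    return PoolingDesign(
        n_pools=n_pools,
        allowed_weights=weights,
        assignments=assignments,
        batch_size_plates=batch_size_plates,
    )


# -- read counts ------------------------------------------------------------

def write_counts(matrix: ReadCountMatrix, path: str | Path) -> None:
    _write_tsv(matrix.to_frame(), path, "per-site per-pool read counts", index=True)


def read_counts(path: str | Path) -> ReadCountMatrix:
    df = _read_tsv(path, index_col=0)
    sites = [parse_site(k) for k in df.index]
    return ReadCountMatrix(sites=sites, counts=df.to_numpy(dtype=np.int64))


# -- genome annotation ------------------------------------------------------

def write_annotation_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for contig, length in annotation.contig_lengths.items():
        lines.append(f"##sequence-region {contig} 1 {length}")
    for r in annotation.genes.itertuples():
        pathways = sorted(annotation.pathway_labels.get(r.gene_id, ()))
        attrs = f"ID={r.gene_id}"
        if pathways:
            attrs += f";Ontology_term={','.join(pathways)}"
        lines.append(
            "\t".join(
                [r.contig, "tnpool", "gene", str(r.start), str(r.end), ".", r.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = annotation.genes.copy()
    df["pathways"] = [
        ",".join(sorted(annotation.pathway_labels.get(g, ()))) for g in df["gene_id"]
    ]
    df["contig_length"] = df["contig"].map(annotation.contig_lengths)
    _write_tsv(df, path, "gene annotation with pathway labels")


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read an annotation from the TSV written by :func:`write_annotation_tsv`."""
    df = _read_tsv(path, dtype={"pathways": str})
    labels = {
        r.gene_id: set(str(r.pathways).split(","))
        for r in df.itertuples()
        if isinstance(r.pathways, str) and r.pathways
    }
    contig_lengths = (
        df.drop_duplicates("contig").set_index("contig")["contig_length"].astype(int).to_dict()
    )
    return GenomeAnnotation(
        genes=df[["gene_id", "contig", "start", "end", "strand"]].reset_index(drop=True),
        pathway_labels=labels,
        contig_lengths=contig_lengths,
    )


# -- libraries --------------------------------------------------------------

def write_library(library: TrueLibrary, path: str | Path) -> None:
    _write_tsv(library.to_frame(), path, "ground-truth arrayed library")


def write_decoded(decoded: DecodedLibrary, path: str | Path, n_pools: int = 24) -> None:
    df = decoded.to_frame(n_pools)
    df["well"] = [well_name(int(w)) if pd.notna(w) else "" for w in df["well"]]
    _write_tsv(df, path, "decoded library (site, barcode, weight, status, plate, well)")


# -- strain panel / phenotypes ----------------------------------------------

def write_strain_panel(panel: StrainPanel, presence_path: str | Path, phenotype_path: str | Path) -> None:
    _write_tsv(
        panel.og_presence.rename_axis("strain_id"),
        presence_path,
        "OG presence/absence (strains x OGs)",
        index=True,
    )
    _write_tsv(panel.phenotypes, phenotype_path, "replicate CFU phenotypes")


def read_strain_panel(presence_path: str | Path, phenotype_path: str | Path) -> StrainPanel:
    presence = _read_tsv(presence_path, index_col=0)
    phenotypes = _read_tsv(phenotype_path)
    return StrainPanel(og_presence=presence, phenotypes=phenotypes)


def read_orthomcl_groups(path: str | Path, strains: list[str] | None = None) -> pd.DataFrame:
    """Presence/absence matrix from an OrthoMCL-style groups file.

    Lines look like ``OG_name: strainA|gene1 strainB|gene2 ...``; presence of
    any member gene marks the strain as carrying the OG.
    """
    presence: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, members = line.partition(":")
        carried = {m.split("|")[0] for m in members.split() if m}
        presence[name.strip()] = carried
    all_strains = strains or sorted({s for c in presence.values() for s in c})
    return pd.DataFrame(
        {og: [int(s in carried) for s in all_strains] for og, carried in presence.items()},
        index=pd.Index(all_strains, name="strain_id"),
    )


# -- load tables -------------------------------------------------------------

def write_load_table(loads: LoadTable, path: str | Path) -> None:
    _write_tsv(loads.rows, path, f"CFU loads, control={loads.control_treatment}")


def read_load_table(path: str | Path, control: str) -> LoadTable:
    return LoadTable(rows=_read_tsv(path), control_treatment=control)
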