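"""Decode pooled-sequencing read counts back to well positions.

For every insertion site, per-pool read counts are thresholded into a
presence barcode (>=50 reads by default), the barcode is classified by its
pool weight, and barcodes with an allowed weight are matched exactly
against the pooling design:

* weight in the allowed set (10/12/14 by default) -> candidate for matching;
* weight 1-2 -> spurious signal, most plausibly a sequencing artifact;
* weight 0, 3-9, or in the gaps between allowed weights -> pool dropout /
  insufficient coverage;
* weight above the allowed maximum -> suspected sister clones (two wells
  sharing one insertion site, whose pool patterns union).

Because allowed weights differ by 2 and a single dropout changes the weight
by 1, any single-pool error is detectable: the site is set aside instead of
being silently mapped to the wrong well. No nearest-codeword rescue is
performed by default; ``rescue_distance=1`` enables it for designs with
minimum pairwise Hamming distance >= 4 (an extension beyond plain
discard-on-mismatch decoding).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .design import PoolingDesign, codeword_to_string

__all__ = [
    "Site",
    "Status",
    "ReadCountMatrix",
    "DecodeRecord",
    "DecodedLibrary",
    "call_presence",
    "classify_barcode",
    "match_barcode",
    "decode_library",
    "pool_count_histogram",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 50

Site = tuple[str, int, str]  # (contig, 1-based position, strand)


class Status(str, Enum):
    MAPPED = "MAPPED"
    LOW_COVERAGE = "LOW_COVERAGE"
    SEQUENCING_ERROR = "SEQUENCING_ERROR"
    SISTER_CLONE_SUSPECT = "SISTER_CLONE_SUSPECT"
    UNMATCHED = "UNMATCHED"

    def __str__(self) -> str:  # plain value in TSV output
        return self.value


CANDIDATE = "CANDIDATE"


@dataclass(frozen=True)
class ReadCountMatrix:
    """Insertion sites x sequencing pools, non-negative read counts."""

    sites: list[Site]
    counts: np.ndarray  # shape (n_sites, n_pools), int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != len(self.sites):
            raise ValueError(
                f"counts shape {counts.shape} does not match {len(self.sites)} sites"
            )
        if counts.size and counts.min() < 0:
            raise ValueError("read counts must be non-negative")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site keys must be unique")

    @property
    def n_pools(self) -> int:
        return int(np.asarray(self.counts).shape[1])

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{c}:{p}:{s}" for c, p, s in self.sites]
        cols = [f"pool_{i + 1:02d}" for i in range(self.n_pools)]
        return pd.DataFrame(np.asarray(self.counts), index=idx, columns=cols).rename_axis("site")


@dataclass(frozen=True)
class DecodeRecord:
    site: Site
    barcode: int
    weight: int
    status: Status
    assigned: tuple[int, int] | None = None  # (plate, well) iff MAPPED

    def __post_init__(self) -> None:
        if (self.assigned is not None) != (self.status is Status.MAPPED):
            raise ValueError("assigned well present iff status is MAPPED")


@dataclass(frozen=True)
class DecodedLibrary:
    records: list[DecodeRecord]
    summary: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = Counter(r.status.value for r in self.records)
        object.__setattr__(self, "summary", {s.value: counts.get(s.value, 0) for s in Status})

    @property
    def mapped_count(self) -> int:
        return self.summary[Status.MAPPED.value]

    def to_frame(self, n_pools: int = 24) -> pd.DataFrame:
        rows = []
        for r in self.records:
            contig, pos, strand = r.site
            plate, well = r.assigned if r.assigned else (None, None)
            rows.append(
                dict(
                    contig=contig,
                    position=pos,
                    strand=strand,
                    barcode=codeword_to_string(r.barcode, n_pools),
                    weight=r.weight,
                    status=r.status.value,
                    plate=plate,
                    well=well,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["contig", "position", "strand", "barcode", "weight", "status", "plate", "well"],
        )


def call_presence(count_row: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> int:
    """Threshold one site's per-pool counts into a presence barcode.

    Bit i of the result is 1 iff ``count_row[i] >= threshold``. The boundary
    count (exactly ``threshold`` reads) calls presence.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    row = np.asarray(count_row)
    return int(sum(1 << i for i in np.nonzero(row >= threshold)[0]))


def classify_barcode(
    barcode: int, allowed_weights: frozenset[int] | set[int] = frozenset({10, 12, 14})
) -> str:
    """Pre-match classification of a presence barcode by pool weight."""
    w = int(barcode).bit_count()
    lo, hi = min(allowed_weights), max(allowed_weights)
    if w in allowed_weights:
        return CANDIDATE
    if w > hi:
        return Status.SISTER_CLONE_SUSPECT.value
    if w in (1, 2) and w < lo:
        return Status.SEQUENCING_ERROR.value
    return Status.LOW_COVERAGE.value  # weight 0, 3..lo-1, or gaps between weights


def match_barcode(barcode: int, design: PoolingDesign) -> tuple[int, int] | None:
    """Exact codeword match to a well; None when absent from the design."""
    if design.has_duplicates:
        raise ValueError("design contains duplicate codewords; decoding is ambiguous")
    return design.lookup(barcode)


def decode_library(
    matrix: ReadCountMatrix,
    design: PoolingDesign,
    threshold: int = DEFAULT_THRESHOLD,
    rescue_distance: int = 0,
) -> DecodedLibrary:
    """Threshold, classify and match every site of a read-count matrix.

    Sites with allowed-weight barcodes that match a design codeword exactly
    are MAPPED; allowed-weight barcodes absent from the design are
    UNMATCHED. Two sites decoding to the same well are both demoted to
    UNMATCHED (conservative handling of duplicate insertion sites). With
    ``rescue_distance=1`` an unmatched candidate is mapped to the unique
    codeword within Hamming distance 1, if any (requires design minimum
    distance >= 4 to be safe).
    """
    if matrix.n_pools != design.n_pools:
        raise ValueError(
            f"matrix has {matrix.n_pools} pools but design has {design.n_pools}"
        )
    counts = np.asarray(matrix.counts)
    codebook = design.codewords() if rescue_distance else None

    prelim: list[tuple[Site, int, int, str, tuple[int, int] | None]] = []
    for site, row in zip(matrix.sites, counts):
        barcode = call_presence(row, threshold)
        weight = barcode.bit_count()
        cls = classify_barcode(barcode, design.allowed_weights)
        assigned = None
        if cls == CANDIDATE:
            assigned = match_barcode(barcode, design)
            if assigned is None and rescue_distance:
                near = np.nonzero(
                    np.bitwise_count(codebook ^ np.uint32(barcode)) <= rescue_distance
                )[0]
                if len(near) == 1:
                    assigned = design.lookup(int(codebook[near[0]]))
            cls = Status.MAPPED.value if assigned is not None else Status.UNMATCHED.value
        prelim.append((site, barcode, weight, cls, assigned))

    well_claims = Counter(a for *_, a in prelim if a is not None)
    records = []
    for site, barcode, weight, cls, assigned in prelim:
        if assigned is not None and well_claims[assigned] > 1:
            logger.warning(
                "well %s claimed by %d sites; demoting site %s to UNMATCHED",
                assigned, well_claims[assigned], site,
            )
            cls, assigned = Status.UNMATCHED.value, None
        records.append(
            DecodeRecord(site=site, barcode=barcode, weight=weight, status=Status(cls), assigned=assigned)
        )
    return DecodedLibrary(records=records)


def pool_count_histogram(decoded: DecodedLibrary, n_pools: int = 24) -> np.ndarray:
    """Histogram of barcode weights over sites (bins 0..n_pools inclusive)."""
    weights = np.fromiter((r.weight for r in decoded.records), dtype=int, count=len(decoded.records))
    return np.bincount(weights, minlength=n_pools + 1)
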