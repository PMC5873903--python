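"""Combinatorial pooling designs for arrayed mutant libraries.

Each well of each 96-well plate receives a binary codeword over the
sequencing pools: the mutant from that well is pipetted into exactly the
pools whose bit is 1. Codewords are constant-weight (weights restricted to
a small set, by default {10, 12, 14} over 24 pools) so that any single
pool dropout changes the weight to a value outside the allowed set and is
therefore detectable rather than silently mis-decoded.

Codewords are represented as Python ints with bit ``i`` standing for pool
``i`` (0-based); the TSV serialization writes a 24-character 0/1 string
whose leftmost character is pool 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoolingDesign",
    "BatchPlan",
    "DesignReport",
    "CapacityError",
    "capacity",
    "build_design",
    "batch_plan",
    "validate_design",
    "well_name",
    "well_index",
    "codeword_to_string",
    "string_to_codeword",
]

WELLS_PER_PLATE = 96
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


class CapacityError(ValueError):
    """Requested design exceeds the capacity of the codeword space."""


def well_name(index: int) -> str:
    """Map a 0-95 well index to its plate label (row-major A1..H12)."""
    if not 0 <= index < WELLS_PER_PLATE:
        raise ValueError(f"well index {index} outside 0..95")
    return f"{PLATE_ROWS[index // PLATE_COLS]}{index % PLATE_COLS + 1}"


def well_index(name: str) -> int:
    """Inverse of :func:`well_name` (accepts A1 or A01 styles)."""
    row = PLATE_ROWS.index(name[0].upper())
    col = int(name[1:])
    if not 1 <= col <= PLATE_COLS:
        raise ValueError(f"column {col} outside 1..12 in well {name!r}")
    return row * PLATE_COLS + (col - 1)


def codeword_to_string(codeword: int, n_pools: int) -> str:
    return "".join("1" if codeword >> i & 1 else "0" for i in range(n_pools))


def string_to_codeword(s: str) -> int:
    if set(s) - {"0", "1"}:
        raise ValueError(f"codeword string {s!r} contains non-binary characters")
    return sum(1 << i for i, c in enumerate(s) if c == "1")


def capacity(n_pools: int, weights: set[int] | frozenset[int]) -> int:
    """Number of distinct codewords of length ``n_pools`` with weight in ``weights``.

    This is the unconstrained ceiling on library size: sum over the allowed
    weights w of C(n_pools, w).
    """
    for w in weights:
        if not 0 <= w <= n_pools:
            raise ValueError(f"weight {w} outside 0..{n_pools}")
    return sum(math.comb(n_pools, w) for w in set(weights))


@dataclass(frozen=True)
class PoolingDesign:
    """Bijection (plate, well) <-> codeword, plus the batch plan parameters.

    ``assignments`` maps ``(plate, well_index)`` with plates numbered from 1
    and wells 0..95 in row-major A1..H12 order.
    """

    n_pools: int
    allowed_weights: frozenset[int]
    assignments: dict[tuple[int, int], int]
    batch_size_plates: int = 5
    _lookup: dict[int, tuple[int, int]] = field(init=False, repr=False, compare=False)
    # duplicate assignment is tolerated at construction (validate_design
    # reports it; the decoder refuses to match against such a design)
    has_duplicates: bool = field(init=False, repr=False, compare=False, default=False)

    def __post_init__(self) -> None:
        lookup: dict[int, tuple[int, int]] = {}
        for key, cw in self.assignments.items():
            if cw in lookup:
                object.__setattr__(self, "has_duplicates", True)
            else:
                lookup[cw] = key
        object.__setattr__(self, "_lookup", lookup)

    @property
    def n_plates(self) -> int:
        return max((p for p, _ in self.assignments), default=0)

    def assign(self, plate: int, well: int) -> int:
        return self.assignments[(plate, well)]

    def lookup(self, codeword: int) -> tuple[int, int] | None:
        """Return the (plate, well) owning ``codeword``, or None."""
        return self._lookup.get(codeword)

    def codewords(self) -> np.ndarray:
        """All assigned codewords as a uint32 array (assignment order)."""
        return np.fromiter(self.assignments.values(), dtype=np.uint32)


@dataclass(frozen=True)
class BatchPlan:
    """Two-stage pooling plan: intermediate pools per plate batch, then a merge.

    ``batches[b]`` is ``(plate_ids, instructions)`` where ``instructions[p]``
    lists the (plate, well_index) pairs pipetted into intermediate pool ``p``
    of batch ``b``. ``final_merge[p]`` lists the (batch, pool) intermediate
    pools combined into final pool ``p``.
    """

    batches: list[tuple[list[int], list[list[tuple[int, int]]]]]
    final_merge: list[list[tuple[int, int]]]


@dataclass(frozen=True)
class DesignReport:
    duplicate_codewords: list[tuple[tuple[int, int], tuple[int, int]]]
    weight_violations: list[tuple[tuple[int, int], int]]
    subset_pairs: list[tuple[tuple[int, int], tuple[int, int]]]
    min_hamming_distance: int | None

    @property
    def is_clean(self) -> bool:
        return not (self.duplicate_codewords or self.weight_violations or self.subset_pairs)


def _constant_weight_codewords(n_pools: int, weight: int):
    """Yield all weight-``weight`` codewords of ``n_pools`` bits in colex order.

    Gosper's hack: enumerates same-popcount ints in increasing numeric order,
    which for constant weight is colexicographic order of the support sets.
    """
    if weight == 0:
        yield 0
        return
    v = (1 << weight) - 1
    limit = 1 << n_pools
    while v < limit:
        yield v
        c = v & -v
        r = v + c
        v = (((r ^ v) >> 2) // c) | r


def build_design(
    n_plates: int,
    wells_per_plate: int = WELLS_PER_PLATE,
    n_pools: int = 24,
    weights: set[int] = frozenset({10, 12, 14}),
    subset_free: bool = False,
    min_distance: int | None = None,
    seed: int = 0,
    batch_size_plates: int = 5,
) -> PoolingDesign:
    """Construct a pooling design for ``n_plates`` plates.

    Codewords are enumerated per weight class in colexicographic order and the
    classes interleaved round-robin, optionally rejecting candidates that are
    a bitwise subset/superset of an accepted codeword (``subset_free``) or
    closer than ``min_distance`` in Hamming distance to one. The ``seed``
    selects a random permutation of pool positions applied uniformly to the
    whole codebook, giving reproducibly distinct but isomorphic designs.

    Raises
    ------
    CapacityError
        If the request exceeds the unconstrained capacity, or the filters
        exhaust the codeword space first (the message names the constraint).
    """
    n_needed = n_plates * wells_per_plate
    cap = capacity(n_pools, weights)
    if n_needed > cap:
        raise CapacityError(
            f"{n_needed} wells requested but capacity({n_pools}, {sorted(weights)}) = {cap}"
        )

    gens = [_constant_weight_codewords(n_pools, w) for w in sorted(weights)]
    accepted: list[int] = []
    acc_arr = np.zeros(n_needed, dtype=np.uint32)  # parallel to `accepted`
    exhausted = [False] * len(gens)
    gi = 0
    while len(accepted) < n_needed:
        if all(exhausted):
            constraint = "subset_free" if subset_free else f"min_distance={min_distance}"
            raise CapacityError(
                f"codeword space exhausted after {len(accepted)} of {n_needed} "
                f"wells under constraint {constraint}"
            )
        g = gens[gi % len(gens)]
        gi += 1
        if exhausted[(gi - 1) % len(gens)]:
            continue
        for cand in g:
            view = acc_arr[: len(accepted)]
            if subset_free:
                inter = view & np.uint32(cand)
                if np.any((inter == cand) | (inter == view)):
                    continue
            if min_distance is not None and len(accepted):
                dist = np.bitwise_count(view ^ np.uint32(cand))
                if dist.min() < min_distance:
                    continue
            acc_arr[len(accepted)] = cand
            accepted.append(cand)
            break
        else:
            exhausted[(gi - 1) % len(gens)] = True

    perm = np.random.default_rng(seed).permutation(n_pools)
    permuted = [sum(((cw >> i) & 1) << int(perm[i]) for i in range(n_pools)) for cw in accepted]

    assignments = {
        (plate, well): permuted[(plate - 1) * wells_per_plate + well]
        for plate in range(1, n_plates + 1)
        for well in range(wells_per_plate)
    }
    return PoolingDesign(
        n_pools=n_pools,
        allowed_weights=frozenset(weights),
        assignments=assignments,
        batch_size_plates=batch_size_plates,
    )


def batch_plan(design: PoolingDesign) -> BatchPlan:
    """Derive the two-stage pipetting plan from a design.

    Plates are grouped ``batch_size_plates`` at a time into intermediate sets
    of ``n_pools`` pools; the final pools merge all intermediate pools at the
    same position.
    """
    plates = sorted({p for p, _ in design.assignments})
    bs = design.batch_size_plates
    batches = []
    for b in range(0, len(plates), bs):
        batch_plates = plates[b : b + bs]
        instructions: list[list[tuple[int, int]]] = [[] for _ in range(design.n_pools)]
        for (plate, well), cw in design.assignments.items():
            if plate in batch_plates:
                for pool in range(design.n_pools):
                    if cw >> pool & 1:
                        instructions[pool].append((plate, well))
        batches.append((batch_plates, instructions))
    final_merge = [
        [(b, pool) for b in range(len(batches))] for pool in range(design.n_pools)
    ]
    return BatchPlan(batches=batches, final_merge=final_merge)


def validate_design(design: PoolingDesign) -> DesignReport:
    """Report-only integrity check: duplicates, weight violations, subset
    pairs, and the minimum pairwise Hamming distance."""
    items = list(design.assignments.items())
    seen: dict[int, tuple[int, int]] = {}
    duplicates = []
    for key, cw in items:
        if cw in seen:
            duplicates.append((seen[cw], key))
        else:
            seen[cw] = key
    weight_violations = [
        (key, w)
        for key, cw in items
        if (w := int(cw).bit_count()) not in design.allowed_weights
    ]
    subset_pairs = []
    min_dist: int | None = None
    if len(items) > 1:
        keys = [k for k, _ in items]
        arr = np.array([cw for _, cw in items], dtype=np.uint32)
        min_dist = int(design.n_pools)
        for i in range(len(arr) - 1):
            rest = arr[i + 1 :]
            inter = rest & arr[i]
            sub = np.nonzero((inter == arr[i]) | (inter == rest))[0]
            for j in sub:
                if rest[j] != arr[i]:
                    subset_pairs.append((keys[i], keys[i + 1 + int(j)]))
            d = np.bitwise_count(rest ^ arr[i])
            nz = d[d > 0]
            if nz.size:
                min_dist = min(min_dist, int(nz.min()))
    return DesignReport(
        duplicate_codewords=duplicates,
        weight_violations=weight_violations,
        subset_pairs=subset_pairs,
        min_hamming_distance=min_dist,
    )
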