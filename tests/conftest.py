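import numpy as np
import pytest
from hypothesis import settings

import tnpool as tp

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_design() -> tp.PoolingDesign:
    """Two plates, default 24-pool weights {10,12,14}."""
    return tp.build_design(n_plates=2, seed=11)


@pytest.fixture(scope="session")
def annotation() -> tp.GenomeAnnotation:
    return tp.gen_annotation(
        n_genes=200,
        genome_length=400_000,
        pathway_sizes={"ko00001": 20, "ko00002": 30, "ko00003": 12},
        seed=7,
    )


@pytest.fixture(scope="session")
def library(annotation) -> tp.TrueLibrary:
    essential = set(annotation.gene_ids[:20])
    return tp.gen_library(
        annotation,
        n_mutants=180,
        essential_genes=essential,
        intergenic_fraction=0.15,
        sister_clone_rate=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def clean_matrix(library, small_design) -> tp.ReadCountMatrix:
    """Noiseless pooled reads: Poisson depth, no dropout, no background."""
    return tp.gen_pool_reads(
        library, small_design, mean_depth=200, dropout_p=0.0,
        noise_mean=0.0, dispersion=0.0, spurious_site_rate=0.0, seed=17,
    )


@pytest.fixture(scope="session")
def decoded(clean_matrix, small_design) -> tp.DecodedLibrary:
    return tp.decode_library(clean_matrix, small_design)


def brute_force_min_distance(codewords: list[int]) -> int:
    """O(n^2) oracle for the minimum pairwise Hamming distance."""
    best = None
    for i in range(len(codewords)):
        for j in range(i + 1, len(codewords)):
            d = (codewords[i] ^ codewords[j]).bit_count()
            if best is None or d < best:
                best = d
    return best


def brute_force_subset_pairs(codewords: list[int]) -> list[tuple[int, int]]:
    """O(n^2) oracle for strict bitwise subset pairs."""
    pairs = []
    for i in range(len(codewords)):
        for j in range(len(codewords)):
            if i != j and codewords[i] != codewords[j]:
                if codewords[i] & codewords[j] == codewords[i]:
                    pairs.append((i, j))
    return pairs
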