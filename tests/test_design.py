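"""Pooling-design construction, validation and batch planning."""

import itertools
import math

import numpy as np
import pytest

import tnpool as tp
from tnpool.design import (
    CapacityError,
    codeword_to_string,
    string_to_codeword,
    well_index,
    well_name,
)

from conftest import brute_force_min_distance, brute_force_subset_pairs


class TestCapacity:
    def test_single_full_codeword(self):
        assert tp.capacity(4, {4}) == 1

    def test_zero_weight(self):
        assert tp.capacity(24, {0}) == 1

    def test_default_code_space(self):
        # oracle: exact sum of binomial coefficients in integer arithmetic
        expected = sum(math.comb(24, w) for w in (10, 12, 14))
        assert tp.capacity(24, {10, 12, 14}) == expected == 6_626_668

    @pytest.mark.parametrize("n_pools,weights", [(8, {2, 3}), (6, {1, 5}), (5, {0, 5})])
    def test_matches_exhaustive_enumeration(self, n_pools, weights):
        # independent oracle: literally enumerate the codewords
        count = sum(
            1
            for k in weights
            for _ in itertools.combinations(range(n_pools), k)
        )
        assert tp.capacity(n_pools, weights) == count

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            tp.capacity(4, {5})


class TestWellNaming:
    def test_row_major_corners(self):
        assert well_name(0) == "A1"
        assert well_name(11) == "A12"
        assert well_name(12) == "B1"
        assert well_name(95) == "H12"

    def test_roundtrip(self):
        for i in range(96):
            assert well_index(well_name(i)) == i


class TestBuildDesign:
    def test_all_weights_allowed(self, small_design):
        for cw in small_design.assignments.values():
            assert cw.bit_count() in {10, 12, 14}

    def test_bijectivity(self, small_design):
        # lookup o assign is the identity on wells
        for (plate, well), cw in small_design.assignments.items():
            assert small_design.lookup(cw) == (plate, well)

    def test_deterministic_given_seed(self):
        d1 = tp.build_design(n_plates=1, seed=5)
        d2 = tp.build_design(n_plates=1, seed=5)
        assert d1.assignments == d2.assignments
        d3 = tp.build_design(n_plates=1, seed=6)
        assert d1.assignments != d3.assignments

    def test_study_scale_succeeds(self):
        # 90 plates = 8,640 wells, enough for an 8,550-mutant library
        d = tp.build_design(n_plates=90, seed=0)
        assert len(d.assignments) == 8640
        assert len({*d.assignments.values()}) == 8640

    def test_over_capacity_rejected(self):
        with pytest.raises(CapacityError):
            tp.build_design(n_plates=2, n_pools=6, weights={3}, seed=0)

    def test_subset_free_verified_by_brute_force(self):
        d = tp.build_design(n_plates=1, subset_free=True, seed=3)
        assert brute_force_subset_pairs(list(d.assignments.values())) == []

    def test_min_distance_verified_by_brute_force(self):
        d = tp.build_design(n_plates=1, min_distance=4, seed=3)
        assert brute_force_min_distance(list(d.assignments.values())) >= 4

    def test_filters_can_exhaust_space(self):
        # tiny code space + aggressive distance filter -> named capacity error
        with pytest.raises(CapacityError, match="constraint"):
            tp.build_design(
                n_plates=1, wells_per_plate=60, n_pools=8, weights={3, 4},
                min_distance=4, seed=0,
            )

    def test_single_dropout_always_detectable(self, small_design):
        # weights differ by 2; losing one pool gives an odd weight outside
        # the allowed set -- checked exhaustively over all codewords and bits
        for cw in small_design.assignments.values():
            for bit in range(small_design.n_pools):
                if cw >> bit & 1:
                    assert (cw ^ (1 << bit)).bit_count() not in small_design.allowed_weights

    def test_double_dropout_cannot_hit_weight10_in_subset_free_design(self):
        # brute force: no assigned weight-12 codeword minus two bits equals
        # an assigned weight-10 codeword when subset-freeness is enforced
        d = tp.build_design(n_plates=1, subset_free=True, seed=9)
        by_weight = {}
        for cw in d.assignments.values():
            by_weight.setdefault(cw.bit_count(), set()).add(cw)
        for cw in by_weight.get(12, ()):
            bits = [b for b in range(d.n_pools) if cw >> b & 1]
            for b1, b2 in itertools.combinations(bits, 2):
                assert cw ^ (1 << b1) ^ (1 << b2) not in by_weight.get(10, set())


class TestBatchPlan:
    def test_five_plates_one_batch(self):
        d = tp.build_design(n_plates=5, seed=1)
        plan = tp.batch_plan(d)
        assert len(plan.batches) == 1

    def test_twelve_plates_three_batches(self):
        d = tp.build_design(n_plates=12, seed=1)
        plan = tp.batch_plan(d)
        assert [len(p) for p, _ in plan.batches] == [5, 5, 2]

    def test_pooling_roundtrip_recovers_codewords(self):
        # execute the plan: union of a well's intermediate-pool memberships,
        # merged through final_merge, must equal its codeword exactly
        d = tp.build_design(n_plates=7, seed=2)
        plan = tp.batch_plan(d)
        recovered: dict[tuple[int, int], int] = {}
        for b, (_, instructions) in enumerate(plan.batches):
            for pool, wells in enumerate(instructions):
                for key in wells:
                    # find which final pool this intermediate pool feeds
                    finals = [fp for fp, srcs in enumerate(plan.final_merge) if (b, pool) in srcs]
                    assert len(finals) == 1
                    recovered[key] = recovered.get(key, 0) | (1 << finals[0])
        assert recovered == d.assignments

    def test_every_plate_in_exactly_one_batch(self):
        d = tp.build_design(n_plates=11, seed=2)
        plan = tp.batch_plan(d)
        seen = [p for plates, _ in plan.batches for p in plates]
        assert sorted(seen) == list(range(1, 12))
        assert len(seen) == len(set(seen))


class TestValidateDesign:
    def test_clean_design(self):
        d = tp.build_design(n_plates=1, subset_free=True, seed=4)
        report = tp.validate_design(d)
        assert report.is_clean
        assert report.duplicate_codewords == []
        assert report.weight_violations == []
        assert report.subset_pairs == []

    def test_duplicate_codewords_reported(self):
        cw = string_to_codeword("1" * 10 + "0" * 14)
        d = tp.PoolingDesign(
            n_pools=24,
            allowed_weights=frozenset({10, 12, 14}),
            assignments={(1, 0): cw, (1, 1): cw},
        )
        report = tp.validate_design(d)
        assert report.duplicate_codewords == [((1, 0), (1, 1))]

    def test_weight_violation_reported(self):
        d = tp.PoolingDesign(
            n_pools=24,
            allowed_weights=frozenset({10, 12, 14}),
            assignments={(1, 0): string_to_codeword("111" + "0" * 21)},
        )
        report = tp.validate_design(d)
        assert report.weight_violations == [((1, 0), 3)]

    def test_min_distance_matches_brute_force(self):
        d = tp.build_design(n_plates=1, seed=8)
        report = tp.validate_design(d)
        assert report.min_hamming_distance == brute_force_min_distance(
            list(d.assignments.values())
        )

    def test_subset_pairs_match_brute_force_count(self):
        d = tp.build_design(n_plates=1, seed=8)
        report = tp.validate_design(d)
        oracle = brute_force_subset_pairs(list(d.assignments.values()))
        # subset is antisymmetric on distinct codewords: one ordered pair each
        assert len(report.subset_pairs) == len(oracle)


def test_codeword_string_roundtrip():
    s = "101000000001110000011011"
    assert codeword_to_string(string_to_codeword(s), 24) == s
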