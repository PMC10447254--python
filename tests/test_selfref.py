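import numpy as np
import pytest

from mtkit.selfref import (
    CoordinateMap,
    MtVariantCall,
    ReferenceSequence,
    build_consensus,
    lift_calls,
    lift_coverage,
    lift_position,
    shift_coordinate,
)

from conftest import apply_edits_bruteforce, random_homoplasmic_edits, random_reference


def call(pos, ref, alt, het=0.99, **kw):
    return MtVariantCall("ref", pos, ref, alt, het, **kw)


class TestBuildConsensus:
    def test_no_calls_gives_identity(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"), [])
        assert b.consensus.bases == "ACGT"
        assert b.map.blocks == [(0, 0, 4)]

    def test_snv_substitutes_without_length_change(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "T")])
        assert b.consensus.bases == "ATGT"
        assert b.map.blocks == [(0, 0, 4)]  # coordinates unchanged

    def test_insertion_splits_blocks(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "CA")])
        # oracle: brute-force string edit
        assert b.consensus.bases == apply_edits_bruteforce("ACGT", b.applied)
        assert b.consensus.bases == "ACAGT"
        assert b.map.cons_length == 5
        assert len(b.map.blocks) == 2

    def test_heteroplasmic_and_flagged_calls_skipped(self):
        b = build_consensus(
            ReferenceSequence("ref", "ACGT"),
            [call(2, "C", "T", het=0.5),
             call(3, "G", "A", filters={"weak_evidence"})])
        assert b.consensus.bases == "ACGT"
        reasons = {r for _, r in b.skipped}
        assert reasons == {"below_threshold", "caller_flag"}

    def test_overlapping_call_skipped_with_reason(self):
        b = build_consensus(ReferenceSequence("ref", "ACGTAC"),
                            [call(2, "CG", "C"), call(3, "G", "A")])
        assert [r for _, r in b.skipped] == ["overlap"]
        assert len(b.applied) == 1

    def test_ref_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="pos 2"):
            build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "G", "T")])

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(ReferenceSequence("ref", "ACGT"), [],
                            hom_threshold=0.4)


class TestLiftPosition:
    def test_identity_map(self):
        m = CoordinateMap.identity(100)
        assert lift_position(m, 17, "to_reference") == 17
        assert lift_position(m, 17, "to_consensus") == 17

    def test_inserted_base_lifts_to_left_anchor(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "CA")])
        assert lift_position(b.map, 3, "to_reference") == 2

    def test_deleted_base_has_no_consensus_image(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(1, "AC", "A")])
        assert b.consensus.bases == "AGT"
        assert lift_position(b.map, 2, "to_consensus") is None

    def test_out_of_range_errors(self):
        m = CoordinateMap.identity(10)
        with pytest.raises(ValueError):
            lift_position(m, 11, "to_consensus")

    def test_round_trip_identity_outside_indel_footprints(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ref = random_reference(rng)
            calls = random_homoplasmic_edits(rng, ref)
            b = build_consensus(ref, calls)
            footprint = set()
            for c in b.applied:
                footprint.update(range(c.pos, c.pos + len(c.ref_allele)))
            for pos in range(1, ref.length + 1):
                cp = lift_position(b.map, pos, "to_consensus")
                if pos in footprint:
                    continue
                assert cp is not None
                assert lift_position(b.map, cp, "to_reference") == pos

    def test_fuzzed_consensus_matches_bruteforce_editor(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ref = random_reference(rng)
            calls = random_homoplasmic_edits(rng, ref, n_edits=8)
            b = build_consensus(ref, calls)
            assert b.consensus.bases == apply_edits_bruteforce(ref.bases,
                                                               b.applied)


class TestLiftCalls:
    def test_identity_build_passes_call_through(self):
        ref = random_reference(np.random.default_rng(0), length=400)
        b = build_consensus(ref, [])
        c = MtVariantCall(ref.name, 302,
                          ref.bases[301], "ACGT"[("ACGT".index(ref.bases[301]) + 1) % 4],
                          0.2)
        lifted, rejects = lift_calls(b, [c])
        assert not rejects
        assert lifted[0].pos == 302
        assert lifted[0].heteroplasmy == 0.2

    def test_reversion_call_composes_to_flipped_fraction(self):
        # consensus has T where reference had C; a consensus call back to C
        # at fraction 0.3 means 0.7 of molecules carry T relative to reference
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "T")])
        lifted, rejects = lift_calls(
            b, [MtVariantCall("ref_consensus", 2, "T", "C", 0.3,
                              depth=100, alt_depth=30)])
        assert not rejects
        (lc,) = lifted
        assert (lc.pos, lc.ref_allele, lc.alt_allele) == (2, "C", "T")
        assert lc.heteroplasmy == pytest.approx(0.7)
        assert lc.alt_depth == 70

    def test_third_allele_at_edited_site(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "T")])
        lifted, _ = lift_calls(b, [MtVariantCall("c", 2, "T", "G", 0.25)])
        (lc,) = lifted
        assert (lc.pos, lc.ref_allele, lc.alt_allele) == (2, "C", "G")
        assert lc.heteroplasmy == pytest.approx(0.25)

    def test_call_at_inserted_base_becomes_length_variant(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "CA")])
        lifted, rejects = lift_calls(b, [MtVariantCall("c", 3, "A", "G", 0.3)])
        assert not rejects
        (lc,) = lifted
        assert lc.pos == 2
        assert (lc.ref_allele, lc.alt_allele) == ("C", "CG")

    def test_consensus_allele_mismatch_rejected_not_dropped(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"), [])
        lifted, rejects = lift_calls(b, [MtVariantCall("c", 2, "G", "A", 0.2)])
        assert lifted == []
        assert rejects[0][1] == "consensus_allele_mismatch"


class TestLiftCoverage:
    def test_identity(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"), [])
        assert lift_coverage(b, [5, 5, 5, 5]).tolist() == [5, 5, 5, 5]

    def test_deletion_inherits_left_anchor(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(1, "AC", "A")])
        assert lift_coverage(b, [7, 7, 7]).tolist() == [7, 7, 7, 7]

    def test_inserted_base_contributes_nothing(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"),
                            [call(2, "C", "CA")])
        assert lift_coverage(b, [3, 3, 9, 3, 3]).tolist() == [3, 3, 3, 3]

    def test_length_mismatch_errors(self):
        b = build_consensus(ReferenceSequence("ref", "ACGT"), [])
        with pytest.raises(ValueError):
            lift_coverage(b, [1, 2, 3])

    def test_coverage_mass_bookkeeping(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ref = random_reference(rng)
            b = build_consensus(ref, random_homoplasmic_edits(rng, ref))
            cov = rng.integers(0, 100, size=b.map.cons_length)
            out = lift_coverage(b, cov)
            mapped_cons = set()
            for _, c, n in b.map.blocks:
                mapped_cons.update(range(c, c + n))
            inserted = [i for i in range(b.map.cons_length)
                        if i not in mapped_cons]
            # anchor-copied mass: each deleted reference base receives the
            # value of the last consensus base mapped before the gap
            anchor_sum = 0
            prev_end_r, prev_anchor = 0, None
            for r, c, n in b.map.blocks:
                if r > prev_end_r and prev_anchor is not None:
                    anchor_sum += (r - prev_end_r) * cov[prev_anchor]
                prev_end_r, prev_anchor = r + n, c + n - 1
            if prev_end_r < b.map.ref_length and prev_anchor is not None:
                anchor_sum += (b.map.ref_length - prev_end_r) * cov[prev_anchor]
            assert out.sum() == cov.sum() - cov[inserted].sum() + anchor_sum


class TestShiftCoordinate:
    def test_stated_convention(self):
        assert shift_coordinate(1, 8000, 16569) == 8001

    def test_wraps_through_origin(self):
        assert shift_coordinate(8570, 8000, 16569) == 1

    def test_zero_shift_is_identity(self):
        assert shift_coordinate(123, 0, 16569) == 123

    def test_round_trip_all_positions(self):
        length, shift = 16569, 8000
        pos = np.arange(1, length + 1)
        orig = (pos - 1 + shift) % length + 1
        for p, o in zip(pos[::97], orig[::97]):
            assert shift_coordinate(int(p), shift, length, "to_original") == o
            assert shift_coordinate(int(o), shift, length, "to_shifted") == p

    def test_non_circular_rejected(self):
        with pytest.raises(ValueError):
            shift_coordinate(1, 10, 100, circular=False)
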