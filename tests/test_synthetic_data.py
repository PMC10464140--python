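"""Synthetic locus generation, engineered haplotypes, and read simulation."""

import numpy as np
import pytest

from paraloci.locus_model import Interval
from paraloci.synthetic_data import (
    DeletionSpec,
    LocusParams,
    ReadSimParams,
    apply_deletion,
    apply_transposition,
    generate_locus,
    simulate_depth_profile,
    simulate_reads,
    walk_fragments,
)


class TestGenerateLocus:
    def test_same_seed_is_byte_identical(self):
        l1, _ = generate_locus(LocusParams(seed=11))
        l2, _ = generate_locus(LocusParams(seed=11))
        assert l1.sequence == l2.sequence

    def test_different_seed_changes_sequence(self):
        l1, _ = generate_locus(LocusParams(seed=11))
        l2, _ = generate_locus(LocusParams(seed=12))
        assert l1.sequence != l2.sequence

    def test_planted_gene_body_substitution_count(self):
        # direct-scan oracle over the gene region at 94% identity
        params = LocusParams(seed=5, gene_len=10000)
        locus, truth = generate_locus(params)
        ly = truth.layout
        a = np.frombuffer(locus.sequence.encode(), np.uint8)
        g = ly.gene_region
        diffs = int(np.sum(a[g.start : g.end] != a[g.start + ly.delta : g.end + ly.delta]))
        assert diffs == round(0.06 * 10000) == 600

    def test_planted_long_segment_substitution_count(self, locus, truth):
        # 3000-nt segment at 96% identity carries exactly 120 differences
        ly = truth.layout
        a = np.frombuffer(locus.sequence.encode(), np.uint8)
        s = ly.seg_long
        diffs = int(np.sum(a[s.start : s.end] != a[s.start + ly.delta : s.end + ly.delta]))
        assert diffs == 120

    def test_psv_table_matches_direct_scan(self, locus, truth):
        ly = truth.layout
        a = np.frombuffer(locus.sequence.encode(), np.uint8)
        blk_a = a[ly.block_a.start : ly.block_a.end]
        blk_b = a[ly.block_b.start : ly.block_b.end]
        scan = np.flatnonzero(blk_a != blk_b) + ly.block_a.start
        assert truth.planted_psvs.pos_a.tolist() == scan.tolist()

    def test_crossover_tracts_are_psv_free(self, truth):
        for tract in truth.layout.tracts.values():
            assert len(truth.planted_psvs.indices_in_a(tract)) == 0

    def test_too_small_gene_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            LocusParams(seed=1, gene_len=1000)


class TestApplyTransposition:
    def test_ref_is_identity(self, locus):
        seq, tr = apply_transposition(locus, "REF")
        assert seq == locus.sequence
        assert tr.haplotype == "REF"

    def test_t30_flips_every_segment_psv(self, locus, truth):
        # direct scan of PSV bases before/after the segment replacement
        seq, _ = apply_transposition(locus, "T3_0")
        assert len(seq) == len(locus.sequence)
        seg = locus.haplotypes["T3_0"].acceptor_segment
        idx = truth.planted_psvs.indices_in_a(seg)
        assert len(idx) > 0
        for i in idx:
            psv = truth.planted_psvs[int(i)]
            assert seq[psv.pos_a] == psv.base_b
        outside = np.setdiff1d(np.arange(len(truth.planted_psvs)), idx)
        for i in outside[:50]:
            psv = truth.planted_psvs[int(i)]
            assert seq[psv.pos_a] == psv.base_a

    def test_t22_and_t30_differ_only_between_segment_ends(self, locus):
        # positionwise diff oracle
        s22, _ = apply_transposition(locus, "T2_2")
        s30, _ = apply_transposition(locus, "T3_0")
        short = locus.haplotypes["T2_2"].acceptor_segment
        long = locus.haplotypes["T3_0"].acceptor_segment
        diffs = [i for i in range(len(s22)) if s22[i] != s30[i]]
        assert diffs, "segment identities make the two haplotypes distinct"
        assert min(diffs) >= short.end
        assert max(diffs) < long.end

    def test_unknown_kind_rejected(self, locus):
        with pytest.raises(KeyError):
            apply_transposition(locus, "T9_9")


class TestApplyDeletion:
    def test_single_crossover_length_arithmetic(self, locus, truth):
        spec = truth.deletion_specs["A"]
        out, tr = apply_deletion(locus.sequence, spec, locus, seed=1)
        (cut,) = tr.crossovers
        q = cut + locus.frame_delta
        assert len(out) == len(locus.sequence) - (q - cut)

    def test_three_crossovers_match_hand_built_concatenation(self, locus, truth):
        # hand-built oracle: concatenate the four truth fragments directly
        spec = truth.deletion_specs["G"]
        out, tr = apply_deletion(locus.sequence, spec, locus, seed=2)
        assert tr.fragment_order == ["A", "C", "B", "D"]
        c1, c2, c3 = tr.crossovers
        d = locus.frame_delta
        s = locus.sequence
        oracle = s[:c1] + s[c1 + d : c2 + d] + s[c2:c3] + s[c3 + d :]
        assert out == oracle

    def test_deletion_spanning_segment_is_undetermined(self, locus, truth):
        out, tr = apply_deletion(locus.sequence, truth.deletion_specs["H"],
                                 locus, seed=3)
        assert tr.background == "UNDETERMINED"

    def test_background_follows_haploid(self, locus, truth):
        hap, tr0 = apply_transposition(locus, "T3_0")
        _, tr = apply_deletion(hap, truth.deletion_specs["E"], locus, seed=4,
                               truth_in=tr0)
        assert tr.background == "T3_0"

    def test_material_conservation(self, locus, truth):
        # no material invented: output length = input - total deleted span
        for label in "ABEGH":
            spec = truth.deletion_specs[label]
            out, tr = apply_deletion(locus.sequence, spec, locus, seed=5)
            deleted = sum(len(iv) for iv in tr.deleted_spans)
            assert len(out) == len(locus.sequence) - deleted

    def test_truth_crossovers_inside_their_tracts(self, locus, truth):
        for label, spec in truth.deletion_specs.items():
            for seed in (1, 2, 3):
                _, tr = apply_deletion(locus.sequence, spec, locus, seed=seed)
                for cut, tract in zip(tr.crossovers, spec.crossover_tracts):
                    assert tract.start <= cut < tract.end

    def test_inconsistent_fragment_order_rejected(self):
        with pytest.raises(ValueError, match="fragment_order inconsistent"):
            DeletionSpec("X", [Interval(10, 20)], "REF",
                         fragment_order=["A", "B", "C"])


class TestWalkFragments:
    def test_single_cut(self):
        order, frags, deleted = walk_fragments([100], delta=1000, locus_len=3000)
        assert order == ["A", "B"]
        assert deleted == [Interval(100, 1100)]

    def test_no_cut_is_reference(self):
        order, frags, deleted = walk_fragments([], delta=1000, locus_len=3000)
        assert order == ["A"] and deleted == []


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, locus):
        reads = simulate_reads((locus.sequence, locus.sequence),
                               ReadSimParams(seed=7, depth=2))
        from paraloci.synthetic_data import revcomp

        for r in reads:
            frag = locus.sequence[r.origin.start : r.origin.end]
            expected = frag if r.strand == "+" else revcomp(frag)
            assert r.sequence == expected

    def test_same_seed_identical_reads(self, locus):
        p = ReadSimParams(seed=8, depth=2, err_mismatch=0.01)
        r1 = simulate_reads((locus.sequence, locus.sequence), p)
        r2 = simulate_reads((locus.sequence, locus.sequence), p)
        assert [(a.read_id, a.sequence) for a in r1] == [
            (b.read_id, b.sequence) for b in r2
        ]

    def test_realized_depth_close_to_target(self, locus):
        p = ReadSimParams(seed=9, depth=30)
        reads = simulate_reads((locus.sequence, locus.sequence), p)
        emitted = sum(len(r.origin) for r in reads)
        realized = emitted / len(locus.sequence)
        assert abs(realized - 30) / 30 < 0.10

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="error rates"):
            ReadSimParams(seed=1, err_mismatch=0.3, err_ins=0.2, err_del=0.1)


class TestDepthProfileSimulation:
    def test_copy_signature(self, locus):
        hd = locus.haplotypes["T3_0"]
        for copies, exp_a, exp_b in [(0, 1.0, 1.0), (1, 0.5, 1.5), (2, 0.0, 2.0)]:
            windows = simulate_depth_profile(locus, copies, seed=copies + 1)
            a = np.mean([d for iv, d in windows if hd.acceptor_segment.overlaps(iv)])
            b = np.mean([d for iv, d in windows if hd.donor_segment.overlaps(iv)])
            assert a == pytest.approx(exp_a, abs=0.12)
            assert b == pytest.approx(exp_b, abs=0.15)
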