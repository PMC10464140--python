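"""Read classification, switch calling, consensus regions, and genotyping."""

import itertools

import pytest

from paraloci.breakpoint_caller import (
    BreakpointRegionCall,
    ReadPath,
    ReconstructionError,
    SiteCall,
    SwitchInterval,
    call_read_switches,
    classify_allele,
    classify_sites,
    merge_regions,
    place_read,
    reconstruct_allele,
)
from paraloci.locus_model import AlleleDefinition, Interval
from paraloci.synthetic_data import apply_transposition
from tests.conftest import call_scenario, engineer


def mk_sites(assignments, positions=None, frame="A"):
    positions = positions or [10 * (i + 1) for i in range(len(assignments))]
    return [
        SiteCall(psv_index=i, read_pos=i, pos_a=p, frame=frame,
                 observed_base="A", assignment=a)
        for i, (a, p) in enumerate(zip(assignments, positions))
    ]


def brute_force_switches(labels, k):
    """Independent oracle for the run rule: groups of >= k concordant
    informative sites seed runs; adjacent same-label runs merge; one switch
    between adjacent runs of different labels."""
    informative = [x for x in labels if x in "AB"]
    groups = [(lab, len(list(g))) for lab, g in itertools.groupby(informative)]
    seeds = [lab for lab, n in groups if n >= k]
    merged = [lab for lab, _ in itertools.groupby(seeds)]
    return len(merged) - 1 if merged else 0


class TestCallReadSwitches:
    def test_uniform_run_has_no_switch(self):
        path = call_read_switches(mk_sites("AAAAA"), min_run=3)
        assert path.switch_intervals == []
        assert [r[0] for r in path.runs] == ["A"]

    def test_single_switch_interval_is_the_site_gap(self):
        # A x5 then B x5 at positions 10..100: the unique decomposition has
        # one switch in the open gap between site 5 and site 6
        path = call_read_switches(mk_sites("AAAAABBBBB"), min_run=3)
        assert len(path.switch_intervals) == 1
        sw = path.switch_intervals[0]
        assert (sw.label_from, sw.label_to) == ("A", "B")
        assert (sw.interval.start, sw.interval.end) == (51, 60)

    def test_lone_opposite_site_cannot_seed_a_run(self):
        path = call_read_switches(mk_sites("AABAA"), min_run=2)
        assert path.switch_intervals == []

    def test_other_sites_are_skipped(self):
        labels = ["A", "A", "OTHER", "A", "A", "B", "B", "OTHER", "B", "B"]
        path = call_read_switches(mk_sites(labels), min_run=3)
        assert len(path.switch_intervals) == 1

    def test_too_few_informative_sites_is_undetermined(self):
        path = call_read_switches(mk_sites(["A", "OTHER"]), min_run=3)
        assert path.undetermined and path.switch_intervals == []

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_switch_count_matches_exhaustive_oracle(self, k):
        # enumerate every label sequence of length 6 over {A, B, OTHER}
        for labels in itertools.product(["A", "B", "OTHER"], repeat=6):
            path = call_read_switches(mk_sites(list(labels)), min_run=k)
            assert len(path.switch_intervals) == brute_force_switches(labels, k), labels

    def test_frame_split_prevents_cross_copy_switches(self):
        # a read spanning both gene copies of the reference: concordant in
        # each frame, so no switch may be emitted
        sites = mk_sites("AAAA", positions=[10, 20, 30, 40], frame="A") + mk_sites(
            "BBBB", positions=[50, 60, 70, 80], frame="B"
        )
        for i, s in enumerate(sites):
            sites[i] = SiteCall(s.psv_index, i, s.pos_a, s.frame,
                                s.observed_base, s.assignment)
        path = call_read_switches(sites, min_run=3)
        assert path.switch_intervals == []

    def test_min_run_must_be_positive(self):
        with pytest.raises(ValueError):
            call_read_switches(mk_sites("AAA"), min_run=0)


def mk_path(intervals, read_id="r"):
    return ReadPath(
        read_id=read_id,
        runs=[],
        switch_intervals=[
            SwitchInterval("A", "B", Interval(s, e)) for s, e in intervals
        ],
    )


class TestMergeRegions:
    def test_identical_intervals_merge_with_support(self):
        paths = [mk_path([(100, 200)], f"r{i}") for i in range(2)]
        calls = merge_regions(paths, min_support=2)
        assert len(calls) == 1
        assert calls[0].n_support == 2
        assert (calls[0].region_a.start, calls[0].region_a.end) == (100, 200)

    def test_overlap_merges_by_intersection(self):
        paths = [mk_path([(100, 200)]), mk_path([(150, 400)]),
                 mk_path([(120, 260)])]
        calls = merge_regions(paths, min_support=3)
        assert len(calls) == 1
        assert (calls[0].region_a.start, calls[0].region_a.end) == (150, 200)

    def test_disjoint_intervals_stay_separate(self):
        paths = [mk_path([(100, 200)]) for _ in range(3)] + [
            mk_path([(500, 600)]) for _ in range(3)
        ]
        calls = merge_regions(paths, min_support=3)
        assert len(calls) == 2

    def test_min_support_filters(self):
        calls = merge_regions([mk_path([(100, 200)])], min_support=3)
        assert calls == []

    def test_boundary_noise_twin_absorbed(self):
        major = [mk_path([(100, 200)], f"m{i}") for i in range(20)]
        minor = [mk_path([(210, 240)], f"n{i}") for i in range(3)]
        calls = merge_regions(major + minor, min_support=3)
        assert len(calls) == 1
        assert calls[0].n_support == 20


def region(s, e, lf="A", lt="B", n=5):
    return BreakpointRegionCall(
        region_a=Interval(s, e),
        region_b=Interval(s + 1000, e + 1000),
        label_from=lf,
        label_to=lt,
        n_support=n,
    )


class TestReconstructAllele:
    def test_zero_regions_is_reference(self, locus):
        call = reconstruct_allele([], locus)
        assert call.is_reference and call.deleted_spans == []

    def test_single_region_deletes_between_frames(self, locus):
        r = region(12000, 12100)
        call = reconstruct_allele([r], locus)
        assert call.fragment_order == ["A", "B"]
        (span,) = call.deleted_spans
        assert span.start == 12000
        assert len(span) == locus.frame_delta

    def test_non_alternating_regions_rejected(self, locus):
        bad = [region(12000, 12100, "B", "A")]
        with pytest.raises(ReconstructionError):
            reconstruct_allele(bad, locus)
        bad2 = [region(12000, 12100), region(13000, 13100)]  # A->B twice
        with pytest.raises(ReconstructionError):
            reconstruct_allele(bad2, locus)


class TestClassifyAllele:
    @pytest.fixture()
    def catalog(self):
        return [
            AlleleDefinition("C", [Interval(1000, 1200)], ["A", "B"], "T2_2"),
            AlleleDefinition("E", [Interval(1000, 1200)], ["A", "B"], "T3_0"),
            AlleleDefinition("A", [Interval(3000, 3100)], ["A", "B"], "REF"),
        ]

    def mk_call(self, s, e, locus):
        return reconstruct_allele([region(s, e)], locus)

    def test_background_resolves_shared_region(self, catalog, locus):
        call = self.mk_call(1010, 1190, locus)
        assert classify_allele(call, catalog, background="T3_0") == "E"
        assert classify_allele(call, catalog, background="T2_2") == "C"

    def test_unmatched_regions_are_novel(self, catalog, locus):
        call = self.mk_call(8000, 8100, locus)
        assert classify_allele(call, catalog, background="REF") == "NOVEL"

    def test_insufficient_overlap_is_novel(self, catalog, locus):
        call = self.mk_call(1150, 1600, locus)  # < 50% reciprocal overlap
        assert classify_allele(call, catalog, background="T3_0") == "NOVEL"

    def test_empty_catalog_is_an_error(self, locus):
        with pytest.raises(ValueError, match="catalog"):
            classify_allele(self.mk_call(1000, 1100, locus), [], "REF")


class TestSiteClassification:
    def test_pure_paralog_a_read_is_all_a(self, locus, truth):
        seg = locus.informative_region
        read = locus.sequence[seg.start : seg.start + 4000]
        pl = place_read(read, locus.sequence, "r0")
        sites = classify_sites(pl, truth.planted_psvs)
        assert sites and all(s.assignment == "A" for s in sites)

    def test_fused_read_has_single_label_change(self, locus, truth):
        hap, tr = engineer(locus, truth, "A", seed=77)
        (cut,) = tr.crossovers
        read = hap[cut - 2000 : cut + 2000]
        pl = place_read(read, locus.sequence, "r1")
        sites = classify_sites(pl, truth.planted_psvs.restrict_a(
            locus.informative_region))
        path = call_read_switches(sites, min_run=3)
        assert [r[0] for r in path.runs] == ["A", "B"]
        (sw,) = path.switch_intervals
        assert (sw.label_from, sw.label_to) == ("A", "B")
        assert sw.interval.start <= cut <= sw.interval.end

    def test_error_at_psv_is_other(self, locus, truth):
        psv = truth.planted_psvs[200]
        start = psv.pos_a - 500
        read = list(locus.sequence[start : psv.pos_a + 500])
        third = ({"A", "C", "G", "T"} - {psv.base_a, psv.base_b}).pop()
        read[psv.pos_a - start] = third
        pl = place_read("".join(read), locus.sequence, "r2")
        sites = classify_sites(pl, truth.planted_psvs)
        by_index = {s.psv_index for s in sites if s.assignment == "OTHER"}
        assert 200 in by_index

    def test_reverse_strand_read_places_identically(self, locus):
        from paraloci.synthetic_data import revcomp

        frag = locus.sequence[5000:9000]
        fwd = place_read(frag, locus.sequence, "f")
        rev = place_read(revcomp(frag), locus.sequence, "r")
        assert fwd.ref_interval == rev.ref_interval
        assert rev.strand == "-"

    def test_unplaceable_read_returns_none(self, locus):
        import numpy as np

        rng = np.random.default_rng(0)
        junk = rng.choice(list("ACGT"), size=3000)
        assert place_read("".join(junk), locus.sequence, "j") is None


class TestGenotypeScenarios:
    def test_hom_sample_is_hom(self, hom_e_call):
        assert hom_e_call["genotype"].zygosity == "HOM"
        assert len(hom_e_call["genotype"].alleles) == 1

    def test_consensus_regions_contain_no_interior_psvs(self, hom_e_call, truth):
        for reg in hom_e_call["regions"]:
            assert len(truth.planted_psvs.indices_in_a(reg.region_a)) == 0

    def test_three_region_allele_walks_a_c_b_d(self, hom_g_call, locus, truth):
        from paraloci.haplotype_typing import split_background_regions

        bg, _, del_regions = split_background_regions(
            hom_g_call["regions"], locus.haplotypes
        )
        call = reconstruct_allele(del_regions, locus)
        assert call.fragment_order == ["A", "C", "B", "D"]
        assert bg == "UNDETERMINED"
        assert classify_allele(call, truth.catalog, background=bg) == "G"
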