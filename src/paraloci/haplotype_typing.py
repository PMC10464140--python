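"""3'-UTR transposition-haplotype typing.

The common structural haplotype of the locus replaces a 2.2 kb (short) or
3.0 kb (long) segment of the A-gene 3' UTR with the homologous segment from
the B-gene 3' UTR.  Both variants share their 5' boundary region; they are
told apart by where the paralog identity returns to A at the 3' end.

Two complementary typing routes are provided:

* read-based: PSV content of long reads over the acceptor segment (majority
  B-like means the transposition is present; the 3' switch region resolves
  short versus long);
* depth-based: in short-read data mapped against the reference, the
  transposition appears as loss of coverage over the A-gene segment with a
  concomitant reciprocal gain over the B-gene segment.  Depth genotyping
  cannot separate the short from the long variant and reports the combined
  variant class only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .breakpoint_caller import BreakpointRegionCall, ReadPath, merge_regions
from .locus_model import HaplotypeDefinition, Interval, PSVTable, ParalogLocus

__all__ = [
    "HaplotypeCall",
    "DepthProfile",
    "DepthGenotype",
    "CohortAFEstimate",
    "type_from_reads",
    "split_background_regions",
    "depth_genotype",
    "estimate_cohort_af",
]


@dataclass
class HaplotypeCall:
    kind: str  # REF / T2_2 / T3_0 / UNDETERMINED
    n_a_like: int
    n_b_like: int
    boundary_region: Interval | None = None


@dataclass
class DepthProfile:
    """Per-window normalized depth over the locus (diploid baseline ~1.0)."""

    window_size: int
    windows: list[tuple[Interval, float]]

    def __post_init__(self) -> None:
        if any(d < 0 for _, d in self.windows):
            raise ValueError("depths must be non-negative")


@dataclass
class DepthGenotype:
    copies: int | None  # copies of the variant haplotype, 0/1/2; None if undetermined
    ratio_a: float | None
    ratio_b: float | None
    discordant: bool = False
    note: str = ""


@dataclass
class CohortAFEstimate:
    af: float
    ci_low: float
    ci_high: float
    n_alleles: int


def _segment_evidence(
    paths: list[ReadPath], segment: Interval
) -> tuple[int, int]:
    """A-like / B-like PSV observations over the acceptor segment.

    Only sites from reads placed over the A frame count: a read placed over
    the B-gene copy trivially reads B there and says nothing about the
    haplotype of the A copy.
    """
    n_a = n_b = 0
    for path in paths:
        for s in path.sites:
            if s.frame == "A" and segment.contains(s.pos_a):
                if s.assignment == "A":
                    n_a += 1
                elif s.assignment == "B":
                    n_b += 1
    return n_a, n_b


def type_from_reads(
    paths: list[ReadPath],
    psv_table: PSVTable,
    haplotypes: dict[str, HaplotypeDefinition],
    regions: list[BreakpointRegionCall] | None = None,
    min_evidence: int = 3,
) -> HaplotypeCall:
    """Type the transposition haplotype from long-read PSV content.

    Majority B-like segment PSVs mean the transposition is present; the
    kind is resolved by which 3' boundary region the identity switch back
    to A falls in.  When the defining segment is deleted on the allele (the
    switch pattern never returns to A at either boundary), the haplotype is
    UNDETERMINED, as is a sample with insufficient evidence.
    """
    if not haplotypes:
        raise ValueError("no haplotype definitions for this locus")
    segment = haplotypes["T3_0"].acceptor_segment
    n_a, n_b = _segment_evidence(paths, segment)
    if n_a + n_b < min_evidence:
        return HaplotypeCall("UNDETERMINED", n_a, n_b)
    if n_a >= n_b:
        return HaplotypeCall("REF", n_a, n_b)
    if regions is None:
        regions = merge_regions(paths, min_support=1)
    for kind in ("T2_2", "T3_0"):
        hd = haplotypes[kind]
        for reg in regions:
            if (
                (reg.label_from, reg.label_to) == ("B", "A")
                and reg.region_a.overlaps(hd.three_prime_region)
            ):
                return HaplotypeCall(kind, n_a, n_b, boundary_region=reg.region_a)
    # B-like segment without a boundary switch: the deletion spans the
    # haplotype-defining segment
    return HaplotypeCall("UNDETERMINED", n_a, n_b)


def split_background_regions(
    regions: list[BreakpointRegionCall],
    haplotypes: dict[str, HaplotypeDefinition],
) -> tuple[str, list[BreakpointRegionCall], list[BreakpointRegionCall]]:
    """Separate transposition-haplotype boundary switches from deletion
    breakpoints.

    Returns (background kind, background regions, remaining regions).  The
    background is the haplotype whose 5' and 3' boundary regions are both
    matched by switches; with no such pair the background is REF, unless
    the remaining regions imply that the deletion covers the defining
    segment, in which case it is UNDETERMINED.
    """
    if not haplotypes:
        return "REF", [], list(regions)
    fp_iv = haplotypes["T3_0"].five_prime_region
    fp = [
        r
        for r in regions
        if (r.label_from, r.label_to) == ("A", "B") and r.region_a.overlaps(fp_iv)
    ]
    for kind in ("T3_0", "T2_2"):
        tp_iv = haplotypes[kind].three_prime_region
        tp = [
            r
            for r in regions
            if (r.label_from, r.label_to) == ("B", "A") and r.region_a.overlaps(tp_iv)
        ]
        if fp and tp:
            background_regions = [fp[0], tp[0]]
            rest = [r for r in regions if r not in background_regions]
            return kind, background_regions, rest

    segment = haplotypes["T3_0"].acceptor_segment
    background = "REF"
    # walk the remaining switches: a B-frame stretch covering the segment
    # start makes the background undeterminable
    ordered = sorted(regions, key=lambda r: r.region_a.start)
    label = "A"
    for r in ordered:
        if r.label_from == label:
            label = r.label_to
        if label == "B" and r.region_a.start <= segment.start:
            nxt = [x for x in ordered if x.region_a.start > r.region_a.start]
            back = next(
                (x for x in nxt if (x.label_from, x.label_to) == ("B", "A")), None
            )
            if back is None or back.region_a.start >= segment.start:
                background = "UNDETERMINED"
    return background, [], list(regions)


def depth_genotype(
    profile: DepthProfile,
    locus: ParalogLocus,
    psv_table: PSVTable | None = None,
    kind: str = "T3_0",
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> DepthGenotype:
    """Copy count of the transposed segment from a coverage profile.

    The A-segment retention ratio (segment depth over flanking baseline) is
    thresholded into 0, 1 or 2 copies of the variant haplotype; a
    concordant reciprocal gain over the B-gene donor segment is required,
    otherwise the call is flagged discordant.  Only windows containing at
    least one PSV are informative for mapping-based depth and are used when
    a PSV table is supplied.
    """
    hd = locus.haplotypes[kind]
    acceptor, donor = hd.acceptor_segment, hd.donor_segment

    def informative(iv: Interval) -> bool:
        if psv_table is None:
            return True
        return len(psv_table.indices_in_a(iv)) > 0 or len(
            psv_table.indices_in_b(iv)
        ) > 0

    a_depths, b_depths, flank_depths = [], [], []
    for iv, depth in profile.windows:
        if acceptor.overlaps(iv):
            if informative(iv):
                a_depths.append(depth)
        elif donor.overlaps(iv):
            if informative(iv):
                b_depths.append(depth)
        else:
            flank_depths.append(depth)
    if not flank_depths or float(np.median(flank_depths)) == 0.0:
        return DepthGenotype(None, None, None, note="flanking depth is zero")
    baseline = float(np.median(flank_depths))
    if not a_depths or not b_depths:
        return DepthGenotype(None, None, None, note="no informative segment windows")
    ratio_a = float(np.mean(a_depths)) / baseline
    ratio_b = float(np.mean(b_depths)) / baseline
    lo, hi = thresholds
    if ratio_a >= hi:
        copies = 0
    elif ratio_a >= lo:
        copies = 1
    else:
        copies = 2
    discordant = abs(ratio_b - (1.0 + copies / 2.0)) > 0.25
    return DepthGenotype(copies, ratio_a, ratio_b, discordant=discordant)


def estimate_cohort_af(genotypes: list[int]) -> CohortAFEstimate:
    """Cohort allele frequency of the variant haplotype with a 95% Wilson
    score interval, from per-sample copy counts (0/1/2)."""
    if not genotypes:
        raise ValueError("empty cohort")
    if any(g not in (0, 1, 2) for g in genotypes):
        raise ValueError("copy counts must be 0, 1 or 2")
    n_alleles = 2 * len(genotypes)
    k = int(sum(genotypes))
    af = k / n_alleles
    lo, hi = proportion_confint(k, n_alleles, alpha=0.05, method="wilson")
    return CohortAFEstimate(af=af, ci_low=float(lo), ci_high=float(hi),
                            n_alleles=n_alleles)
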