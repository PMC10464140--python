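"""Long-read breakpoint-region calling and allele reconstruction.

Reads are classified at paralog-specific variants (PSVs): each PSV a read
overlaps yields a site call A, B, or OTHER.  A crossover between the two
paralog frames shows up as a switch between a run of A calls and a run of
B calls; because the sequence between the bounding informative sites is
identical in both paralogs, the crossover can only be localized to the
open interval between them — the *breakpoint region*.  Consensus regions
across reads are formed by interval intersection (the narrowest interval
consistent with every supporting read), the rearranged allele is
reconstructed by walking the locus and jumping frames at each region, and
the result is classified against an allele catalog.

Coordinates: every site call and region is expressed in the A frame
(positions within the homology block that holds gene A), regardless of
which frame the read was placed in, so evidence from both gene copies is
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from .locus_model import (
    AlleleDefinition,
    Interval,
    PSVTable,
    ParalogLocus,
)
from .synthetic_data import revcomp, walk_fragments

__all__ = [
    "Placement",
    "SiteCall",
    "SwitchInterval",
    "ReadPath",
    "BreakpointRegionCall",
    "AlleleCall",
    "GenotypeCall",
    "ReconstructionError",
    "place_read",
    "classify_sites",
    "call_read_switches",
    "merge_regions",
    "reconstruct_allele",
    "classify_allele",
    "genotype_sample",
    "call_sample",
]

logger = logging.getLogger(__name__)


class ReconstructionError(ValueError):
    """Raised when called regions imply a non-linear fragment walk."""


@dataclass
class Placement:
    """A read's contiguous placement on the locus (plus strand of the locus)."""

    read_id: str
    strand: str
    ref_interval: Interval
    oriented_seq: str  # read sequence on the locus plus strand
    pairs_read: np.ndarray  # aligned read positions (match/mismatch columns)
    pairs_ref: np.ndarray  # aligned locus positions, same length
    edit_distance: int
    locus_arr: np.ndarray | None = None  # full locus as bytes (shared view)


def place_read(
    read_seq: str,
    locus_seq: str,
    read_id: str = "",
    max_divergence: float = 0.40,
) -> Placement | None:
    """Place a read on the locus with the internal aligner.

    Infix (glocal) alignment of the full read against the locus, tried on
    both strands; the orientation with the lower edit distance wins (plus
    strand on ties).  Returns None for reads that do not place anywhere
    under ``max_divergence``.
    """
    best = None
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        res = edlib.align(seq, locus_seq, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], strand, seq, res)
    if best is None:
        return None
    ed, strand, seq, res = best
    if ed > max_divergence * len(seq):
        return None
    start, end_inclusive = res["locations"][0]
    pr, pf = _cigar_pairs(res["cigar"], start)
    return Placement(
        read_id=read_id,
        strand=strand,
        ref_interval=Interval(start, end_inclusive + 1),
        oriented_seq=seq,
        pairs_read=pr,
        pairs_ref=pf,
        edit_distance=ed,
        locus_arr=np.frombuffer(locus_seq.encode(), dtype=np.uint8),
    )


def _cigar_pairs(cigar: str, ref_start: int) -> tuple[np.ndarray, np.ndarray]:
    pr: list[int] = []
    pf: list[int] = []
    i, j = 0, ref_start
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
            continue
        if ch in "=XM":
            pr.extend(range(i, i + n))
            pf.extend(range(j, j + n))
            i += n
            j += n
        elif ch == "I":  # read insertion: consumes read only
            i += n
        elif ch == "D":  # read deletion: consumes reference only
            j += n
        n = 0
    return np.asarray(pr, dtype=np.int64), np.asarray(pf, dtype=np.int64)


@dataclass(frozen=True)
class SiteCall:
    """One read observation at one PSV."""

    psv_index: int
    read_pos: int
    pos_a: int  # canonical A-frame coordinate of the PSV
    frame: str  # 'A' or 'B': which paralog copy the read is placed over
    observed_base: str
    assignment: str  # 'A', 'B', or 'OTHER'


def classify_sites(
    placement: Placement,
    psv_table: PSVTable,
    context_halfwidth: int = 10,
    max_register_offset: int = 4,
    min_match_fraction: float = 0.75,
) -> list[SiteCall]:
    """Site calls for every PSV overlapped by a placed read.

    PSVs are looked up in both coordinate frames (a read may lie over either
    gene copy); bases at non-PSV positions are ignored.  An empty list is
    returned when the read overlaps no PSV.

    The assignment at each site is a *context vote*, not a single-base
    readout: the read's local window (2 x ``context_halfwidth`` + 1 bases
    around the aligned position, searched over register offsets up to
    ``max_register_offset``) is compared against the same window of both
    paralog copies, and the site is assigned to whichever copy matches
    better.  This is robust to the small register drift a unit-cost
    alignment exhibits between informative sites of diverged paralogs; when
    neither context reaches ``min_match_fraction`` (the read is not
    tracking homologous sequence there) or the two contexts tie, the site
    is OTHER.
    """
    read_arr = np.frombuffer(placement.oriented_seq.encode(), dtype=np.uint8)
    locus_arr = placement.locus_arr
    if locus_arr is None:
        raise ValueError("placement lacks the locus sequence cache")
    w = context_halfwidth
    win = np.arange(-w, w + 1)
    offsets = np.arange(-max_register_offset, max_register_offset + 1)

    calls: list[SiteCall] = []
    for frame in ("A", "B"):
        if frame == "A":
            idxs = psv_table.indices_in_a(placement.ref_interval)
            ref_positions = psv_table.pos_a[idxs]
        else:
            idxs = psv_table.indices_in_b(placement.ref_interval)
            ref_positions = psv_table.pos_b[idxs]
        if len(idxs) == 0:
            continue
        where = np.searchsorted(placement.pairs_ref, ref_positions)
        keep = (where < len(placement.pairs_ref)) & (
            placement.pairs_ref[np.minimum(where, len(placement.pairs_ref) - 1)]
            == ref_positions
        )
        idxs, ref_positions, where = idxs[keep], ref_positions[keep], where[keep]
        if len(idxs) == 0:
            continue
        read_pos = placement.pairs_read[where]
        pos_a = psv_table.pos_a[idxs]
        pos_b = psv_table.pos_b[idxs]

        # context windows on the locus for both paralog copies
        ctx_a_idx = np.clip(pos_a[:, None] + win, 0, len(locus_arr) - 1)
        ctx_b_idx = np.clip(pos_b[:, None] + win, 0, len(locus_arr) - 1)
        ctx_a = locus_arr[ctx_a_idx]
        ctx_b = locus_arr[ctx_b_idx]

        centered = read_pos[:, None] + win
        n_valid = ((centered >= 0) & (centered < len(read_arr))).sum(axis=1)
        best_a = np.full(len(idxs), -1)
        best_b = np.full(len(idxs), -1)
        off_a = np.zeros(len(idxs), dtype=int)
        off_b = np.zeros(len(idxs), dtype=int)
        for off in offsets:
            r_idx = centered + off
            valid = (r_idx >= 0) & (r_idx < len(read_arr))
            r_win = read_arr[np.clip(r_idx, 0, len(read_arr) - 1)]
            sa = ((r_win == ctx_a) & valid).sum(axis=1)
            sb = ((r_win == ctx_b) & valid).sum(axis=1)
            imp_a = sa > best_a
            imp_b = sb > best_b
            off_a = np.where(imp_a, off, off_a)
            off_b = np.where(imp_b, off, off_b)
            best_a = np.maximum(best_a, sa)
            best_b = np.maximum(best_b, sb)
        floor = np.ceil(min_match_fraction * np.maximum(n_valid, 1)).astype(int)
        chosen_off = np.where(best_a >= best_b, off_a, off_b)
        mappable = np.maximum(best_a, best_b) >= floor

        for k in range(len(idxs)):
            rp = int(read_pos[k]) + int(chosen_off[k])
            if not 0 <= rp < len(read_arr):
                continue
            obs = chr(read_arr[rp])
            psv = psv_table[int(idxs[k])]
            if not mappable[k]:
                assignment = "OTHER"
            elif obs == psv.base_a:
                assignment = "A"
            elif obs == psv.base_b:
                assignment = "B"
            else:
                assignment = "OTHER"
            calls.append(
                SiteCall(
                    psv_index=int(idxs[k]),
                    read_pos=rp,
                    pos_a=int(pos_a[k]),
                    frame=frame,
                    observed_base=obs,
                    assignment=assignment,
                )
            )
    calls.sort(key=lambda c: c.read_pos)
    return calls


@dataclass(frozen=True)
class SwitchInterval:
    """A paralog-identity switch within one read."""

    label_from: str
    label_to: str
    interval: Interval  # A-frame, open gap between the bounding sites


@dataclass
class ReadPath:
    """Run decomposition of one read's site calls."""

    read_id: str
    runs: list[tuple[str, int, int]]  # (label, first psv_index, last psv_index)
    switch_intervals: list[SwitchInterval]
    sites: list[SiteCall] = field(default_factory=list)
    undetermined: bool = False

    @property
    def informative_span(self) -> Interval | None:
        pos = [s.pos_a for s in self.sites if s.assignment in "AB"]
        return Interval(min(pos), max(pos) + 1) if pos else None


def call_read_switches(
    sites: list[SiteCall], min_run: int = 3, read_id: str = ""
) -> ReadPath:
    """Decompose a read's site calls into paralog-identity runs.

    Runs are maximal stretches of at least ``min_run`` concordant
    assignments; OTHER sites are skipped and shorter opposite-label groups
    are absorbed as noise, so isolated base errors at PSVs cannot seed a
    run.  With fewer than ``min_run`` informative sites in total the path
    is UNDETERMINED and no switches are emitted.

    Site calls are compared only within one placement frame: a read that
    simply spans both gene copies of the reference shows concordant calls
    in each frame and produces no switch.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    informative = [s for s in sites if s.assignment in ("A", "B")]
    if len(informative) < min_run:
        return ReadPath(read_id, [], [], sites=sites, undetermined=True)

    runs: list[tuple[str, list[SiteCall]]] = []
    switches: list[SwitchInterval] = []
    # group by placement frame first (frame changes only when a read crosses
    # from one gene copy to the other through non-homologous sequence)
    frame_groups: list[list[SiteCall]] = []
    for s in informative:
        if frame_groups and frame_groups[-1][-1].frame == s.frame:
            frame_groups[-1].append(s)
        else:
            frame_groups.append([s])

    group_of_run: list[int] = []
    for gi, group in enumerate(frame_groups):
        # contiguous same-assignment groups
        sub: list[tuple[str, list[SiteCall]]] = []
        for s in group:
            if sub and sub[-1][0] == s.assignment:
                sub[-1][1].append(s)
            else:
                sub.append((s.assignment, [s]))
        # only groups with >= min_run sites can seed a run
        for label, members in sub:
            if len(members) < min_run:
                continue
            if runs and runs[-1][0] == label and group_of_run[-1] == gi:
                runs[-1][1].extend(members)
            else:
                runs.append((label, list(members)))
                group_of_run.append(gi)

    for i, ((la, sa), (lb, sb)) in enumerate(zip(runs, runs[1:])):
        if group_of_run[i] != group_of_run[i + 1]:
            # a switch between placement frames is the read simply spanning
            # both gene copies, not a paralog-identity change
            continue
        last = sa[-1]
        first = sb[0]
        lo, hi = last.pos_a, first.pos_a
        if lo + 1 > hi:
            continue
        switches.append(SwitchInterval(la, lb, Interval(lo + 1, hi)))

    run_summary = [(label, members[0].psv_index, members[-1].psv_index)
                   for label, members in runs]
    return ReadPath(read_id, run_summary, switches, sites=sites)


@dataclass
class BreakpointRegionCall:
    """Consensus breakpoint region across reads.

    The interval is the intersection of all supporting reads' switch
    intervals: the narrowest region consistent with the evidence.  Its
    interior contains no PSV, which is why the crossover cannot be
    localized further.
    """

    region_a: Interval
    region_b: Interval
    label_from: str
    label_to: str
    n_support: int
    ambiguous: bool = False

    @property
    def size(self) -> int:
        return len(self.region_a)

    def contains_crossover(self, cut: int) -> bool:
        """Whether cut position ``cut`` (first base of the new frame) is
        consistent with this region."""
        return self.region_a.start <= cut <= self.region_a.end


def merge_regions(
    paths: list[ReadPath],
    min_support: int = 3,
    frame_delta: int | None = None,
    absorb_slop: int = 60,
    absorb_ratio: float = 0.5,
) -> list[BreakpointRegionCall]:
    """Consensus across reads: co-locating switch intervals merged by
    interval intersection, calls with fewer than ``min_support`` reads
    discarded, output sorted by position.

    A sequencing error at a region's bounding PSV shifts that read's switch
    interval by one informative site, producing a sparsely supported twin
    next to the true region; a call within ``absorb_slop`` bp of a
    same-label-pair call carrying at least ``1/absorb_ratio`` times its
    support is therefore discarded as boundary noise."""
    by_pair: dict[tuple[str, str], list[Interval]] = {}
    for path in paths:
        for sw in path.switch_intervals:
            by_pair.setdefault((sw.label_from, sw.label_to), []).append(sw.interval)

    calls: list[BreakpointRegionCall] = []
    for (la, lb), intervals in sorted(by_pair.items()):
        intervals.sort(key=lambda iv: (iv.start, iv.end))
        cluster: Interval | None = None
        n = 0
        for iv in intervals + [None]:
            if iv is not None and cluster is not None:
                inter = cluster.intersection(iv)
                if inter is not None:
                    cluster, n = inter, n + 1
                    continue
            if cluster is not None and n >= min_support:
                delta = frame_delta or 0
                calls.append(
                    BreakpointRegionCall(
                        region_a=cluster,
                        region_b=Interval(cluster.start + delta, cluster.end + delta),
                        label_from=la,
                        label_to=lb,
                        n_support=n,
                    )
                )
            cluster, n = iv, 1
    calls.sort(key=lambda c: (c.region_a.start, c.region_a.end))
    # absorb boundary-noise twins into their dominant neighbour
    drop: set[int] = set()
    for i, ci in enumerate(calls):
        for j, cj in enumerate(calls):
            if i == j or j in drop:
                continue
            same_pair = (ci.label_from, ci.label_to) == (cj.label_from, cj.label_to)
            gap = max(cj.region_a.start - ci.region_a.end,
                      ci.region_a.start - cj.region_a.end)
            if same_pair and gap <= absorb_slop and (
                ci.n_support <= absorb_ratio * cj.n_support
            ):
                drop.add(i)
                break
    calls = [c for i, c in enumerate(calls) if i not in drop]
    # flag overlapping calls with inconsistent label pairs
    for c1, c2 in zip(calls, calls[1:]):
        if c1.region_a.overlaps(c2.region_a) and (
            (c1.label_from, c1.label_to) != (c2.label_from, c2.label_to)
        ):
            c1.ambiguous = c2.ambiguous = True
            logger.warning(
                "overlapping breakpoint regions with inconsistent paralog "
                "labels: %s and %s", c1, c2
            )
    return calls


@dataclass
class AlleleCall:
    """One reconstructed structural allele."""

    regions: list[BreakpointRegionCall]
    fragment_order: list[str]
    deleted_spans: list[Interval]
    class_label: str | None = None
    background: str = "UNDETERMINED"
    error: str | None = None

    @property
    def is_reference(self) -> bool:
        return not self.regions


def reconstruct_allele(
    regions: list[BreakpointRegionCall], locus: ParalogLocus
) -> AlleleCall:
    """Reconstruct the rearranged allele implied by a set of regions.

    The locus is walked in the A frame, jumping from the acceptor to the
    donor frame at each region; fragments are named by reference order, so
    the deleted span(s) are exactly the reference material on no fragment.
    """
    if not regions:
        return AlleleCall([], ["A"], [], background="REF")
    regions = sorted(regions, key=lambda r: r.region_a.start)
    expected = "A"
    for r in regions:
        if r.label_from != expected or r.label_to == r.label_from:
            raise ReconstructionError(
                f"regions imply a non-linear walk: expected a switch from "
                f"{expected}, got {r.label_from}->{r.label_to} at {r.region_a}"
            )
        expected = r.label_to
    cuts = [r.region_a.start for r in regions]
    order, _, deleted = walk_fragments(cuts, locus.frame_delta, len(locus.sequence))
    return AlleleCall(regions=regions, fragment_order=order, deleted_spans=deleted)


def classify_allele(
    call: AlleleCall,
    catalog: list[AlleleDefinition],
    background: str = "UNDETERMINED",
    min_reciprocal_overlap: float = 0.5,
) -> str:
    """Assign a catalog label to a reconstructed allele.

    A label matches when every called region reciprocally overlaps the
    corresponding catalog region by at least ``min_reciprocal_overlap`` and
    the backgrounds agree; alleles sharing regions but differing in
    transposition length (the C-versus-E situation) are resolved by the
    background.  Anything unmatched is NOVEL.
    """
    if not catalog:
        raise ValueError("allele catalog is empty")
    matches = []
    for entry in catalog:
        if len(entry.regions) != len(call.regions):
            continue
        ok = all(
            creg.region_a.reciprocal_overlap(ereg) >= min_reciprocal_overlap
            for creg, ereg in zip(call.regions, entry.regions)
        )
        if not ok:
            continue
        if entry.background != background:
            continue
        matches.append(entry)
    if not matches:
        return "NOVEL"
    if len(matches) > 1:
        matches.sort(key=lambda e: sum(len(r) for r in e.regions))
        logger.warning(
            "multiple catalog labels match (%s); choosing the one with the "
            "smaller regions", [m.label for m in matches]
        )
    return matches[0].label


@dataclass
class GenotypeCall:
    """Sample-level genotype: one or two structural alleles."""

    alleles: list[AlleleCall]
    zygosity: str  # HOM / HET / COMPOUND_HET / UNDETERMINED
    support_fractions: list[float]
    n_informative_reads: int = 0


def genotype_sample(
    paths: list[ReadPath],
    regions: list[BreakpointRegionCall],
    locus: ParalogLocus,
    support_threshold: float = 0.2,
    vote_slop: int = 60,
    min_flank_sites: int = 3,
) -> GenotypeCall:
    """Cluster reads by allele signature and call the genotype.

    Each read votes 1 (switch seen) or 0 (reference pattern) at every
    consensus region whose interval its informative span covers; reads with
    compatible votes are greedily clustered.  Two variant clusters each at
    or above ``support_threshold`` of informative reads give COMPOUND_HET;
    one variant cluster plus a reference-pattern cluster gives HET; a single
    variant cluster gives HOM.
    """
    informative = [p for p in paths if not p.undetermined]
    if not informative:
        return GenotypeCall([], "UNDETERMINED", [], 0)
    if not regions:
        return GenotypeCall(
            [reconstruct_allele([], locus)], "HOM", [1.0], len(informative)
        )

    votes_per_read: list[dict[int, int]] = []
    voters: list[ReadPath] = []
    for path in informative:
        span = path.informative_span
        if span is None:
            continue
        pos_informative = np.array(
            sorted(s.pos_a for s in path.sites if s.assignment in "AB")
        )
        votes: dict[int, int] = {}
        for ri, reg in enumerate(regions):
            # a read can only vote on a region it could have detected: at
            # least one full run of informative sites on each side
            n_left = int(np.searchsorted(pos_informative, reg.region_a.start))
            n_right = len(pos_informative) - int(
                np.searchsorted(pos_informative, reg.region_a.end, side="right")
            )
            covered = n_left >= min_flank_sites and n_right >= min_flank_sites
            if covered:
                # a base error at a bounding PSV shifts a read's switch by
                # one informative site, so votes tolerate a small offset
                supported = any(
                    (sw.label_from, sw.label_to) == (reg.label_from, reg.label_to)
                    and max(sw.interval.start - reg.region_a.end,
                            reg.region_a.start - sw.interval.end) <= vote_slop
                    for sw in path.switch_intervals
                )
                votes[ri] = 1 if supported else 0
        if votes:
            votes_per_read.append(votes)
            voters.append(path)

    if not votes_per_read:
        return GenotypeCall([], "UNDETERMINED", [], len(informative))

    # most informative reads first, so they establish the allele backbones;
    # a read then joins the compatible cluster it shares the most voted
    # regions with.  Reads sharing no region with any compatible cluster
    # cannot be phased onto a specific allele and stay unassigned.
    order = sorted(range(len(votes_per_read)),
                   key=lambda i: (-len(votes_per_read[i]), i))
    prototypes: list[dict[int, int]] = []
    members: list[int] = []
    n_assigned = 0
    for i in order:
        votes = votes_per_read[i]
        compatible = [
            ci
            for ci, proto in enumerate(prototypes)
            if all(proto.get(k, v) == v for k, v in votes.items())
        ]
        shared = {
            ci: sum(1 for k in votes if k in prototypes[ci])
            for ci in compatible
        }
        if not prototypes:
            prototypes.append(dict(votes))
            members.append(1)
            n_assigned += 1
        elif not compatible:
            prototypes.append(dict(votes))
            members.append(1)
            n_assigned += 1
        else:
            best = max(compatible, key=lambda ci: (shared[ci], -ci))
            if shared[best] == 0:
                continue  # ambiguous: overlaps no cluster's regions
            prototypes[best].update(votes)
            members[best] += 1
            n_assigned += 1

    n_voters = n_assigned
    fractions = [m / n_voters for m in members]
    variant = [
        (proto, frac)
        for proto, frac in zip(prototypes, fractions)
        if any(v == 1 for v in proto.values()) and frac >= support_threshold
    ]
    ref_frac = sum(
        frac
        for proto, frac in zip(prototypes, fractions)
        if all(v == 0 for v in proto.values())
    )
    variant.sort(key=lambda t: -t[1])
    if len(variant) > 2:
        logger.warning(
            "%d variant clusters above threshold; keeping the top two",
            len(variant),
        )
        variant = variant[:2]

    def allele_for(proto: dict[int, int]) -> AlleleCall:
        regs = [regions[ri] for ri, v in sorted(proto.items()) if v == 1]
        try:
            return reconstruct_allele(regs, locus)
        except ReconstructionError as exc:
            logger.warning("allele reconstruction failed: %s", exc)
            return AlleleCall(regions=regs, fragment_order=[], deleted_spans=[],
                              error=str(exc))

    if not variant:
        return GenotypeCall(
            [reconstruct_allele([], locus)], "HOM", [1.0], n_voters
        )
    if len(variant) == 2:
        return GenotypeCall(
            [allele_for(p) for p, _ in variant],
            "COMPOUND_HET",
            [f for _, f in variant],
            n_voters,
        )
    proto, frac = variant[0]
    if ref_frac >= support_threshold:
        return GenotypeCall(
            [allele_for(proto), reconstruct_allele([], locus)],
            "HET",
            [frac, ref_frac],
            n_voters,
        )
    return GenotypeCall([allele_for(proto)], "HOM", [frac], n_voters)


def call_sample(
    reads,
    locus: ParalogLocus,
    psv_table: PSVTable,
    min_run: int = 3,
    min_support: int = 3,
    support_threshold: float = 0.2,
) -> tuple[list[ReadPath], list[BreakpointRegionCall], GenotypeCall]:
    """End-to-end convenience: place reads, call switches, merge, genotype.

    ``reads`` is an iterable of (read_id, sequence) pairs or objects with
    ``read_id``/``sequence`` attributes.
    """
    if locus.informative_region is not None:
        psv_table = psv_table.restrict_a(locus.informative_region)
    paths = []
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "sequence") else r
        placement = place_read(seq, locus.sequence, read_id=rid)
        if placement is None:
            continue
        sites = classify_sites(placement, psv_table)
        paths.append(call_read_switches(sites, min_run=min_run, read_id=rid))
    regions = merge_regions(paths, min_support=min_support,
                            frame_delta=locus.frame_delta)
    genotype = genotype_sample(paths, regions, locus,
                               support_threshold=support_threshold)
    return paths, regions, genotype
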