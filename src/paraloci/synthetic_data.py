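"""Synthetic paralog loci with exact truth.

Emulates the architecture of a tandem paralog pair inside two homology
blocks: ~80% identity flanking sequence, ~94% identity gene bodies, and a
~96% identity 3'-UTR segment that exists in two transposition haplotypes
(a short 2.2 kb and a long 3.0 kb variant sharing their 5' boundary).
Deletion alleles are engineered by drawing 1-3 crossovers inside designated
homology tracts; tracts are kept free of paralog-specific variants so that,
exactly as in real data, a crossover cannot be localized more precisely than
its tract.

Substitutions between the two blocks are planted by exact count rather than
by Bernoulli sampling, so the identity of every sub-region matches its
requested value exactly and the paralog-specific-variant (PSV) table is
known without alignment.  One substitution is always forced into the short
gap on either side of each designated tract, guaranteeing that every tract
is bounded by informative positions and adjacent tracts can never merge
into one apparent breakpoint region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .locus_model import (
    AlleleDefinition,
    GeneModel,
    HaplotypeDefinition,
    HomologyBlock,
    Interval,
    PSV,
    PSVTable,
    ParalogLocus,
)

__all__ = [
    "LocusParams",
    "LocusLayout",
    "DeletionSpec",
    "ReadSimParams",
    "SimRead",
    "HaploidTruth",
    "SimTruth",
    "generate_locus",
    "apply_transposition",
    "apply_deletion",
    "simulate_reads",
    "simulate_depth_profile",
    "walk_fragments",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LocusParams:
    """Parameters of the synthetic locus generator.

    Defaults reproduce the architecture this package is built around:
    a 2.2 kb / 3.0 kb 3'-UTR transposition segment pair, 80% flank identity,
    94% gene-body identity and 96% segment identity.
    """

    seed: int
    flank_block_len: int = 2200
    gene_len: int = 8000
    utr_segment_len_short: int = 2200
    utr_segment_len_long: int = 3000
    identity_flank: float = 0.80
    identity_gene: float = 0.94
    identity_utr_segment: float = 0.96
    n_exons: int = 20
    utr_margin: int = 300
    utr_margin_post: int = 3000
    unique_flank_len: int = 400

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("identity_flank", "identity_gene", "identity_utr_segment"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.utr_segment_len_short >= self.utr_segment_len_long:
            raise ValueError("short segment must be shorter than long segment")
        if self.flank_block_len < 2000:
            raise ValueError("flank_block_len must be >= 2000 to host the allele catalog")
        if self.gene_len < 150 * self.n_exons:
            raise ValueError(
                f"gene_len {self.gene_len} too small for {self.n_exons} exons"
            )


@dataclass
class LocusLayout:
    """All derived coordinates of one synthetic locus (locus coordinates)."""

    params: LocusParams
    block_len: int
    block_a: Interval
    block_b: Interval
    gene_region: Interval  # A-frame, exons+introns
    seg_start: int  # A-frame start of the transposition segment (s0)
    seg_short: Interval
    seg_long: Interval
    flank3_start: int
    tracts: dict[str, Interval]  # designated PSV-free crossover tracts, A-frame
    exon_len: int
    intron_len: int

    @property
    def delta(self) -> int:
        return self.block_b.start - self.block_a.start


@dataclass(frozen=True)
class DeletionSpec:
    """Recipe for one engineered deletion allele."""

    label: str
    crossover_tracts: list[Interval]  # A-frame intervals, 1-3 of them
    background: str  # REF / T2_2 / T3_0 / UNDETERMINED
    fragment_order: list[str] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.crossover_tracts) <= 3:
            raise ValueError("1 to 3 crossover tracts required")
        if self.fragment_order is not None and len(self.fragment_order) != len(
            self.crossover_tracts
        ) + 1:
            raise ValueError(
                "fragment_order inconsistent with tract count: "
                f"{len(self.fragment_order)} labels for "
                f"{len(self.crossover_tracts)} crossovers"
            )


@dataclass(frozen=True)
class ReadSimParams:
    """Long-read simulation parameters (lognormal lengths, uniform errors)."""

    seed: int
    depth: float = 30.0
    read_len_mean: float = 6000.0
    read_len_sd: float = 2000.0
    err_mismatch: float = 0.0
    err_ins: float = 0.0
    err_del: float = 0.0
    min_read_len: int = 500

    def __post_init__(self) -> None:
        rates = (self.err_mismatch, self.err_ins, self.err_del)
        if any(r < 0 for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be >= 0 and sum to < 0.5")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class SimRead:
    read_id: str
    sequence: str
    haploid_index: int
    origin: Interval  # interval on the source haploid
    strand: str  # '+' or '-'
    quality_char: str = "5"  # constant Q20 placeholder

    @property
    def quality(self) -> str:
        return self.quality_char * len(self.sequence)


@dataclass
class HaploidTruth:
    """Exact provenance of one engineered haploid sequence."""

    haplotype: str  # REF / T2_2 / T3_0
    allele_label: str  # "REF" or a deletion allele label
    crossovers: list[int] = field(default_factory=list)  # A-frame cut positions
    crossover_tracts: list[Interval] = field(default_factory=list)
    fragment_order: list[str] = field(default_factory=list)
    deleted_spans: list[Interval] = field(default_factory=list)
    background: str = "REF"


@dataclass
class SimTruth:
    """Oracle bookkeeping for one simulated locus/sample."""

    layout: LocusLayout
    planted_psvs: PSVTable
    catalog: list[AlleleDefinition]
    deletion_specs: dict[str, DeletionSpec]
    haploids: list[HaploidTruth] = field(default_factory=list)
    reads: list[SimRead] = field(default_factory=list)

    def catalog_entry(self, label: str) -> AlleleDefinition:
        for entry in self.catalog:
            if entry.label == label:
                return entry
        raise KeyError(label)


def _build_layout(params: LocusParams) -> LocusLayout:
    p = params
    u = p.unique_flank_len
    utr_len = p.utr_segment_len_long + p.utr_margin + p.utr_margin_post
    block_len = 2 * p.flank_block_len + p.gene_len + utr_len
    block_a = Interval(u, u + block_len)
    block_b = Interval(u + block_len + u, u + block_len + u + block_len)

    a0 = block_a.start
    gene_region = Interval(a0 + p.flank_block_len, a0 + p.flank_block_len + p.gene_len)
    u0 = gene_region.end
    s0 = u0 + p.utr_margin
    f0 = u0 + utr_len  # flank3 start

    n = p.n_exons
    exon_len = (p.gene_len // (2 * n)) // 3 * 3  # keep the CDS in frame
    intron_len = (p.gene_len - n * exon_len) // max(n - 1, 1)
    step = exon_len + intron_len

    def intron_tract(i: int, size: int) -> Interval:
        """Centered tract in the intron following exon ``i`` (1-based)."""
        istart = gene_region.start + i * step - intron_len
        size = min(size, intron_len - 70)
        if size < 20:
            raise ValueError("introns too short to host crossover tracts")
        mid = istart + intron_len // 2
        return Interval(mid - size // 2, mid - size // 2 + size)

    e0 = s0 + p.utr_segment_len_long  # end of the long transposition segment
    tracts = {
        # haplotype boundary regions
        "hp5": Interval(s0 - 30, s0 + 30),
        "hp3_22": Interval(s0 + p.utr_segment_len_short - 30,
                           s0 + p.utr_segment_len_short + 30),
        "hp3_30": Interval(e0 - 30, e0 + 30),
        # deletion-allele tracts (sizes span the 30-410 nt scale); all in the
        # high-identity 3' UTR zone or in introns, as in the real locus.
        # Adjacent tracts are kept ~200 nt apart so that roughly ten
        # informative sites separate neighbouring breakpoint regions
        "ce": Interval(e0 + 250, e0 + 450),
        "a": Interval(e0 + 700, e0 + 880),
        "b": Interval(e0 + 1000, e0 + 1100),
        "d": Interval(e0 + 1300, e0 + 1710),
        "f": Interval(e0 + 1900, e0 + 1930),
        "g1": intron_tract(7, 53),
        "g2": Interval(e0 + 520, e0 + 580),
        "g3": Interval(e0 + 2100, e0 + 2200),
        "h": intron_tract(15, 144),
    }
    assert tracts["g3"].end + 60 <= f0, "utr_margin_post too small for the catalog"

    return LocusLayout(
        params=p,
        block_len=block_len,
        block_a=block_a,
        block_b=block_b,
        gene_region=gene_region,
        seg_start=s0,
        seg_short=Interval(s0, s0 + p.utr_segment_len_short),
        seg_long=Interval(s0, s0 + p.utr_segment_len_long),
        flank3_start=f0,
        tracts=tracts,
        exon_len=exon_len,
        intron_len=intron_len,
    )


def _plant_region(
    rng: np.random.Generator,
    region: Interval,
    identity: float,
    tracts: list[Interval],
    forced: list[int],
) -> np.ndarray:
    """Choose substitution positions for one region, by exact count."""
    count = round((1.0 - identity) * len(region))
    mask = np.ones(len(region), dtype=bool)
    for t in tracts:
        inter = region.intersection(t)
        if inter is not None:
            mask[inter.start - region.start : inter.end - region.start] = False
    allowed = np.flatnonzero(mask) + region.start
    forced_in = sorted({p for p in forced if region.contains(p)})
    for p in forced_in:
        if not mask[p - region.start]:  # pragma: no cover - layout guards this
            raise ValueError(f"forced separator {p} falls inside a tract")
    if count < len(forced_in):
        raise ValueError(
            f"region {region} too small for identity {identity} with "
            f"{len(forced_in)} forced separators"
        )
    pool = np.setdiff1d(allowed, np.array(forced_in, dtype=np.int64))
    extra = rng.choice(pool, size=count - len(forced_in), replace=False)
    return np.sort(np.concatenate([np.array(forced_in, dtype=np.int64), extra]))


def _make_gene(name: str, layout: LocusLayout, offset: int) -> GeneModel:
    p = layout.params
    step = layout.exon_len + layout.intron_len
    start = layout.gene_region.start + offset
    exons = [
        Interval(start + i * step, start + i * step + layout.exon_len)
        for i in range(p.n_exons)
    ]
    return GeneModel(
        name=name,
        strand="+",
        exons=exons,
        cds_start=exons[0].start,
        cds_end=exons[-1].end,
    )


def _haplotype_definitions(
    layout: LocusLayout, psvs: PSVTable
) -> dict[str, HaplotypeDefinition]:
    defs = {}
    for kind, seg in (("T2_2", layout.seg_short), ("T3_0", layout.seg_long)):
        defs[kind] = HaplotypeDefinition(
            kind=kind,
            five_prime_region=_psv_gap(psvs, layout.tracts["hp5"]),
            three_prime_region=_psv_gap(
                psvs, layout.tracts["hp3_22" if kind == "T2_2" else "hp3_30"]
            ),
            acceptor_segment=seg,
            donor_segment=Interval(seg.start + layout.delta, seg.end + layout.delta),
        )
    return defs


def _psv_gap(psvs: PSVTable, tract: Interval) -> Interval:
    """The full informative-position gap containing ``tract``.

    This is the breakpoint region an ideal caller reports: the open interval
    between the last PSV before the tract and the first PSV after it.
    """
    i = int(np.searchsorted(psvs.pos_a, tract.start))
    if i == 0 or i == len(psvs):
        raise ValueError("tract not bounded by PSVs on both sides")
    left = int(psvs.pos_a[i - 1])
    right = int(psvs.pos_a[i])
    if right < tract.end:
        raise ValueError(f"PSV at {right} falls inside tract {tract}")
    return Interval(left + 1, right)


def _default_specs(layout: LocusLayout) -> dict[str, DeletionSpec]:
    t = layout.tracts
    return {
        "A": DeletionSpec("A", [t["a"]], "REF"),
        "B": DeletionSpec("B", [t["b"]], "T2_2"),
        "C": DeletionSpec("C", [t["ce"]], "T2_2"),
        "D": DeletionSpec("D", [t["d"]], "T2_2"),
        "E": DeletionSpec("E", [t["ce"]], "T3_0"),
        "F": DeletionSpec("F", [t["f"]], "T3_0"),
        "G": DeletionSpec("G", [t["g1"], t["g2"], t["g3"]], "UNDETERMINED"),
        "H": DeletionSpec("H", [t["h"]], "UNDETERMINED"),
    }


def _build_catalog(
    layout: LocusLayout, psvs: PSVTable, specs: dict[str, DeletionSpec]
) -> list[AlleleDefinition]:
    delta = layout.delta
    catalog = []
    for label, spec in sorted(specs.items()):
        regions = [_psv_gap(psvs, tr) for tr in spec.crossover_tracts]
        cuts = [tr.start + len(tr) // 2 for tr in spec.crossover_tracts]
        order, _, _ = walk_fragments(cuts, delta, layout.block_b.end + layout.params.unique_flank_len)
        catalog.append(
            AlleleDefinition(
                label=label,
                regions=regions,
                fragment_order=order,
                background=spec.background,
            )
        )
    return catalog


def generate_locus(params: LocusParams) -> tuple[ParalogLocus, SimTruth]:
    """Generate a synthetic paralog locus and its exact truth.

    Block B is derived from block A by planting substitutions by exact count
    per sub-region (flanks / gene body / UTR segment), never inside the
    designated crossover tracts.  Deterministic per seed.
    """
    layout = _build_layout(params)
    p = params
    rng = np.random.default_rng(p.seed)

    total_len = layout.block_b.end + p.unique_flank_len
    arr = rng.choice(_BASES, size=total_len)

    a0 = layout.block_a.start
    u0 = layout.gene_region.end
    s0 = layout.seg_start
    f0 = layout.flank3_start
    utr_end = u0 + (f0 - u0)  # == f0
    regions = [
        (Interval(a0, layout.gene_region.start), p.identity_flank),
        (Interval(layout.gene_region.start, u0), p.identity_gene),
        (layout.seg_long, p.identity_utr_segment),
        (Interval(u0, s0), p.identity_utr_segment),
        (Interval(layout.seg_long.end, utr_end), p.identity_utr_segment),
        (Interval(f0, layout.block_a.end), p.identity_flank),
    ]
    tract_list = list(layout.tracts.values())
    forced = []
    for tr in tract_list:
        forced.extend([tr.start - 20, tr.end + 19])

    # copy block A into block B, then plant the substitutions
    delta = layout.delta
    arr[layout.block_b.start : layout.block_b.end] = arr[
        layout.block_a.start : layout.block_a.end
    ]
    psvs: list[PSV] = []
    for region, ident in regions:
        sub_pos = _plant_region(rng, region, ident, tract_list, forced)
        for pos in sub_pos.tolist():
            old = arr[pos]
            choices = _BASES[_BASES != old]
            new = rng.choice(choices)
            arr[pos + delta] = new
            psvs.append(PSV(pos, pos + delta, chr(old), chr(new)))
    psv_table = PSVTable(psvs)

    sequence = arr.tobytes().decode()
    n_sub = len(psvs)
    identity = 1.0 - n_sub / layout.block_len
    block = HomologyBlock(
        interval_a=layout.block_a,
        interval_b=layout.block_b,
        identity=identity,
        alignment=None,
        block_id=0,
    )
    gene_a = _make_gene("geneA", layout, 0)
    gene_b = _make_gene("geneB", layout, delta)
    hapdefs = _haplotype_definitions(layout, psv_table)
    locus = ParalogLocus(
        sequence=sequence,
        gene_a=gene_a,
        gene_b=gene_b,
        blocks=[block],
        build_label=f"synthetic-v1-seed{p.seed}",
        haplotypes=hapdefs,
        informative_region=Interval(layout.gene_region.start, layout.flank3_start),
    )
    specs = _default_specs(layout)
    truth = SimTruth(
        layout=layout,
        planted_psvs=psv_table,
        catalog=_build_catalog(layout, psv_table, specs),
        deletion_specs=specs,
    )
    return locus, truth


def apply_transposition(
    locus: ParalogLocus, kind: str
) -> tuple[str, HaploidTruth]:
    """Engineer one haploid carrying the requested 3'-UTR haplotype.

    REF returns the locus sequence unchanged; T2_2 / T3_0 replace the
    acceptor segment in the A-gene 3' UTR with the homologous donor segment
    from the B frame (equal length, so the sequence length is preserved and
    every PSV inside the segment flips from its A to its B allele).
    """
    if kind == "REF":
        return locus.sequence, HaploidTruth(haplotype="REF", allele_label="REF")
    if kind not in locus.haplotypes:
        raise KeyError(f"haplotype kind {kind!r} not defined on this locus")
    hd = locus.haplotypes[kind]
    seq = locus.sequence
    donor = seq[hd.donor_segment.start : hd.donor_segment.end]
    out = seq[: hd.acceptor_segment.start] + donor + seq[hd.acceptor_segment.end :]
    return out, HaploidTruth(haplotype=kind, allele_label="REF", background=kind)


def walk_fragments(
    cuts: list[int], delta: int, locus_len: int
) -> tuple[list[str], list[tuple[str, Interval]], list[Interval]]:
    """Fragment geometry of an allele with crossovers at ``cuts`` (A-frame).

    The allele alternates frames starting in A: A-frame up to the first cut,
    B-frame to the second, and so on.  Fragments are named by their order on
    the reference ('A' = leftmost reference fragment), so a three-crossover
    allele comes out as the rearrangement A-C-B-D.  Returns the fragment
    order, the (name, reference interval) list in walk order, and the
    reference intervals deleted (on no fragment).
    """
    cuts = sorted(cuts)
    bounds = [0] + cuts + [None]
    frags: list[Interval] = []
    for i in range(len(bounds) - 1):
        in_b = i % 2 == 1
        start = bounds[i] + (delta if in_b else 0)
        if bounds[i + 1] is None:
            end = locus_len
        else:
            end = bounds[i + 1] + (delta if in_b else 0)
        if start > end:
            raise ValueError("crossovers imply a non-linear walk")
        frags.append(Interval(start, end))
    order_by_pos = sorted(range(len(frags)), key=lambda i: frags[i].start)
    names = [""] * len(frags)
    for rank, idx in enumerate(order_by_pos):
        names[idx] = chr(ord("A") + rank)
    covered = sorted(frags)
    deleted: list[Interval] = []
    cursor = 0
    for iv in covered:
        if iv.start > cursor:
            deleted.append(Interval(cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < locus_len:
        deleted.append(Interval(cursor, locus_len))
    return names, list(zip(names, frags)), deleted


def apply_deletion(
    haploid: str,
    spec: DeletionSpec,
    locus: ParalogLocus,
    seed: int,
    truth_in: HaploidTruth | None = None,
) -> tuple[str, HaploidTruth]:
    """Engineer a deletion allele on ``haploid`` by 1-3 crossovers.

    Crossover positions are drawn uniformly inside each tract of ``spec``;
    the output is the concatenation of the fragment walk.  Cut position ``c``
    means the sequence switches from the A frame to the B frame (or back)
    such that position ``c`` is the first position taken from the new frame.
    """
    rng = np.random.default_rng(seed)
    delta = locus.frame_delta
    cuts = []
    for tr in spec.crossover_tracts:
        cuts.append(int(rng.integers(tr.start, tr.end)))
    cuts.sort()
    order, frags, deleted = walk_fragments(cuts, delta, len(haploid))
    if spec.fragment_order is not None and order != spec.fragment_order:
        raise ValueError(
            f"declared fragment order {spec.fragment_order} inconsistent with "
            f"walk order {order}"
        )
    out = "".join(haploid[iv.start : iv.end] for _, iv in frags)

    base = truth_in or HaploidTruth(haplotype="REF", allele_label="REF")
    background = base.haplotype if base.haplotype != "REF" else spec.background
    if base.haplotype == "REF" and spec.background == "REF":
        background = "REF"
    seg = locus.haplotypes["T3_0"].acceptor_segment if locus.haplotypes else None
    if seg is not None and cuts[0] <= seg.start:
        # the deletion's B-frame span covers the haplotype-defining segment,
        # so the background cannot be read off the sequence
        background = "UNDETERMINED"
    return out, HaploidTruth(
        haplotype=base.haplotype,
        allele_label=spec.label,
        crossovers=cuts,
        crossover_tracts=list(spec.crossover_tracts),
        fragment_order=order,
        deleted_spans=deleted,
        background=background,
    )


def simulate_reads(
    diplotype: tuple[str, str],
    params: ReadSimParams,
    haploid_truths: tuple[HaploidTruth, HaploidTruth] | None = None,
) -> list[SimRead]:
    """Simulate error-bearing long reads from a pair of haploids.

    Reads are drawn from both haploids proportional to length, with
    lognormal lengths clipped to [min_read_len, haploid length], uniform
    start positions, random strand, and independent per-base mismatch /
    insertion / deletion errors.  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    lens = np.array([len(h) for h in diplotype], dtype=float)
    target_bases = params.depth * lens.mean()
    sigma2 = math.log(1.0 + (params.read_len_sd / params.read_len_mean) ** 2)
    mu = math.log(params.read_len_mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)

    reads: list[SimRead] = []
    emitted = 0.0
    i = 0
    while emitted < target_bases:
        hap_idx = int(rng.random() < lens[1] / lens.sum())
        hap = diplotype[hap_idx]
        rl = int(np.clip(rng.lognormal(mu, sigma), params.min_read_len, len(hap)))
        start = int(rng.integers(0, len(hap) - rl + 1))
        frag = hap[start : start + rl]
        seq = _apply_errors(frag, params, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(
            SimRead(
                read_id=f"read{i:05d}_h{hap_idx}",
                sequence=seq,
                haploid_index=hap_idx,
                origin=Interval(start, start + rl),
                strand=strand,
            )
        )
        emitted += rl
        i += 1
    return reads


def _apply_errors(frag: str, params: ReadSimParams, rng: np.random.Generator) -> str:
    if params.err_mismatch == params.err_ins == params.err_del == 0.0:
        return frag
    arr = np.frombuffer(frag.encode(), dtype=np.uint8)
    u = rng.random(len(arr))
    out = bytearray()
    p_mm = params.err_mismatch
    p_ins = p_mm + params.err_ins
    p_del = p_ins + params.err_del
    for base, x in zip(arr, u):
        if x < p_mm:
            choices = _BASES[_BASES != base]
            out.append(int(rng.choice(choices)))
        elif x < p_ins:
            out.append(int(base))
            out.append(int(rng.choice(_BASES)))
        elif x < p_del:
            continue
        else:
            out.append(int(base))
    return out.decode()


def simulate_depth_profile(
    locus: ParalogLocus,
    variant_copies: int,
    kind: str = "T3_0",
    window_size: int = 100,
    mean_count: float = 100.0,
    seed: int = 0,
) -> list[tuple[Interval, float]]:
    """Poisson depth profile of a diploid with ``variant_copies`` T alleles.

    Mimics the short-read coverage signature of the transposition against
    the reference: apparent loss over the A-gene acceptor segment with a
    concomitant reciprocal gain over the B-gene donor segment.  Depths are
    normalized so that ordinary diploid coverage is ~1.0.
    """
    if variant_copies not in (0, 1, 2):
        raise ValueError("variant_copies must be 0, 1 or 2")
    hd = locus.haplotypes[kind]
    rng = np.random.default_rng(seed)
    n = len(locus.sequence)
    windows = []
    for start in range(0, n, window_size):
        iv = Interval(start, min(start + window_size, n))
        if hd.acceptor_segment.overlaps(iv):
            expect = (2 - variant_copies) / 2.0
        elif hd.donor_segment.overlaps(iv):
            expect = (2 + variant_copies) / 2.0
        else:
            expect = 1.0
        depth = rng.poisson(mean_count * expect) / mean_count
        windows.append((iv, float(depth)))
    return windows
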