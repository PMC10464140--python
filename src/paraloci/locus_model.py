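"""Paralog-locus data model.

A *paralog locus* is a contiguous stretch of genome containing two highly
similar gene copies (here called gene A and gene B) embedded in two larger
homology blocks.  Because the two copies are nearly identical, most positions
are uninformative about which copy a sequencing read came from; the positions
where the copies differ — paralog-specific variants (PSVs), the locus'
"gene-specific nucleotides" — carry all of the discriminating signal.

This module defines the coordinate frame used by every downstream stage:

* all locus coordinates are 0-based half-open on the plus strand internally,
  converted to 1-based inclusive only in human-readable reports;
* the pairwise alignment between the two homology blocks induces a monotone
  position map A<->B, from which the PSV table is derived;
* haplotype and deletion-allele catalogs are expressed as intervals in the
  A-frame (positions within the block containing gene A).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import edlib
import numpy as np

__all__ = [
    "Interval",
    "GeneModel",
    "BlockAlignment",
    "HomologyBlock",
    "ParalogLocus",
    "PSV",
    "PSVTable",
    "HaplotypeDefinition",
    "AlleleDefinition",
    "align_paralogs",
    "compute_psv_table",
    "sequence_identity",
]

_DNA = set("ACGTN")
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

# biopython is only needed for the affine-gap backend on short inputs
_AFFINE_MAX_LEN = 10_000


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "Interval") -> "Interval | None":
        s, e = max(self.start, other.start), min(self.end, other.end)
        return Interval(s, e) if s < e else None

    def reciprocal_overlap(self, other: "Interval") -> float:
        """Fraction of the *longer* interval covered by the intersection."""
        inter = self.intersection(other)
        if inter is None:
            return 0.0
        denom = max(len(self), len(other), 1)
        return len(inter) / denom

    def to_json(self) -> list[int]:
        return [self.start, self.end]


@dataclass
class GeneModel:
    """Exon/CDS annotation of one gene copy, in locus coordinates."""

    name: str
    strand: str
    exons: list[Interval]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ex = sorted(self.exons)
        if ex != list(self.exons):
            raise ValueError("exons must be sorted in genomic order")
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons {a} and {b}")
        if not self.cds_start < self.cds_end:
            raise ValueError("cds_start must be < cds_end")
        if not any(e.contains(self.cds_start) for e in ex):
            raise ValueError("cds_start not inside any exon")
        if not any(e.contains(self.cds_end - 1) for e in ex):
            raise ValueError("cds_end not inside any exon")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "strand": self.strand,
            "exons": [e.to_json() for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            name=d["name"],
            strand=d["strand"],
            exons=[Interval(*e) for e in d["exons"]],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
        )


class BlockAlignment:
    """Global pairwise alignment of two homologous sequences.

    Stores, per aligned column, the index into sequence A and sequence B
    (or -1 for a gap), and exposes a monotone position map between the two
    coordinate frames.
    """

    def __init__(self, seq_a: str, seq_b: str, a_idx: np.ndarray, b_idx: np.ndarray):
        self.seq_a = seq_a
        self.seq_b = seq_b
        self.a_idx = np.asarray(a_idx, dtype=np.int64)
        self.b_idx = np.asarray(b_idx, dtype=np.int64)
        if self.a_idx.shape != self.b_idx.shape:
            raise ValueError("column index arrays differ in length")
        match_mask = (self.a_idx >= 0) & (self.b_idx >= 0)
        self._pairs_a = self.a_idx[match_mask]
        self._pairs_b = self.b_idx[match_mask]

    @property
    def n_columns(self) -> int:
        return len(self.a_idx)

    @property
    def n_gap_columns(self) -> int:
        return int(np.sum((self.a_idx < 0) | (self.b_idx < 0)))

    def match_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Paired (pos_A, pos_B) arrays over non-gap columns, both monotone."""
        return self._pairs_a, self._pairs_b

    def map_a_to_b(self, pos_a: int) -> int | None:
        """B-frame position aligned to ``pos_a``; None if ``pos_a`` is gapped."""
        i = np.searchsorted(self._pairs_a, pos_a)
        if i < len(self._pairs_a) and self._pairs_a[i] == pos_a:
            return int(self._pairs_b[i])
        return None

    def map_b_to_a(self, pos_b: int) -> int | None:
        i = np.searchsorted(self._pairs_b, pos_b)
        if i < len(self._pairs_b) and self._pairs_b[i] == pos_b:
            return int(self._pairs_a[i])
        return None


def _validate_seq(seq: str, alphabet: str, which: str) -> None:
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    allowed = _DNA if alphabet == "dna" else _PROTEIN
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"sequence {which} contains characters outside the {alphabet} "
            f"alphabet: {sorted(bad)!r}"
        )


def _align_affine(seq_a: str, seq_b: str) -> BlockAlignment:
    """Affine-gap global alignment (match +1, mismatch -1, open -4, extend -1)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
    )
    aln = next(iter(aligner.align(seq_a, seq_b)))  # first = deterministic tie-break
    a_idx: list[int] = []
    b_idx: list[int] = []
    coords = aln.coordinates  # shape (2, n_segments+1)
    for k in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, k]), int(coords[0, k + 1])
        b0, b1 = int(coords[1, k]), int(coords[1, k + 1])
        if a1 > a0 and b1 > b0:  # diagonal
            a_idx.extend(range(a0, a1))
            b_idx.extend(range(b0, b1))
        elif a1 > a0:  # gap in B
            a_idx.extend(range(a0, a1))
            b_idx.extend([-1] * (a1 - a0))
        else:  # gap in A
            a_idx.extend([-1] * (b1 - b0))
            b_idx.extend(range(b0, b1))
    return BlockAlignment(seq_a, seq_b, np.array(a_idx), np.array(b_idx))


def _align_affine_banded(seq_a: str, seq_b: str, band: int) -> BlockAlignment:
    """Banded Gotoh alignment with the same scoring as the exact backend
    (match +1, mismatch -1, gap open -4, extend -1).

    The band is centred on the main diagonal, which is appropriate for the
    near-equal-length, high-identity homology blocks this package targets;
    the caller guarantees |len(A) - len(B)| is well inside the band.
    """
    match, mismatch, gap_open, gap_ext = 1, -1, -4, -1
    n, m = len(seq_a), len(seq_b)
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    width = 2 * band + 1
    neg = -(10**9)

    # k indexes the diagonal offset: j = i + (k - band)
    M = np.full((n + 1, width), neg, dtype=np.int32)
    Ix = np.full((n + 1, width), neg, dtype=np.int32)  # gap in B (consumes A)
    Iy = np.full((n + 1, width), neg, dtype=np.int32)  # gap in A (consumes B)
    ptr_m = np.zeros((n + 1, width), dtype=np.uint8)  # 0=M,1=Ix,2=Iy
    ptr_x = np.zeros((n + 1, width), dtype=np.uint8)
    ptr_y = np.zeros((n + 1, width), dtype=np.uint8)

    M[0, band] = 0
    for k in range(band + 1, width):
        j = k - band
        if j <= m:
            Iy[0, k] = gap_open + gap_ext * (j - 1)
            ptr_y[0, k] = 2
    ks = np.arange(width)
    for i in range(1, n + 1):
        js = i + ks - band
        inside = (js >= 1) & (js <= m)
        j_idx = np.clip(js - 1, 0, m - 1)
        sub = np.where(a[i - 1] == b[j_idx], match, mismatch)
        both_n = (a[i - 1] == ord("N")) | (b[j_idx] == ord("N"))
        sub = np.where(both_n, mismatch, sub)

        # diagonal: same k in the previous row
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        best_prev = np.maximum(prev_m, np.maximum(prev_x, prev_y))
        src = np.where(prev_m >= np.maximum(prev_x, prev_y), 0,
                       np.where(prev_x >= prev_y, 1, 2))
        M[i] = np.where(inside, best_prev + sub, neg)
        ptr_m[i] = src

        # Ix: consume A, j fixed -> k shifts by +1 in the previous row
        up_m = np.concatenate([prev_m[1:], [neg]])
        up_x = np.concatenate([prev_x[1:], [neg]])
        open_x = up_m + gap_open
        ext_x = up_x + gap_ext
        Ix[i] = np.where(js >= 0, np.maximum(open_x, ext_x), neg)
        Ix[i] = np.where(js <= m, Ix[i], neg)
        ptr_x[i] = np.where(open_x >= ext_x, 0, 1)

        # Iy: consume B, same row -> k-1 in the current row (sequential scan)
        row_m, row_x = M[i], Ix[i]
        iy_row = np.full(width, neg, dtype=np.int64)
        py_row = np.zeros(width, dtype=np.uint8)
        for k in range(1, width):
            if not inside[k]:
                continue
            open_y = row_m[k - 1] + gap_open
            ext_y = iy_row[k - 1] + gap_ext
            if open_y >= ext_y:
                iy_row[k], py_row[k] = open_y, 0
            else:
                iy_row[k], py_row[k] = ext_y, 2
        Iy[i] = iy_row
        ptr_y[i] = py_row

    k_end = m - n + band
    if not 0 <= k_end < width:
        raise ValueError("length difference exceeds the alignment band")
    scores = {0: M[n, k_end], 1: Ix[n, k_end], 2: Iy[n, k_end]}
    state = max(scores, key=lambda s: (scores[s], -s))

    a_idx: list[int] = []
    b_idx: list[int] = []
    i, k = n, k_end
    while i > 0 or (k - band + i) > 0:
        j = i + k - band
        if state == 0:
            if i == 0 or j == 0:
                break
            a_idx.append(i - 1)
            b_idx.append(j - 1)
            state = int(ptr_m[i, k])
            i -= 1  # k unchanged: diagonal
        elif state == 1:
            a_idx.append(i - 1)
            b_idx.append(-1)
            state = int(ptr_x[i, k])
            i -= 1
            k += 1
        else:
            a_idx.append(-1)
            b_idx.append(j - 1)
            state = int(ptr_y[i, k])
            k -= 1
        if i == 0 and (k - band + i) == 0:
            break
    a_idx.reverse()
    b_idx.reverse()
    return BlockAlignment(seq_a, seq_b, np.array(a_idx), np.array(b_idx))


def _align_edlib(seq_a: str, seq_b: str) -> BlockAlignment:
    """Banded Needleman-Wunsch via edlib; used for long inputs."""
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    a_idx: list[int] = []
    b_idx: list[int] = []
    i = j = 0
    for n, op in _iter_cigar(res["cigar"]):
        if op in "=XM":
            a_idx.extend(range(i, i + n))
            b_idx.extend(range(j, j + n))
            i += n
            j += n
        elif op == "I":  # insertion in B relative to A (consumes B)
            a_idx.extend([-1] * n)
            b_idx.extend(range(j, j + n))
            j += n
        elif op == "D":  # deletion in B relative to A (consumes A)
            a_idx.extend(range(i, i + n))
            b_idx.extend([-1] * n)
            i += n
        else:  # pragma: no cover
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return BlockAlignment(seq_a, seq_b, np.array(a_idx), np.array(b_idx))


def _iter_cigar(cigar: str) -> Iterator[tuple[int, str]]:
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


_BAND = 100


def align_paralogs(seq_a: str, seq_b: str, alphabet: str = "dna") -> BlockAlignment:
    """Globally align two paralogous sequences with affine gap costs
    (match +1, mismatch -1, gap open -4, extend -1).

    The full dynamic program is used up to 10 kb per sequence; longer
    near-equal-length inputs use a banded version of the same recurrence
    (the homology blocks this package targets are >=80% identical, far
    inside the band), and inputs whose lengths differ by more than the
    band fall back to a banded edit-distance alignment.  Deterministic for
    fixed inputs.
    """
    _validate_seq(seq_a, alphabet, "A")
    _validate_seq(seq_b, alphabet, "B")
    if max(len(seq_a), len(seq_b)) <= _AFFINE_MAX_LEN:
        return _align_affine(seq_a, seq_b)
    if abs(len(seq_a) - len(seq_b)) <= _BAND // 2:
        return _align_affine_banded(seq_a, seq_b, band=_BAND)
    return _align_edlib(seq_a, seq_b)


@dataclass(frozen=True)
class PSV:
    """One paralog-specific variant: a mismatch column of the block alignment."""

    pos_a: int
    pos_b: int
    base_a: str
    base_b: str
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise ValueError("PSV bases must differ between the paralogs")


class PSVTable:
    """All PSVs of a homology block, sorted by A-frame position.

    Provides O(log n) lookup of the PSVs overlapped by an interval in either
    coordinate frame.
    """

    def __init__(self, psvs: Sequence[PSV]):
        psvs = sorted(psvs, key=lambda p: p.pos_a)
        self.psvs: list[PSV] = list(psvs)
        self.pos_a = np.array([p.pos_a for p in psvs], dtype=np.int64)
        self.pos_b = np.array([p.pos_b for p in psvs], dtype=np.int64)
        if len(self.pos_b) > 1 and not np.all(np.diff(self.pos_b) > 0):
            raise ValueError("PSV position map must be monotone in both frames")

    def __len__(self) -> int:
        return len(self.psvs)

    def __iter__(self) -> Iterator[PSV]:
        return iter(self.psvs)

    def __getitem__(self, i: int) -> PSV:
        return self.psvs[i]

    def indices_in_a(self, iv: Interval) -> np.ndarray:
        lo = np.searchsorted(self.pos_a, iv.start, side="left")
        hi = np.searchsorted(self.pos_a, iv.end, side="left")
        return np.arange(lo, hi)

    def indices_in_b(self, iv: Interval) -> np.ndarray:
        lo = np.searchsorted(self.pos_b, iv.start, side="left")
        hi = np.searchsorted(self.pos_b, iv.end, side="left")
        return np.arange(lo, hi)

    def restrict_a(self, iv: Interval) -> "PSVTable":
        """The sub-table of PSVs whose A-frame position lies in ``iv``."""
        return PSVTable([self.psvs[i] for i in self.indices_in_a(iv)])

    def swapped(self) -> "PSVTable":
        """The same table with the roles of the two paralogs exchanged."""
        return PSVTable(
            [PSV(p.pos_b, p.pos_a, p.base_b, p.base_a, p.block_id) for p in self.psvs]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pos_A": self.pos_a,
                "pos_B": self.pos_b,
                "base_A": [p.base_a for p in self.psvs],
                "base_B": [p.base_b for p in self.psvs],
                "block_id": [p.block_id for p in self.psvs],
            }
        )


def compute_psv_table(
    alignment: BlockAlignment,
    block_id: int = 0,
    offset_a: int = 0,
    offset_b: int = 0,
) -> PSVTable:
    """Extract the PSV table from a block alignment.

    One PSV per mismatch column; gap columns are excluded, as are columns
    involving the ambiguity character N (N never forms a PSV).  ``offset_a``
    and ``offset_b`` shift block-local coordinates into locus coordinates.
    """
    pa, pb = alignment.match_columns()
    psvs = []
    for i, j in zip(pa.tolist(), pb.tolist()):
        a, b = alignment.seq_a[i], alignment.seq_b[j]
        if a != b and a != "N" and b != "N":
            psvs.append(PSV(i + offset_a, j + offset_b, a, b, block_id))
    return PSVTable(psvs)


def sequence_identity(alignment: BlockAlignment) -> float:
    """Matches over non-gap aligned columns, in [0, 1].

    Gap columns are excluded from the denominator; for equal-length gap-free
    alignments this equals positional identity.
    """
    pa, pb = alignment.match_columns()
    if len(pa) == 0:
        raise ValueError("alignment has no non-gap columns; identity undefined")
    a = np.frombuffer(alignment.seq_a.encode(), dtype=np.uint8)[pa]
    b = np.frombuffer(alignment.seq_b.encode(), dtype=np.uint8)[pb]
    return float(np.mean(a == b))


@dataclass
class HomologyBlock:
    """A pair of homologous intervals on the locus, with their alignment."""

    interval_a: Interval
    interval_b: Interval
    identity: float
    alignment: BlockAlignment | None = None
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.interval_a.overlaps(self.interval_b):
            raise ValueError("homology block intervals must be disjoint")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.alignment is not None:
            obs = sequence_identity(self.alignment)
            if abs(obs - self.identity) > 1e-9:
                raise ValueError(
                    f"stored identity {self.identity} != alignment identity {obs}"
                )


HAPLOTYPE_KINDS = ("REF", "T2_2", "T3_0")


@dataclass
class HaplotypeDefinition:
    """One 3'-UTR transposition haplotype of the locus.

    ``kind`` REF is the reference arrangement; T2_2 and T3_0 are the short
    (2.2 kb) and long (3.0 kb) transpositions, in which the acceptor segment
    of the A-gene 3' UTR is replaced by the homologous donor segment from the
    B-gene 3' UTR.  The two transpositions share the 5' breakpoint region but
    have distinct 3' breakpoint regions.
    """

    kind: str
    five_prime_region: Interval
    three_prime_region: Interval
    acceptor_segment: Interval  # A-frame
    donor_segment: Interval  # B-frame

    def __post_init__(self) -> None:
        if self.kind not in HAPLOTYPE_KINDS:
            raise ValueError(f"unknown haplotype kind {self.kind!r}")


ALLELE_LABELS = tuple("ABCDEFGH") + ("NOVEL",)
BACKGROUNDS = ("REF", "T2_2", "T3_0", "UNDETERMINED")


@dataclass
class AlleleDefinition:
    """Catalog entry for one deletion allele (letter code A-H)."""

    label: str
    regions: list[Interval]  # A-frame breakpoint-region intervals
    fragment_order: list[str]
    background: str

    def __post_init__(self) -> None:
        if self.label not in ALLELE_LABELS:
            raise ValueError(f"unknown allele label {self.label!r}")
        if self.background not in BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        if len(self.fragment_order) != len(self.regions) + 1:
            raise ValueError(
                "fragment_order must have one more entry than regions "
                f"({len(self.fragment_order)} vs {len(self.regions)})"
            )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "regions": [r.to_json() for r in self.regions],
            "fragment_order": self.fragment_order,
            "background": self.background,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleDefinition":
        return cls(
            label=d["label"],
            regions=[Interval(*r) for r in d["regions"]],
            fragment_order=list(d["fragment_order"]),
            background=d["background"],
        )


@dataclass
class ParalogLocus:
    """The full locus: sequence, the two gene models, and homology blocks."""

    sequence: str
    gene_a: GeneModel
    gene_b: GeneModel
    blocks: list[HomologyBlock]
    build_label: str = "synthetic-v1"
    haplotypes: dict[str, HaplotypeDefinition] = field(default_factory=dict)
    #: A-frame interval where PSV readout is reliable for breakpoint calling
    #: (the high-identity gene + UTR core; in low-identity flanks the register
    #: of a unit-cost alignment drifts between informative sites).  None means
    #: the whole block.
    informative_region: Interval | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for gene in (self.gene_a, self.gene_b):
            if gene.span.end > n:
                raise ValueError(f"gene {gene.name} extends past the locus end")
        for gene, attr in ((self.gene_a, "interval_a"), (self.gene_b, "interval_b")):
            covered = any(
                getattr(b, attr).start <= gene.span.start
                and gene.span.end <= getattr(b, attr).end
                for b in self.blocks
            )
            if self.blocks and not covered:
                raise ValueError(f"gene {gene.name} is not covered by any block")

    @property
    def block(self) -> HomologyBlock:
        """The principal homology block (the one holding both gene bodies)."""
        return self.blocks[0]

    @property
    def frame_delta(self) -> int:
        """Offset from A-frame to B-frame coordinates for the principal block.

        Only defined when the two block intervals have equal length (the
        substitution-only synthetic regime); general loci must go through the
        block alignment's position map instead.
        """
        b = self.block
        if len(b.interval_a) != len(b.interval_b):
            raise ValueError("frame_delta undefined for unequal-length blocks")
        return b.interval_b.start - b.interval_a.start

    def a_to_b(self, pos_a: int) -> int:
        return pos_a + self.frame_delta

    def b_to_a(self, pos_b: int) -> int:
        return pos_b - self.frame_delta

    def gene_models_json(self) -> str:
        return json.dumps(
            {"gene_A": self.gene_a.to_dict(), "gene_B": self.gene_b.to_dict()},
            indent=2,
        )
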