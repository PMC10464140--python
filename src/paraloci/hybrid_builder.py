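"""In-frame hybrid gene and protein construction.

A crossover in intron *n* of two equal-architecture paralogs fuses the
coding exons 1..n of gene A to exons n+1..end of gene B.  Because the
junction may fall between codon positions, the junction codon can take
nucleotides from both genes; the hybrid is therefore assembled at the
nucleotide level and translated as a whole, never exon-by-exon.  (The
classic example: a junction codon taking its first two nucleotides from
the last exon of the A side and its third from the first B-side exon can
remain synonymous even when the B-side nucleotide differs.)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table

from .locus_model import GeneModel, ParalogLocus

__all__ = [
    "TranscriptModel",
    "HybridSpec",
    "ProteinDiff",
    "FrameError",
    "PrematureStopError",
    "build_hybrid_cds",
    "translate",
    "protein_diff",
    "positional_identity",
    "transcript_from_gene",
    "load_toy_transcripts",
    "load_reference_proteins",
    "fetch_reference_proteins",
]

_DATA_DIR = Path(__file__).parent / "data"


class FrameError(ValueError):
    """Coding sequence length or junction phase breaks the reading frame."""


class PrematureStopError(ValueError):
    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon {codon_index + 1}")


@dataclass
class TranscriptModel:
    """Coding exon structure of one transcript.

    ``exons`` holds the coding portion of each exon, 5'->3' in transcript
    order; the frame offset of exon *i* is the cumulative coding length of
    exons before it, modulo 3.
    """

    name: str
    exons: list[str]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript must have at least one coding exon")
        if self.cds_length % 3 != 0:
            raise FrameError(
                f"{self.name}: coding length {self.cds_length} is not a "
                "multiple of 3"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds(self) -> str:
        return "".join(self.exons)

    @property
    def cds_length(self) -> int:
        return len(self.cds)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - (1 if self.cds[-3:] in _STOPS else 0)

    def frame_offset(self, exon_index: int) -> int:
        """Frame phase at the start of exon ``exon_index`` (0-based)."""
        return sum(len(e) for e in self.exons[:exon_index]) % 3

    def to_dict(self) -> dict:
        return {"name": self.name, "exons": list(self.exons)}

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(name=d["name"], exons=list(d["exons"]))


@dataclass
class HybridSpec:
    """Hybrid with the crossover in intron ``junction_intron`` (1-based).

    ``junction_intron = n`` keeps coding exons 1..n of ``source_a`` and
    appends exons n+1..end of ``source_b``; n = 0 gives wildtype B and
    n = n_exons gives wildtype A.
    """

    junction_intron: int
    source_a: TranscriptModel
    source_b: TranscriptModel

    def __post_init__(self) -> None:
        if self.source_a.n_exons != self.source_b.n_exons:
            raise ValueError(
                "hybrid construction requires equal exon counts "
                f"({self.source_a.n_exons} vs {self.source_b.n_exons})"
            )
        if not 0 <= self.junction_intron <= self.source_a.n_exons:
            raise ValueError(
                f"junction intron {self.junction_intron} outside "
                f"[0, {self.source_a.n_exons}]"
            )


def build_hybrid_cds(spec: HybridSpec) -> str:
    """Nucleotide-level concatenation of the two coding sources.

    Refuses (with both phases reported) when the exon boundary phases at
    the junction differ between the two transcripts, which would shift the
    reading frame of the B-side exons.
    """
    n = spec.junction_intron
    phase_a = spec.source_a.frame_offset(n) if n < spec.source_a.n_exons else (
        spec.source_a.cds_length % 3
    )
    phase_b = spec.source_b.frame_offset(n) if n < spec.source_b.n_exons else (
        spec.source_b.cds_length % 3
    )
    if phase_a != phase_b:
        raise FrameError(
            f"junction in intron {n} is out of frame: phase {phase_a} in "
            f"{spec.source_a.name} vs phase {phase_b} in {spec.source_b.name}"
        )
    return "".join(spec.source_a.exons[:n]) + "".join(spec.source_b.exons[n:])


_STOPS = set(standard_dna_table.stop_codons)
_CODON_TABLE = dict(standard_dna_table.forward_table)


def translate(cds: str, require_stop: bool = True,
              allow_internal_stops: bool = False) -> str:
    """Standard-genetic-code translation; terminal stop stripped.

    Internal stops raise (or translate to ``*`` when
    ``allow_internal_stops``); a missing start codon is a warning only, so
    toy coding fragments translate cleanly.
    """
    if len(cds) % 3 != 0:
        raise FrameError(f"coding length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    elif require_stop:
        raise FrameError("coding sequence does not end with a stop codon")
    aas = []
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            if allow_internal_stops:
                aas.append("*")
                continue
            raise PrematureStopError(i)
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at codon {i + 1}")
        aas.append(aa)
    protein = "".join(aas)
    if protein and not protein.startswith("M"):
        warnings.warn("coding sequence does not begin with a start codon",
                      stacklevel=2)
    return protein


@dataclass
class ProteinDiff:
    """Positionwise differences between two equal-length proteins."""

    positions: list[tuple[int, str, str]]  # (1-based index, wildtype, hybrid)

    @property
    def n_diff(self) -> int:
        return len(self.positions)


def protein_diff(wildtype: str, hybrid: str) -> ProteinDiff:
    """Positionwise amino-acid differences (1-based positions).

    Raises on unequal lengths rather than truncating silently; the hybrids
    this package builds preserve length whenever the two paralog proteins
    are equally long.
    """
    if len(wildtype) != len(hybrid):
        raise ValueError(
            f"protein lengths differ ({len(wildtype)} vs {len(hybrid)}); "
            "positionwise comparison undefined"
        )
    positions = [
        (i + 1, w, h) for i, (w, h) in enumerate(zip(wildtype, hybrid)) if w != h
    ]
    return ProteinDiff(positions)


def positional_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("positional identity requires equal lengths")
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def transcript_from_gene(locus: ParalogLocus, gene: GeneModel) -> TranscriptModel:
    """Extract the coding exon portions of a gene from its locus sequence."""
    exons = []
    for ex in gene.exons:
        s = max(ex.start, gene.cds_start)
        e = min(ex.end, gene.cds_end)
        if s < e:
            exons.append(locus.sequence[s:e])
    if gene.strand == "-":
        from .synthetic_data import revcomp

        exons = [revcomp(e) for e in reversed(exons)]
    return TranscriptModel(name=gene.name, exons=exons)


def load_toy_transcripts() -> tuple[TranscriptModel, TranscriptModel]:
    """The packaged toy paralog transcript pair used in examples and tests."""
    with open(_DATA_DIR / "toy_transcripts.json") as fh:
        d = json.load(fh)
    return (
        TranscriptModel.from_dict(d["transcript_A"]),
        TranscriptModel.from_dict(d["transcript_B"]),
    )


_UNIPROT = {
    "P51800": "clc_ka_P51800.fasta",
    "P51801": "clc_kb_P51801.fasta",
}


def fetch_reference_proteins(dest_dir: Path | str | None = None) -> dict[str, Path]:
    """Optional one-time download of the two reference channel proteins.

    Fetches UniProt P51800 (ClC-Ka) and P51801 (ClC-Kb) FASTAs into the
    package data directory (or ``dest_dir``) for the real-locus hybrid
    checks.  Requires network access; everything else in the package runs
    without it.
    """
    import urllib.request

    dest = Path(dest_dir) if dest_dir is not None else _DATA_DIR
    dest.mkdir(parents=True, exist_ok=True)
    out = {}
    for acc, fname in _UNIPROT.items():
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
        path = dest / fname
        with urllib.request.urlopen(url, timeout=30) as resp:
            path.write_bytes(resp.read())
        out[acc] = path
    return out


def load_reference_proteins(data_dir: Path | str | None = None) -> dict[str, str]:
    """Load the fetched reference protein sequences (see
    :func:`fetch_reference_proteins`).  Raises FileNotFoundError with a
    pointer to the fetch step when they are absent."""
    from Bio import SeqIO

    src = Path(data_dir) if data_dir is not None else _DATA_DIR
    out = {}
    for acc, fname in _UNIPROT.items():
        path = src / fname
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found; run "
                "paraloci.hybrid_builder.fetch_reference_proteins() once "
                "(requires network access) to obtain the reference proteins"
            )
        rec = next(SeqIO.parse(str(path), "fasta"))
        out[acc] = str(rec.seq)
    return out
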