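"""File formats: FASTA/FASTQ, PSV tables, BED, depth TSV, and VCF output.

One conversion layer owns the coordinate duality: everything is 0-based
half-open in memory and in BED; PSV TSV files, VCF and human-readable
reports are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus_model import GeneModel, Interval, PSV, PSVTable, ParalogLocus

__all__ = [
    "SeqRead",
    "read_sequences",
    "write_sequences",
    "write_psv_table",
    "read_psv_table",
    "write_regions_bed",
    "read_depth_tsv",
    "write_depth_tsv",
    "SVRecord",
    "write_sv_output",
]


@dataclass
class SeqRead:
    """One sequence record (FASTA) with optional qualities (FASTQ)."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SeqRead]:
    """Read FASTA or FASTQ records (format inferred from the suffix when
    not given).  Malformed records raise with the offending file named."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix in (".fastq", ".fq") else "fasta"
    out = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            out.append(SeqRead(rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc
    return out


def write_sequences(records, path: str | Path, fmt: str | None = None) -> None:
    """Write FASTA (80-column wrapped) or FASTQ.  Accepts SeqRead objects or
    anything with read_id/sequence (and quality for FASTQ)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix in (".fastq", ".fq") else "fasta"
    seqrecords = []
    for r in records:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            qual = getattr(r, "quality", None)
            if qual is None:
                raise ValueError(f"{r.read_id}: FASTQ output requires qualities")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        seqrecords.append(rec)
    with open(path, "w") as fh:
        if fmt == "fasta":
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
            writer.write_file(seqrecords)
        else:
            SeqIO.write(seqrecords, fh, "fastq")


def read_locus(fasta_path: str | Path, gene_models_path: str | Path,
               build_label: str = "external") -> ParalogLocus:
    """Load a locus from a FASTA (single record) plus a JSON gene-model
    file with entries ``gene_A`` and ``gene_B``
    ({name, strand, exons[[start,end)...], cds_start, cds_end})."""
    records = read_sequences(fasta_path, "fasta")
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one locus record, "
            f"got {len(records)}"
        )
    with open(gene_models_path) as fh:
        d = json.load(fh)
    return ParalogLocus(
        sequence=records[0].sequence,
        gene_a=GeneModel.from_dict(d["gene_A"]),
        gene_b=GeneModel.from_dict(d["gene_B"]),
        blocks=[],
        build_label=build_label,
    )


def write_psv_table(table: PSVTable, path: str | Path) -> None:
    """PSV table as TSV, 1-based positions in the file."""
    df = table.to_dataframe()
    df["pos_A"] = df["pos_A"] + 1
    df["pos_B"] = df["pos_B"] + 1
    df.to_csv(path, sep="\t", index=False)


def read_psv_table(path: str | Path) -> PSVTable:
    df = pd.read_csv(path, sep="\t")
    return PSVTable(
        [
            PSV(int(r.pos_A) - 1, int(r.pos_B) - 1, r.base_A, r.base_B,
                int(r.block_id))
            for r in df.itertuples(index=False)
        ]
    )


def write_regions_bed(regions, path: str | Path, name_prefix: str = "bp") -> None:
    """Breakpoint regions as BED (0-based half-open), one line per region."""
    with open(path, "w") as fh:
        for i, reg in enumerate(regions):
            fh.write(
                f"locus\t{reg.region_a.start}\t{reg.region_a.end}\t"
                f"{name_prefix}{i}_{reg.label_from}>{reg.label_to}\t"
                f"{reg.n_support}\t+\n"
            )


def read_depth_tsv(path: str | Path) -> list[tuple[Interval, float]]:
    """Depth profile TSV: chrom, start, end, depth (0-based half-open)."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "start", "end", "depth"], comment="#")
    return [
        (Interval(int(r.start), int(r.end)), float(r.depth))
        for r in df.itertuples(index=False)
    ]


def write_depth_tsv(windows, path: str | Path, chrom: str = "locus") -> None:
    with open(path, "w") as fh:
        for iv, depth in windows:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{depth:.6g}\n")


@dataclass
class SVRecord:
    """One symbolic structural-variant record for VCF output.

    POS/END are 0-based here and converted on write; the breakpoint-region
    uncertainty is encoded as confidence intervals around POS and END
    (CIPOS/CIEND), following the standard convention for imprecise variants.
    """

    locus_name: str
    pos: int
    end: int
    ci_pos: tuple[int, int]
    ci_end: tuple[int, int]
    sv_type: str = "DEL"
    allele_class: str = "NOVEL"
    background: str = "UNDETERMINED"
    genotype: str = "1/1"
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.end < self.pos:
            raise ValueError("END must be >= POS")
        if not (self.ci_pos[0] <= 0 <= self.ci_pos[1]):
            raise ValueError("CIPOS must bracket POS")
        if not (self.ci_end[0] <= 0 <= self.ci_end[1]):
            raise ValueError("CIEND must bracket END")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=paraloci
##contig=<ID={contig},length={length}>
##ALT=<ID=DEL,Description="Deletion relative to the reference locus">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS (breakpoint region bounds)">
##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END (breakpoint region bounds)">
##INFO=<ID=ALLELECLASS,Number=1,Type=String,Description="Catalog class of the structural allele (A-H or NOVEL)">
##INFO=<ID=BACKGROUND,Number=1,Type=String,Description="Transposition haplotype background (REF, T2_2, T3_0, UNDETERMINED)">
##INFO=<ID=EVENT,Number=1,Type=String,Description="Identifier shared by records of one complex allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_sv_output(
    calls: list[SVRecord],
    path: str | Path,
    contig: str = "locus",
    contig_length: int = 0,
    sample: str = "sample",
    reference_base: str = "N",
) -> None:
    """Symbolic-allele VCF with region uncertainty in CIPOS/CIEND.

    Unsorted calls are sorted automatically (with a warning via logging).
    An empty call set yields a valid header-only file.
    """
    import logging

    ordered = sorted(calls, key=lambda c: (c.pos, c.end))
    if ordered != calls:
        logging.getLogger(__name__).warning("SV records were unsorted; sorting")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=contig_length,
                                    sample=sample))
        for i, c in enumerate(ordered):
            info = (
                f"SVTYPE={c.sv_type};END={c.end};"
                f"CIPOS={c.ci_pos[0]},{c.ci_pos[1]};"
                f"CIEND={c.ci_end[0]},{c.ci_end[1]};"
                f"ALLELECLASS={c.allele_class};BACKGROUND={c.background}"
            )
            if c.event_id:
                info += f";EVENT={c.event_id}"
            fh.write(
                f"{contig}\t{c.pos + 1}\tsv{i}\t{reference_base}\t"
                f"<{c.sv_type}>\t.\tPASS\t{info}\tGT\t{c.genotype}\n"
            )


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON artifact (sorted keys, stable float formatting)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
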