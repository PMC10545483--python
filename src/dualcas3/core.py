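"""Shared genomic data types and readers/writers.

All internal coordinates are 0-based, half-open ``[start, end)``. External
formats that use other conventions (VCF's 1-based positions, GFF3's 1-based
closed intervals) are converted at the I/O boundary and nowhere else.

Sequence alphabet is restricted to ``A C G T N``; lowercase input is
uppercased and every other character (IUPAC ambiguity codes included)
collapses to ``N``. An ``N`` never matches a guide base downstream, which
makes site calling conservative at ambiguous reference positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "GenomeSequence",
    "Exon",
    "ExonModel",
    "VariantCall",
    "read_fasta",
    "write_fasta",
    "read_variants",
    "write_cnv_table",
    "read_exon_model",
    "revcomp",
    "normalize_sequence",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
_STRANDS = {"+", "-", "."}

CNV_KINDS = {"loss": "cnv_loss", "gain": "cnv_gain"}


class FormatError(ValueError):
    """Raised for malformed input files."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GenomeSequence:
    """In-memory genome: mapping of contig name to an ACGTN string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            if not set(seq) <= _VALID:
                self.contigs[name] = normalize_sequence(seq)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.contigs[interval.contig][interval.start : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Lowercase is normalized to uppercase and non-ACGTN characters map to N.
    Duplicate headers and empty files raise :class:`FormatError`.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        contigs[rec.id] = normalize_sequence(str(rec.seq))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    """Write contigs sorted by name, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(genome.contigs[name]), id=name, description="")
        for name in sorted(genome.contigs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """A CNV, SNV or indel call in internal coordinates.

    CNVs carry their two breakpoints as ``interval``; point variants carry a
    width-1 interval whose ``start`` is the (left-aligned) variant position.
    """

    kind: str  # cnv_loss | cnv_gain | snv | indel
    interval: GenomicInterval
    sample: str = ""
    call_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"cnv_loss", "cnv_gain", "snv", "indel"}:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def is_cnv(self) -> bool:
        return self.kind.startswith("cnv")

    @property
    def position(self) -> int:
        """Representative coordinate of a point variant (left-aligned start)."""
        return self.interval.start


def _read_cnv_table(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            contig, start_s, end_s, cnv_type, call_id = fields[:5]
            sample = fields[5] if len(fields) > 5 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if cnv_type not in CNV_KINDS:
                raise FormatError(f"{path}:{lineno}: unknown CNV type {cnv_type!r}")
            calls.append(
                VariantCall(
                    kind=CNV_KINDS[cnv_type],
                    interval=GenomicInterval(contig, start, end),
                    sample=sample,
                    call_id=call_id,
                )
            )
    return calls


def _read_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref or ""
            alts = rec.alts or ()
            kind = "snv"
            for alt in alts:
                if alt is not None and len(alt) != len(ref):
                    kind = "indel"
            start = rec.pos - 1  # VCF is 1-based
            calls.append(
                VariantCall(
                    kind=kind,
                    interval=GenomicInterval(rec.chrom, start, start + max(1, len(ref))),
                    call_id=rec.id or "",
                )
            )
    return calls


def read_variants(path: str | Path, kind: str) -> list[VariantCall]:
    """Read a call set.

    ``kind="cnv"`` expects a BED-like TSV (contig, start, end, loss|gain, id);
    ``kind="snv_indel"`` expects a VCF, whose 1-based POS is shifted to the
    internal 0-based convention.
    """
    if kind == "cnv":
        return _read_cnv_table(path)
    if kind == "snv_indel":
        return _read_vcf(path)
    raise ValueError(f"kind must be 'cnv' or 'snv_indel', got {kind!r}")


def write_cnv_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = sorted(calls, key=lambda c: (c.interval.contig, c.interval.start))
    with open(path, "w") as fh:
        for c in rows:
            cnv_type = c.kind.removeprefix("cnv_")
            fh.write(
                f"{c.interval.contig}\t{c.interval.start}\t{c.interval.end}"
                f"\t{cnv_type}\t{c.call_id}\t{c.sample}\n"
            )


# ---------------------------------------------------------------------------
# Exon models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    number: int
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ExonModel:
    """One transcript's exons, ordered 5'→3' along the transcript strand."""

    gene: str
    exons: list[Exon]
    frame_offset: int = 0  # codon phase of the first exon's first base

    def __post_init__(self) -> None:
        ivs = sorted((e.interval for e in self.exons), key=lambda i: i.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise FormatError(
                    f"overlapping exons [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        strand = self.strand
        key = (lambda e: e.interval.start) if strand != "-" else (lambda e: -e.interval.start)
        self.exons = sorted(self.exons, key=key)

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand if self.exons else "."

    @property
    def numbers(self) -> list[int]:
        return [e.number for e in self.exons]

    def exon(self, number: int) -> Exon:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"no exon {number} in {self.gene}")

    def lengths(self) -> list[int]:
        return [e.length for e in self.exons]


def _read_exon_gff3(path: str | Path) -> ExonModel:
    exons: list[GenomicInterval] = []
    numbers: list[int | None] = []
    gene = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            contig, _, ftype, start_s, end_s, _, strand, _, attrs = fields[:9]
            if ftype.lower() != "exon":
                continue
            # GFF3 is 1-based closed
            exons.append(GenomicInterval(contig, int(start_s) - 1, int(end_s), strand))
            number = None
            for kv in attrs.split(";"):
                if kv.startswith(("gene=", "gene_name=", "Parent=")):
                    gene = gene or kv.split("=", 1)[1]
                elif kv.startswith("exon_number="):
                    number = int(kv.split("=", 1)[1])
            numbers.append(number)
    if not exons:
        raise FormatError(f"no exon features in {path}")
    if all(n is not None for n in numbers):
        strand = exons[0].strand
        pairs = sorted(
            zip(numbers, exons), key=lambda p: p[1].start, reverse=(strand == "-")
        )
        return ExonModel(
            gene=gene or "transcript",
            exons=[Exon(number=n, interval=iv) for n, iv in pairs],
        )
    return _number_exons(gene or "transcript", exons)


def _read_exon_bed12(path: str | Path) -> ExonModel:
    with open(path) as fh:
        lines = [l for l in fh if l.strip() and not l.startswith(("#", "track"))]
    if len(lines) != 1:
        raise FormatError(f"{path}: expected a single BED12 transcript line")
    fields = lines[0].rstrip("\n").split("\t")
    if len(fields) < 12:
        raise FormatError(f"{path}: BED12 needs 12 columns")
    contig, chrom_start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != int(fields[9]) or len(starts) != int(fields[9]):
        raise FormatError(f"{path}: blockCount disagrees with block lists")
    exons = [
        GenomicInterval(contig, chrom_start + s, chrom_start + s + sz, strand)
        for s, sz in zip(starts, sizes)
    ]
    return _number_exons(name, exons)


def _number_exons(gene: str, intervals: Sequence[GenomicInterval]) -> ExonModel:
    strand = intervals[0].strand
    ordered = sorted(intervals, key=lambda i: i.start, reverse=(strand == "-"))
    exons = [Exon(number=i + 1, interval=iv) for i, iv in enumerate(ordered)]
    return ExonModel(gene=gene, exons=exons)


def read_exon_model(path: str | Path) -> ExonModel:
    """Read one transcript's exon model from GFF3 or BED12.

    Exons are numbered 1..n in transcript (5'→3') order, so on the minus
    strand exon 1 is the rightmost interval.
    """
    p = Path(path)
    if p.suffix.lower() in {".bed", ".bed12"}:
        return _read_exon_bed12(p)
    return _read_exon_gff3(p)
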