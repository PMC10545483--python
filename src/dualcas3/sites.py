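"""Genome-wide enumeration of putative guide-binding sites.

The scanner reproduces a GGGenome-style mismatch-tolerant substring search:
a site is reported wherever (a) the PAM pattern matches exactly under IUPAC
semantics and (b) the Hamming distance between the spacer and the
protospacer, counted over non-masked positions, is at most the allowance.
The PAM is never counted toward the mismatch budget.

Two search systems are supported:

* ``cas3`` — type I-E Cascade/Cas3. 27-nt protospacer, PAM 5' of the
  protospacer (default ``AAG``), default allowance 8 mismatches, 8-bp seed
  adjacent to the PAM. Cas3 degrades DNA processively toward the PAM side,
  which fixes each site's degradation direction on the reference strand.
* ``cas9`` — SpCas9. 20-nt protospacer, 3' ``NGG`` PAM, default allowance 5.

``scan_genome`` is the production (vectorised) implementation;
``brute_force_scan`` walks every position of both strands with no indexing
or early exit and exists purely as an independent oracle for testing.

Mismatch positions are reported 1-based from the PAM-proximal end of the
spacer, the convention in which the seed region is positions 1..seed_length.
Masked positions are exempt from mismatch counting and are never reported.
An ``N`` in the genome matches no guide base and no PAM letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .core import GenomeSequence, GenomicInterval, revcomp

__all__ = [
    "GuideSpec",
    "BindingSite",
    "scan_genome",
    "brute_force_scan",
    "annotate_seed",
    "degradation_direction",
    "write_sites_bed",
    "read_sites_bed",
]

SYSTEM_DEFAULTS = {
    "cas3": dict(spacer_length=27, pam="AAG", pam_side="5prime", max_mismatches=8),
    "cas9": dict(spacer_length=20, pam="NGG", pam_side="3prime", max_mismatches=5),
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c

# IUPAC letter -> set of concrete bases it matches (N in the genome never
# matches, so sets only ever contain ACGT)
_IUPAC = {k.upper(): set(v.upper()) for k, v in ambiguous_dna_values.items()}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp_iupac(pat: str) -> str:
    return pat.translate(_IUPAC_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class GuideSpec:
    """A crRNA (cas3) or sgRNA (cas9) and its mismatch model.

    ``mask_positions`` are spacer positions (1-based from the PAM-proximal
    end) exempt from mismatch counting; the default is no mask, matching a
    plain mismatch-allowance substring search.
    """

    name: str
    system: str
    spacer: str
    pam: str | None = None
    max_mismatches: int | None = None
    seed_length: int = 8
    mask_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.system not in SYSTEM_DEFAULTS:
            raise ValueError(f"unknown system {self.system!r}")
        defaults = SYSTEM_DEFAULTS[self.system]
        spacer = self.spacer.upper()
        object.__setattr__(self, "spacer", spacer)
        if not spacer or set(spacer) - set("ACGT"):
            raise ValueError(f"spacer must be non-empty ACGT, got {self.spacer!r}")
        if self.pam is None:
            object.__setattr__(self, "pam", defaults["pam"])
        else:
            object.__setattr__(self, "pam", self.pam.upper())
        for c in self.pam:  # type: ignore[union-attr]
            if c not in _IUPAC:
                raise ValueError(f"invalid IUPAC letter {c!r} in PAM {self.pam!r}")
        if self.max_mismatches is None:
            object.__setattr__(self, "max_mismatches", defaults["max_mismatches"])
        if not 0 <= self.max_mismatches <= len(spacer):  # type: ignore[operator]
            raise ValueError("max_mismatches must be within 0..spacer length")
        if not 0 <= self.seed_length <= len(spacer):
            raise ValueError("seed_length must be within 0..spacer length")
        mask = frozenset(int(p) for p in self.mask_positions)
        if any(p < 1 or p > len(spacer) for p in mask):
            raise ValueError("mask positions must lie within 1..spacer length")
        object.__setattr__(self, "mask_positions", mask)

    @property
    def pam_side(self) -> str:
        """'5prime' (PAM upstream of protospacer) or '3prime'."""
        return SYSTEM_DEFAULTS[self.system]["pam_side"]

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    def position_to_index(self, position: int) -> int:
        """Map a 1-based PAM-proximal position to a 0-based 5'→3' spacer index."""
        if self.pam_side == "5prime":
            return position - 1
        return self.spacer_length - position

    def index_to_position(self, index: int) -> int:
        if self.pam_side == "5prime":
            return index + 1
        return self.spacer_length - index


@dataclass(frozen=True)
class BindingSite:
    """A genomic match of a guide.

    ``anchor`` is the PAM-proximal protospacer boundary, the single reference
    point from which attribution windows are measured. ``mismatch_positions``
    are 1-based from the PAM-proximal end.
    """

    guide_name: str
    system: str
    interval: GenomicInterval
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    seed_mismatch_count: int
    pam_matched: bool
    anchor: int

    def __post_init__(self) -> None:
        if self.seed_mismatch_count > self.mismatch_count:
            raise ValueError("seed mismatches cannot exceed total mismatches")

    @property
    def strand(self) -> str:
        return self.interval.strand


def _anchor_of(system: str, interval: GenomicInterval) -> int:
    """PAM-proximal protospacer boundary on the reference."""
    pam_side = SYSTEM_DEFAULTS[system]["pam_side"]
    if pam_side == "5prime":
        return interval.start if interval.strand == "+" else interval.end
    return interval.end if interval.strand == "+" else interval.start


def _make_site(
    guide: GuideSpec, contig: str, start: int, strand: str, proto_fwd: str
) -> BindingSite:
    """Build a site record given the protospacer in guide orientation."""
    positions = []
    masked = {guide.position_to_index(p) for p in guide.mask_positions}
    for i, (g, b) in enumerate(zip(guide.spacer, proto_fwd)):
        if i in masked:
            continue
        if g != b:
            positions.append(guide.index_to_position(i))
    positions.sort()
    seed_mm = sum(1 for p in positions if p <= guide.seed_length)
    interval = GenomicInterval(contig, start, start + guide.spacer_length, strand)
    return BindingSite(
        guide_name=guide.name,
        system=guide.system,
        interval=interval,
        mismatch_count=len(positions),
        mismatch_positions=tuple(positions),
        seed_mismatch_count=seed_mm,
        pam_matched=True,
        anchor=_anchor_of(guide.system, interval),
    )


def _pam_ok_array(codes: np.ndarray, pam: str, offset: int, n_windows: int) -> np.ndarray:
    """Boolean per window start: PAM at window+offset matches under IUPAC."""
    ok = np.ones(n_windows, dtype=bool)
    for j, letter in enumerate(pam):
        allowed = np.zeros(5, dtype=bool)
        for base in _IUPAC[letter]:
            allowed[_CODE[base]] = True
        ok &= allowed[codes[offset + j : offset + j + n_windows]]
    return ok


def _scan_oriented(
    codes: np.ndarray, guide: GuideSpec
) -> np.ndarray:
    """Pattern-start indices of matches in an oriented (5'→3' guide) sequence.

    The pattern is PAM+spacer for 5'-PAM systems, spacer+PAM for 3'-PAM.
    """
    L = guide.spacer_length
    plen = len(guide.pam)  # type: ignore[arg-type]
    pat_len = L + plen
    n_windows = len(codes) - pat_len + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64)
    spacer_offset = plen if guide.pam_side == "5prime" else 0
    pam_offset = 0 if guide.pam_side == "5prime" else L
    masked = {guide.position_to_index(p) for p in guide.mask_positions}
    spacer_codes = _encode(guide.spacer)
    mm = np.zeros(n_windows, dtype=np.int16)
    for i in range(L):
        if i in masked:
            continue
        mm += codes[spacer_offset + i : spacer_offset + i + n_windows] != spacer_codes[i]
    hits = mm <= guide.max_mismatches  # type: ignore[operator]
    hits &= _pam_ok_array(codes, guide.pam, pam_offset, n_windows)  # type: ignore[arg-type]
    return np.flatnonzero(hits)


def scan_genome(genome: GenomeSequence, guide: GuideSpec) -> list[BindingSite]:
    """Enumerate every binding site of ``guide`` on both strands.

    Sites are sorted by (contig, start, strand); overlapping sites on
    opposite strands are both reported.
    """
    plen = len(guide.pam)  # type: ignore[arg-type]
    L = guide.spacer_length
    sites: list[BindingSite] = []
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        total = len(seq)
        fwd_codes = _encode(seq)
        # forward strand: pattern in reference orientation
        for t in _scan_oriented(fwd_codes, guide):
            start = int(t) + (plen if guide.pam_side == "5prime" else 0)
            proto = seq[start : start + L]
            sites.append(_make_site(guide, contig, start, "+", proto))
        # reverse strand: scan the reverse complement, map back
        rc_codes = _encode(revcomp(seq))
        for t in _scan_oriented(rc_codes, guide):
            off = int(t) + (plen if guide.pam_side == "5prime" else 0)
            start = total - off - L
            proto = revcomp(seq[start : start + L])
            sites.append(_make_site(guide, contig, start, "-", proto))
    sites.sort(key=lambda s: (s.interval.contig, s.interval.start, s.strand))
    return sites


def brute_force_scan(genome: GenomeSequence, guide: GuideSpec) -> list[BindingSite]:
    """Position-by-position reference scanner; identical contract to
    :func:`scan_genome` with no indexing or early exit. Test oracle only."""
    plen = len(guide.pam)  # type: ignore[arg-type]
    L = guide.spacer_length
    masked = {guide.position_to_index(p) for p in guide.mask_positions}
    sites: list[BindingSite] = []
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else revcomp(seq)
            total = len(oriented)
            for t in range(total - (L + plen) + 1):
                if guide.pam_side == "5prime":
                    pam_seq, proto = oriented[t : t + plen], oriented[t + plen : t + plen + L]
                    proto_start = t + plen
                else:
                    proto, pam_seq = oriented[t : t + L], oriented[t + L : t + L + plen]
                    proto_start = t
                pam_match = all(
                    b in _IUPAC[p] for p, b in zip(guide.pam, pam_seq)  # type: ignore[arg-type]
                )
                if not pam_match:
                    continue
                mm = sum(
                    1
                    for i in range(L)
                    if i not in masked and proto[i] != guide.spacer[i]
                )
                if mm > guide.max_mismatches:  # type: ignore[operator]
                    continue
                start = proto_start if strand == "+" else total - proto_start - L
                sites.append(_make_site(guide, contig, start, strand, proto))
    sites.sort(key=lambda s: (s.interval.contig, s.interval.start, s.strand))
    return sites


def annotate_seed(site: BindingSite, guide: GuideSpec) -> BindingSite:
    """Recompute ``seed_mismatch_count`` from the mismatch positions."""
    seed_mm = sum(1 for p in site.mismatch_positions if p <= guide.seed_length)
    return replace(site, seed_mismatch_count=seed_mm)


def write_sites_bed(sites: Iterable[BindingSite], path) -> None:
    """BED6+ with mismatch annotations in extra columns.

    Columns: contig, start, end, guide, mismatch_count, strand, system,
    anchor, seed_mismatch_count, comma-joined mismatch positions.
    """
    rows = sorted(sites, key=lambda s: (s.interval.contig, s.interval.start, s.strand))
    with open(path, "w") as fh:
        for s in rows:
            mmpos = ",".join(str(p) for p in s.mismatch_positions) or "."
            fh.write(
                f"{s.interval.contig}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.guide_name}\t{s.mismatch_count}\t{s.strand}"
                f"\t{s.system}\t{s.anchor}\t{s.seed_mismatch_count}\t{mmpos}\n"
            )


def read_sites_bed(path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            contig, start, end, name, mm, strand, system, anchor, seed_mm, mmpos = f[:10]
            positions = () if mmpos == "." else tuple(int(x) for x in mmpos.split(","))
            sites.append(
                BindingSite(
                    guide_name=name,
                    system=system,
                    interval=GenomicInterval(contig, int(start), int(end), strand),
                    mismatch_count=int(mm),
                    mismatch_positions=positions,
                    seed_mismatch_count=int(seed_mm),
                    pam_matched=True,
                    anchor=int(anchor),
                )
            )
    return sites


def degradation_direction(site: BindingSite, invert: bool = False) -> str:
    """Reference-strand direction of Cas3 degradation from this site.

    Cas3 degrades toward the PAM-proximal side: a "+"-strand site with a 5'
    PAM degrades leftward on the reference, a "−"-strand site rightward.
    ``invert`` flips both, for probing the opposite convention.
    """
    if site.system != "cas3":
        raise ValueError("degradation direction is defined only for cas3 sites")
    direction = "left" if site.strand == "+" else "right"
    if invert:
        direction = "right" if direction == "left" else "left"
    return direction
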