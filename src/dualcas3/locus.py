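"""Deletion-junction breakpoint mapping and exon-skipping frame analysis.

Junction mapping models a Sanger-sequenced TA-clone amplicon spanning a
large deletion: the read is the reference with an internal segment excised,
possibly with a short insertion at the junction. Mapping uses exact-match
anchors (Sanger amplicons are high quality): the longest read prefix
matching the reference left flank and the longest suffix matching the right
flank delimit the junction; any unexplained middle is the insertion. When
flank homology makes the breakpoint ambiguous (microhomology) the call is
left-normalised — the deletion start is shifted 5'-ward as far as the
sequence allows, the standard left-alignment convention.

Frame analysis: skipping a contiguous internal run of exons preserves the
reading frame iff the total skipped length is a multiple of 3. Multi-exon
skipping of dystrophin exons 45-55 joins exon 44 to exon 56 in frame,
which is what makes the strategy applicable across patient deletions
anywhere inside that range.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomicInterval, ExonModel
from .sites import BindingSite

__all__ = [
    "JunctionRead",
    "BreakpointCall",
    "FrameReport",
    "UnmappableJunction",
    "map_junction",
    "left_normalize",
    "sites_retained",
    "frame_check",
    "mes_applicability",
]

DEFAULT_ANCHOR_MIN = 20


class UnmappableJunction(ValueError):
    """Read has no usable two-anchor junction against the reference."""


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class BreakpointCall:
    """A left-normalised deletion junction in reference coordinates."""

    read_id: str
    deletion: GenomicInterval
    insertion: str
    microhomology: int

    def __post_init__(self) -> None:
        if self.insertion and self.microhomology:
            raise ValueError("insertion and microhomology are mutually exclusive")


@dataclass(frozen=True)
class FrameReport:
    skipped_exons: tuple[int, ...]
    junction: str
    skipped_length: int
    in_frame: bool


def left_normalize(
    reference: str, start: int, end: int, insertion: str = ""
) -> tuple[int, int, str, int]:
    """Shift a replacement junction maximally 5'-ward.

    The junction replaces ``reference[start:end]`` with ``insertion``. All
    representations producing the same edited sequence are equivalent; the
    canonical one has the smallest ``start``. Returns
    ``(start, end, insertion, shift_count)``.
    """
    shifts = 0
    ins = insertion
    while start > 0:
        if ins:
            if ins[-1] != reference[end - 1]:
                break
            ins = reference[start - 1] + ins[:-1]
        else:
            if reference[start - 1] != reference[end - 1]:
                break
        start -= 1
        end -= 1
        shifts += 1
    return start, end, ins, shifts


def map_junction(
    read: JunctionRead,
    reference: str,
    contig: str = "ref",
    anchor_min: int = DEFAULT_ANCHOR_MIN,
) -> BreakpointCall:
    """Call the deletion junction of one amplicon read against ``reference``.

    Raises :class:`UnmappableJunction` when either flank lacks an exact
    anchor of ``anchor_min`` bases, or when the read contains no gap (e.g.
    an unedited amplicon).
    """
    r = read.sequence.upper()
    reference = reference.upper()
    if len(r) < 2 * anchor_min:
        raise UnmappableJunction(f"{read.read_id}: read shorter than two anchors")
    u = reference.find(r[:anchor_min])
    if u < 0:
        raise UnmappableJunction(f"{read.read_id}: left anchor not found in reference")
    v_tail = reference.rfind(r[-anchor_min:])
    if v_tail < 0:
        raise UnmappableJunction(f"{read.read_id}: right anchor not found in reference")
    v = v_tail + anchor_min  # reference position just past the right anchor

    # extend the left anchor to the longest exact prefix match
    p = anchor_min
    while p < len(r) and u + p < len(reference) and r[p] == reference[u + p]:
        p += 1
    # extend the right anchor to the longest exact suffix match
    s = anchor_min
    while s < len(r) and v - s - 1 >= 0 and r[len(r) - s - 1] == reference[v - s - 1]:
        s += 1

    if p + s <= len(r):
        insertion = r[p : len(r) - s]
        d_start, d_end = u + p, v - s
    else:
        # anchors overlap on the read: pure microhomologous junction
        insertion = ""
        d_start = u + p
        d_end = v - s + (p + s - len(r))
    if d_end <= d_start:
        raise UnmappableJunction(f"{read.read_id}: no deletion gap between anchors")
    d_start, d_end, insertion, shifts = left_normalize(reference, d_start, d_end, insertion)
    return BreakpointCall(
        read_id=read.read_id,
        deletion=GenomicInterval(contig, d_start, d_end),
        insertion=insertion,
        microhomology=0 if insertion else shifts,
    )


def sites_retained(call: BreakpointCall, sites: list[BindingSite]) -> dict[str, bool]:
    """Per-guide flag: is the protospacer retained (not overlapped by the
    deletion)? Half-open overlap, so an abutting deletion retains the site."""
    out: dict[str, bool] = {}
    for site in sites:
        lost = site.interval.overlaps(call.deletion)
        out[site.guide_name] = not lost
    return out


def frame_check(exon_model: ExonModel, skipped_exons: list[int] | tuple[int, ...]) -> FrameReport:
    """Reading-frame consequence of skipping a contiguous internal exon run.

    ``in_frame`` iff the summed skipped length is divisible by 3 — the
    junction's codon phases then match by the cumulative-length argument.
    """
    skipped = sorted(set(int(e) for e in skipped_exons))
    if not skipped:
        raise ValueError("no exons to skip")
    numbers = exon_model.numbers
    for e in skipped:
        if e not in numbers:
            raise ValueError(f"exon {e} not in model {exon_model.gene}")
    idx = [numbers.index(e) for e in skipped]
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError("skipped exons must be contiguous in the transcript")
    if idx[0] == 0 or idx[-1] == len(numbers) - 1:
        raise ValueError("cannot skip the first or last exon (not an internal skip)")
    total = sum(exon_model.exon(e).length for e in skipped)
    left = numbers[idx[0] - 1]
    right = numbers[idx[-1] + 1]
    return FrameReport(
        skipped_exons=tuple(skipped),
        junction=f"exon {left}-exon {right}",
        skipped_length=total,
        in_frame=(total % 3 == 0),
    )


def mes_applicability(
    exon_model: ExonModel,
    patient_deletion_exons: list[int] | tuple[int, ...],
    skip_set: list[int] | tuple[int, ...],
) -> bool:
    """Does multi-exon skipping restore the frame for this patient?

    The patient already lacks ``patient_deletion_exons``; skipping
    ``skip_set`` removes every remaining exon in that range, so the final
    transcript joins the exons flanking the union. The outcome therefore
    depends only on the union of removed exons in the full model: the frame
    is restored iff that union's summed length is divisible by 3. An empty
    skip set asks whether the patient deletion alone is in frame.
    """
    patient = sorted(set(int(e) for e in patient_deletion_exons))
    skips = sorted(set(int(e) for e in skip_set))
    if not patient:
        raise ValueError("patient deletion is empty")
    if skips and not (skips[0] <= patient[0] and patient[-1] <= skips[-1]):
        raise ValueError("patient deletion lies outside the skip range")
    lo = min(patient + skips)
    hi = max(patient + skips)
    removed = [e for e in exon_model.numbers if lo <= e <= hi]
    report = frame_check(exon_model, removed)
    return report.in_frame
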