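"""Ground-truth simulator for dual-Cas3 large-deletion experiments.

Every stage of the analysis pipeline is exercised against data produced
here, with known labels. The generative model encodes the study conditions:

* **Unidirectional deletions.** Cas3 degrades DNA processively toward the
  PAM side. A deletion event starts at a random offset from the guide's
  anchor point, drawn from an exponential law whose 99th percentile is
  5 kb (mean 5000/ln 100 ≈ 1085.7 bp) — the one published constraint on
  start positions — and extends strictly in the degradation direction by a
  length drawn log-uniformly over [200 bp, 100 kb] ("a few hundred base
  pairs to a hundred kilobase pairs").
* **Dual-guide fusion.** With probability ``p_join`` the two crRNAs of a
  pair produce one spanning deletion whose endpoints scatter outward from
  each protospacer (so both protospacers are usually lost, as observed in
  sequenced junction clones); otherwise each site acts independently.
* **Background accumulation.** Passage-dependent spontaneous variants:
  CNV and SNV/indel counts are Poisson in the passage number, with the CNV
  rate calibrated so 18 passages yields ~13 de novo CNVs; positions are
  uniform over the genome (length-proportional null).
* **Droplet wells.** Positive-droplet counts are binomial with
  p = 1 - exp(-lambda) per droplet, lambda set by the per-probe copy
  concentration of the simulated population.

All randomness flows through an explicit seed; identical seeds give
identical outputs byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .core import GenomeSequence, GenomicInterval, VariantCall, write_fasta, write_cnv_table
from .ddpcr import DropletAssay, ProbePanel, DEFAULT_DROPLET_VOLUME_NL
from .sites import BindingSite, GuideSpec, degradation_direction, scan_genome
from .locus import left_normalize

__all__ = [
    "SimConfig",
    "GuidePlant",
    "DeletionEvent",
    "CloneGenotype",
    "make_genome",
    "simulate_deletion_event",
    "simulate_dual_deletion",
    "simulate_background",
    "simulate_droplet_well",
    "population_droplet_wells",
    "emit_callsets",
]

# --- study-condition defaults, collected here so they are auditable -------
OFFSET_Q99_BP = 5_000          # 99% of deletion starts fall within this
OFFSET_MEAN_BP = OFFSET_Q99_BP / math.log(100.0)   # exponential mean ≈ 1085.7
LENGTH_MIN_BP = 200            # "a few hundred base pairs"
LENGTH_MAX_BP = 100_000        # "... to a hundred kilobase pairs"
CNV_RATE_PER_PASSAGE = 13 / 18          # ~13 de novo CNVs in 18 passages
SNV_INDEL_RATE_PER_PASSAGE = 40.0       # order of the published clone totals
BACKGROUND_CNV_MIN_BP = 1_000
BACKGROUND_CNV_MAX_BP = 1_000_000
INDEL_FRACTION = 0.1


@dataclass(frozen=True)
class GuidePlant:
    """A guide copy planted into a simulated genome."""

    guide: GuideSpec
    position: int            # protospacer start (0-based)
    n_mismatches: int = 0
    contig: str = "chrSim"
    strand: str = "+"


@dataclass
class SimConfig:
    """Tunable parameters of the generative model (defaults = study conditions)."""

    genome_length: int = 500_000
    gc_fraction: float = 0.41
    contig: str = "chrSim"
    offset_mean_bp: float = OFFSET_MEAN_BP
    length_min_bp: int = LENGTH_MIN_BP
    length_max_bp: int = LENGTH_MAX_BP
    orientation: str = "inward"
    p_join: float = 0.3
    cnv_rate_per_passage: float = CNV_RATE_PER_PASSAGE
    snv_indel_rate_per_passage: float = SNV_INDEL_RATE_PER_PASSAGE
    droplets_per_well: int = 20_000
    mean_copies_per_droplet: float = 1.0
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_join <= 1.0:
            raise ValueError("p_join must lie in [0, 1]")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.offset_mean_bp <= 0 or self.length_min_bp <= 0:
            raise ValueError("distribution supports must be positive")
        if self.length_max_bp < self.length_min_bp:
            raise ValueError("length_max_bp below length_min_bp")
        if self.orientation not in {"inward", "parallel", "outward"}:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class DeletionEvent:
    """A true simulated deletion with its provenance."""

    interval: GenomicInterval
    guides: tuple[str, ...]
    start_offset_bp: float      # |anchor - proximal deletion edge| at draw time
    truncated: bool = False
    event_id: str = ""


@dataclass
class CloneGenotype:
    """Ground truth for one simulated clone."""

    name: str
    deletions: list[DeletionEvent]
    background: list[VariantCall]
    passages: int = 0


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _mutate_spacer(spacer: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Introduce exactly n substitutions at distinct random positions."""
    if n_mismatches > len(spacer):
        raise ValueError("more mismatches than spacer positions")
    idx = rng.choice(len(spacer), size=n_mismatches, replace=False)
    bases = list(spacer)
    for i in idx:
        alternatives = [b for b in "ACGT" if b != bases[i]]
        bases[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(bases)


def _plant_footprint(plant: GuidePlant) -> tuple[int, int]:
    """Reference interval occupied by protospacer plus PAM."""
    g = plant.guide
    plen = len(g.pam)  # type: ignore[arg-type]
    L = g.spacer_length
    five_prime_pam = g.pam_side == "5prime"
    if plant.strand == "+":
        return (plant.position - plen, plant.position + L) if five_prime_pam else (
            plant.position,
            plant.position + L + plen,
        )
    return (plant.position, plant.position + L + plen) if five_prime_pam else (
        plant.position - plen,
        plant.position + L,
    )


def _concrete_pam(pam: str, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(
        sorted(ambiguous_dna_values[c])[rng.integers(len(ambiguous_dna_values[c]))]
        for c in pam
    )


def make_genome(
    config: SimConfig,
    seed: int,
    plants: Sequence[GuidePlant] = (),
) -> GenomeSequence:
    """Random genome with the requested guide copies planted.

    Each plant writes the (possibly mutated) protospacer and a concrete PAM
    at its position; footprints must not overlap. Deterministic per seed.
    """
    from .core import revcomp

    if config.genome_length < 10_000:
        raise ValueError("genome must be at least 10 kb")
    rng = np.random.default_rng(seed)
    seq = list(_random_bases(config.genome_length, config.gc_fraction, rng))

    footprints = sorted(_plant_footprint(p) for p in plants)
    for (a1, b1), (a2, b2) in zip(footprints, footprints[1:]):
        if a2 < b1:
            raise ValueError("guide plants overlap")
    for fp, plant in zip([_plant_footprint(p) for p in plants], plants):
        if fp[0] < 0 or fp[1] > config.genome_length:
            raise ValueError("plant footprint outside genome")

    for plant in plants:
        g = plant.guide
        proto = _mutate_spacer(g.spacer, plant.n_mismatches, rng)
        pam = _concrete_pam(g.pam, rng)  # type: ignore[arg-type]
        if g.pam_side == "5prime":
            block = pam + proto
            ref_start = plant.position - len(pam) if plant.strand == "+" else plant.position
        else:
            block = proto + pam
            ref_start = plant.position if plant.strand == "+" else plant.position - len(pam)
        if plant.strand == "-":
            block = revcomp(block)
        seq[ref_start : ref_start + len(block)] = block
    return GenomeSequence({config.contig: "".join(seq)})


# ---------------------------------------------------------------------------
# Deletion events
# ---------------------------------------------------------------------------

def _draw_length(config: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = math.log(config.length_min_bp), math.log(config.length_max_bp)
    return max(1, round(math.exp(rng.uniform(lo, hi))))


def _clip_event(
    contig_len: int, start: int, end: int
) -> tuple[int, int, bool]:
    truncated = start < 0 or end > contig_len
    return max(0, start), min(contig_len, end), truncated


def simulate_deletion_event(
    site: BindingSite,
    config: SimConfig,
    seed: int | np.random.Generator,
    contig_length: int | None = None,
) -> DeletionEvent:
    """One unidirectional Cas3 deletion from ``site``.

    The proximal deletion edge sits ``offset`` bp from the site anchor on
    the degradation side (offset ~ Exp(mean), 99th percentile 5 kb) and the
    deletion extends away from the site by a log-uniform length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    direction = degradation_direction(site)
    offset = float(rng.exponential(config.offset_mean_bp))
    length = _draw_length(config, rng)
    if direction == "right":
        start = site.anchor + round(offset)
        end = start + length
    else:
        end = site.anchor - round(offset)
        start = end - length
    truncated = False
    if contig_length is not None:
        start, end, truncated = _clip_event(contig_length, start, end)
    if end <= start:  # fully clipped away; keep a 1-bp remnant at the edge
        start, end = max(0, min(start, (contig_length or end) - 1)), max(1, end)
        truncated = True
    return DeletionEvent(
        interval=GenomicInterval(site.interval.contig, start, end),
        guides=(site.guide_name,),
        start_offset_bp=offset,
        truncated=truncated,
    )


def simulate_dual_deletion(
    site_a: BindingSite,
    site_b: BindingSite,
    config: SimConfig,
    seed: int | np.random.Generator,
    contig_length: int | None = None,
    scatter: bool = True,
) -> list[DeletionEvent]:
    """Dual-crRNA outcome: one fused spanning deletion with probability
    ``p_join``, otherwise independent per-site events.

    Fused endpoints scatter outward from each protospacer by offsets drawn
    from the start-offset law, so both protospacers are typically lost.
    With ``scatter=False`` the fused deletion runs exactly anchor-to-anchor.
    """
    if site_a.interval.contig != site_b.interval.contig:
        raise ValueError("dual deletion requires sites on one contig")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    left, right = sorted((site_a, site_b), key=lambda s: s.anchor)
    if rng.random() < config.p_join:
        o_l = float(rng.exponential(config.offset_mean_bp)) if scatter else 0.0
        o_r = float(rng.exponential(config.offset_mean_bp)) if scatter else 0.0
        start = left.anchor - round(o_l)
        end = right.anchor + round(o_r)
        truncated = False
        if contig_length is not None:
            start, end, truncated = _clip_event(contig_length, start, end)
        if end <= start:
            end = start + 1
        return [
            DeletionEvent(
                interval=GenomicInterval(left.interval.contig, start, end),
                guides=(left.guide_name, right.guide_name),
                start_offset_bp=max(o_l, o_r),
                truncated=truncated,
            )
        ]
    return [
        simulate_deletion_event(left, config, rng, contig_length),
        simulate_deletion_event(right, config, rng, contig_length),
    ]


# ---------------------------------------------------------------------------
# Background variants
# ---------------------------------------------------------------------------

def simulate_background(
    config: SimConfig,
    passages: int,
    seed: int | np.random.Generator,
    genome_length: int | None = None,
    sample: str = "",
) -> list[VariantCall]:
    """Spontaneous passage-dependent CNVs and SNV/indels, uniform placement."""
    if passages < 0:
        raise ValueError("passages must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    glen = genome_length or config.genome_length
    calls: list[VariantCall] = []
    n_cnv = rng.poisson(config.cnv_rate_per_passage * passages)
    for i in range(n_cnv):
        lo, hi = math.log(BACKGROUND_CNV_MIN_BP), math.log(BACKGROUND_CNV_MAX_BP)
        length = min(glen - 1, max(1, round(math.exp(rng.uniform(lo, hi)))))
        start = int(rng.integers(0, glen - length))
        kind = "cnv_loss" if rng.random() < 0.8 else "cnv_gain"
        calls.append(
            VariantCall(
                kind=kind,
                interval=GenomicInterval(config.contig, start, start + length),
                sample=sample,
                call_id=f"bg_cnv_{i}",
            )
        )
    n_point = rng.poisson(config.snv_indel_rate_per_passage * passages)
    for i in range(n_point):
        pos = int(rng.integers(0, glen - 1))
        kind = "indel" if rng.random() < INDEL_FRACTION else "snv"
        calls.append(
            VariantCall(
                kind=kind,
                interval=GenomicInterval(config.contig, pos, pos + 1),
                sample=sample,
                call_id=f"bg_pt_{i}",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Droplet wells
# ---------------------------------------------------------------------------

def simulate_droplet_well(
    lam: float,
    n_droplets: int,
    rng: np.random.Generator,
    sample: str,
    probe: str,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> DropletAssay:
    """Binomial droplet sampling: each droplet is positive with
    probability 1 - exp(-lam)."""
    p_pos = 1.0 - math.exp(-lam)
    n_positive = int(rng.binomial(n_droplets, p_pos))
    return DropletAssay(
        sample=sample,
        probe=probe,
        n_droplets=n_droplets,
        n_positive=n_positive,
        droplet_volume_nl=droplet_volume_nl,
    )


def population_droplet_wells(
    clones: Sequence[CloneGenotype],
    panel: ProbePanel,
    config: SimConfig,
    rng: np.random.Generator,
    sample: str = "population",
) -> list[DropletAssay]:
    """Wells for a pooled population: the per-probe copy concentration is
    reduced by the fraction of clones whose deletions cover the probe."""
    wells = []
    positions = panel.probe_positions()
    ref_name = panel.reference_probe[0]
    for probe, pos in positions.items():
        if probe == ref_name:
            lost_frac = 0.0
        else:
            lost = sum(
                1
                for c in clones
                if any(d.interval.contains_point(pos) for d in c.deletions)
            )
            lost_frac = lost / len(clones) if clones else 0.0
        lam = config.mean_copies_per_droplet * (1.0 - lost_frac)
        wells.append(
            simulate_droplet_well(
                lam,
                config.droplets_per_well,
                rng,
                sample,
                probe,
                config.droplet_volume_nl,
            )
        )
    return wells


# ---------------------------------------------------------------------------
# Emission to standard formats
# ---------------------------------------------------------------------------

def _write_vcf(
    calls: Sequence[VariantCall], genome: GenomeSequence, path: Path
) -> None:
    header = pysam.VariantHeader()
    for name in sorted(genome.contigs):
        header.contigs.add(name, length=genome.length(name))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        ordered = sorted(calls, key=lambda c: (c.interval.contig, c.interval.start))
        for c in ordered:
            pos = c.position
            ref_base = genome.contigs[c.interval.contig][pos]
            if ref_base == "N":
                ref_base = "A"
            if c.kind == "indel":
                alt = ref_base + "A"
            else:
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}.get(ref_base, "A")
            rec = out.new_record(
                contig=c.interval.contig,
                start=pos,          # pysam takes 0-based; writes POS+1
                alleles=(ref_base, alt),
                id=c.call_id or None,
            )
            rec.stop = pos + 1
            out.write(rec)


def _junction_read(
    genome: GenomeSequence,
    event: DeletionEvent,
    rng: np.random.Generator,
    flank: int = 300,
    max_insertion: int = 0,
    max_microhomology: int = 0,
) -> tuple[str, DeletionEvent]:
    """Synthesize an amplicon across a deletion; returns (sequence, event)."""
    seq = genome.contigs[event.interval.contig]
    a, b = event.interval.start, event.interval.end
    left = seq[max(0, a - flank) : a]
    right = seq[b : b + flank]
    insertion = ""
    if max_insertion > 0 and rng.random() < 0.5:
        n = int(rng.integers(1, max_insertion + 1))
        insertion = "".join(rng.choice(list("ACGT"), size=n))
    return left + insertion + right, event


def emit_callsets(
    clone: CloneGenotype,
    genome: GenomeSequence,
    panel: ProbePanel,
    outdir: str | Path,
    config: SimConfig,
    seed: int | np.random.Generator,
    junction_flank: int = 300,
    max_insertion: int = 0,
) -> dict[str, Path]:
    """Write one clone's call sets in every pipeline input format.

    Emits a CNV TSV (true deletions as losses plus background CNVs), a VCF
    of background SNV/indels, a FASTA of junction amplicons across each
    deletion, and a droplet-well TSV (per-probe copy ratio 0 or 1 for a
    single clone). Returns the paths keyed by kind.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cnv_calls = [
        VariantCall(
            kind="cnv_loss",
            interval=e.interval,
            sample=clone.name,
            call_id=e.event_id or f"del_{i}",
        )
        for i, e in enumerate(clone.deletions)
    ] + [c for c in clone.background if c.is_cnv]
    paths["cnv"] = outdir / f"{clone.name}.cnv.tsv"
    write_cnv_table(cnv_calls, paths["cnv"])

    point_calls = [c for c in clone.background if not c.is_cnv]
    paths["vcf"] = outdir / f"{clone.name}.vcf"
    _write_vcf(point_calls, genome, paths["vcf"])

    paths["junctions"] = outdir / f"{clone.name}.junctions.fa"
    with open(paths["junctions"], "w") as fh:
        for i, event in enumerate(clone.deletions):
            read, _ = _junction_read(
                genome, event, rng, flank=junction_flank, max_insertion=max_insertion
            )
            fh.write(f">{clone.name}_junction_{i}\n")
            for j in range(0, len(read), 60):
                fh.write(read[j : j + 60] + "\n")

    wells = population_droplet_wells([clone], panel, config, rng, sample=clone.name)
    paths["wells"] = outdir / f"{clone.name}.wells.tsv"
    with open(paths["wells"], "w") as fh:
        fh.write("sample\tprobe\tn_droplets\tn_positive\n")
        for w in wells:
            fh.write(f"{w.sample}\t{w.probe}\t{w.n_droplets}\t{w.n_positive}\n")
    return paths
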