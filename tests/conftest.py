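"""Shared fixtures: small random genomes, guides, and a dystrophin-like
exon model (synthetic coordinates, canonical Dp427m exon lengths)."""

from __future__ import annotations

import numpy as np
import pytest

from dualcas3 import GuideSpec
from dualcas3.simulate import GuidePlant, SimConfig, make_genome

# Canonical dystrophin (Dp427m) exon lengths for exons 43..57. The exon
# 45-55 block sums to 1779 bp (divisible by 3), which is the arithmetic
# behind frame-restoring multi-exon skipping.
DMD_EXON_LENGTHS = {
    43: 173, 44: 148, 45: 176, 46: 148, 47: 150, 48: 186, 49: 102,
    50: 109, 51: 233, 52: 118, 53: 212, 54: 155, 55: 190, 56: 173, 57: 145,
}


def random_genome(length: int, seed: int, contig: str = "chr1"):
    """Uniform random ACGT genome, deterministic per seed."""
    from dualcas3 import GenomeSequence

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeSequence({contig: seq})


@pytest.fixture
def cas3_guide() -> GuideSpec:
    return GuideSpec(name="ex45", system="cas3", spacer="GATTACAGATTACAGATTACAGATTAC")


@pytest.fixture
def cas9_guide() -> GuideSpec:
    return GuideSpec(name="sg45", system="cas9", spacer="GATTACAGATTACAGATTAC")


@pytest.fixture
def planted_genome(cas3_guide):
    """50-kb genome with the cas3 guide planted exactly once on '+'."""
    cfg = SimConfig(genome_length=50_000, contig="chr1")
    plants = [GuidePlant(guide=cas3_guide, position=20_000, strand="+", contig="chr1")]
    return make_genome(cfg, seed=11, plants=plants), plants


def write_dmd_gff3(path, contig: str = "chrX", start: int = 1_000, gap: int = 500) -> None:
    """Synthetic GFF3 exon model with the canonical DMD exon lengths."""
    pos = start
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for number in sorted(DMD_EXON_LENGTHS):
            ln = DMD_EXON_LENGTHS[number]
            fh.write(
                f"{contig}\tsyn\texon\t{pos + 1}\t{pos + ln}\t.\t+\t."
                f"\tgene=DMD;exon_number={number}\n"
            )
            pos += ln + gap


@pytest.fixture
def dmd_model(tmp_path):
    from dualcas3 import read_exon_model

    path = tmp_path / "dmd.gff3"
    write_dmd_gff3(path)
    return read_exon_model(path)
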