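"""Generative model: determinism, calibrated distributions, and round trips
through the emitted standard-format files."""

import math

import numpy as np
import pytest
from scipy import stats

from dualcas3 import (
    GenomicInterval,
    GuideSpec,
    JunctionRead,
    attribute_variants,
    map_junction,
    panel_layout,
    read_variants,
    scan_genome,
    simulate_background,
    simulate_deletion_event,
    simulate_dual_deletion,
)
from dualcas3.locus import left_normalize
from dualcas3.simulate import (
    CloneGenotype,
    GuidePlant,
    SimConfig,
    emit_callsets,
    make_genome,
)

SPACER_A = "GATTACAGATTACAGATTACAGATTAC"
SPACER_B = "CCGGAATTCCGGAATTCCGGAATTCCG"


@pytest.fixture(scope="module")
def dual_setup():
    """Genome with two planted cas3 guides in inward orientation."""
    ga = GuideSpec(name="ex45", system="cas3", spacer=SPACER_A)
    gb = GuideSpec(name="ex55", system="cas3", spacer=SPACER_B)
    cfg = SimConfig(genome_length=400_000, contig="chrSim")
    plants = [
        GuidePlant(guide=ga, position=100_000, strand="-"),   # degrades rightward
        GuidePlant(guide=gb, position=300_000, strand="+"),   # degrades leftward
    ]
    genome = make_genome(cfg, seed=77, plants=plants)
    site_a = next(s for s in scan_genome(genome, ga)
                  if s.interval.start == 100_000 and s.strand == "-")
    site_b = next(s for s in scan_genome(genome, gb)
                  if s.interval.start == 300_000 and s.strand == "+")
    return genome, cfg, site_a, site_b


class TestMakeGenome:
    def test_identical_seeds_identical_genomes(self):
        cfg = SimConfig(genome_length=20_000)
        g1 = make_genome(cfg, seed=1)
        g2 = make_genome(cfg, seed=1)
        assert g1.contigs == g2.contigs

    def test_different_seeds_differ(self):
        cfg = SimConfig(genome_length=20_000)
        assert make_genome(cfg, 1).contigs != make_genome(cfg, 2).contigs

    def test_plant_mismatch_count_visible_to_scanner(self):
        guide = GuideSpec(name="g", system="cas3", spacer=SPACER_A)
        cfg = SimConfig(genome_length=30_000, contig="c")
        plants = [GuidePlant(guide=guide, position=10_000, n_mismatches=3, contig="c")]
        genome = make_genome(cfg, seed=5, plants=plants)
        at = [s for s in scan_genome(genome, guide)
              if s.interval.start == 10_000 and s.strand == "+"]
        assert len(at) == 1 and at[0].mismatch_count == 3

    def test_overlapping_plants_rejected(self):
        guide = GuideSpec(name="g", system="cas3", spacer=SPACER_A)
        cfg = SimConfig(genome_length=30_000, contig="c")
        plants = [
            GuidePlant(guide=guide, position=10_000, contig="c"),
            GuidePlant(guide=guide, position=10_010, contig="c"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            make_genome(cfg, seed=5, plants=plants)

    def test_unplanted_genome_matches_oracle_scan(self):
        from dualcas3 import brute_force_scan

        guide = GuideSpec(name="g", system="cas3", spacer=SPACER_A, max_mismatches=8)
        genome = make_genome(SimConfig(genome_length=100_000, contig="c"), seed=6)
        assert scan_genome(genome, guide) == brute_force_scan(genome, guide)


class TestDeletionEvents:
    def test_degenerate_config_fixed_length(self, dual_setup):
        genome, _, site_a, _ = dual_setup
        cfg = SimConfig(offset_mean_bp=1e-9, length_min_bp=1_000, length_max_bp=1_000)
        event = simulate_deletion_event(site_a, cfg, seed=1)
        assert event.interval.length == 1_000
        # site degrades rightward: deletion starts at the anchor
        assert event.interval.start == site_a.anchor

    def test_leftward_site_deletes_leftward(self, dual_setup):
        genome, _, _, site_b = dual_setup
        cfg = SimConfig(offset_mean_bp=1e-9, length_min_bp=1_000, length_max_bp=1_000)
        event = simulate_deletion_event(site_b, cfg, seed=1)
        assert event.interval.end == site_b.anchor

    def test_start_offset_quantile_calibration(self, dual_setup):
        _, cfg, site_a, _ = dual_setup
        rng = np.random.default_rng(99)
        offsets = [
            simulate_deletion_event(site_a, cfg, rng).start_offset_bp
            for _ in range(10_000)
        ]
        within = sum(1 for o in offsets if abs(o) <= 5_000) / len(offsets)
        assert within >= 0.985  # calibrated 99th percentile at 5 kb

    def test_length_distribution_log_uniform(self, dual_setup):
        _, cfg, site_a, _ = dual_setup
        rng = np.random.default_rng(100)
        lengths = np.array([
            simulate_deletion_event(site_a, cfg, rng).interval.length
            for _ in range(10_000)
        ])
        # exclude truncated-at-boundary artefacts by using an unbounded draw
        logs = np.log(lengths[lengths < 99_000])
        ks = stats.kstest(
            logs, stats.uniform(math.log(200), math.log(100_000) - math.log(200)).cdf
        )
        assert ks.pvalue > 0.01 or len(logs) < 9_000

    def test_truncation_flagged_at_contig_edge(self, dual_setup):
        genome, _, site_a, _ = dual_setup
        cfg = SimConfig(offset_mean_bp=1e-9, length_min_bp=500_000, length_max_bp=500_000)
        event = simulate_deletion_event(site_a, cfg, seed=2,
                                        contig_length=genome.length("chrSim"))
        assert event.truncated
        assert event.interval.end == genome.length("chrSim")


class TestDualDeletion:
    def test_certain_join_zero_scatter_spans_anchor_to_anchor(self, dual_setup):
        _, _, site_a, site_b = dual_setup
        cfg = SimConfig(p_join=1.0)
        (event,) = simulate_dual_deletion(site_a, site_b, cfg, seed=3, scatter=False)
        lo, hi = sorted((site_a.anchor, site_b.anchor))
        assert (event.interval.start, event.interval.end) == (lo, hi)
        assert set(event.guides) == {"ex45", "ex55"}

    def test_no_join_gives_two_independent_events(self, dual_setup):
        _, _, site_a, site_b = dual_setup
        cfg = SimConfig(p_join=0.0)
        events = simulate_dual_deletion(site_a, site_b, cfg, seed=4)
        assert len(events) == 2
        assert {e.guides[0] for e in events} == {"ex45", "ex55"}

    def test_different_contigs_rejected(self, dual_setup):
        import dataclasses

        _, _, site_a, site_b = dual_setup
        other = dataclasses.replace(
            site_b, interval=GenomicInterval("chrOther", 100, 127, "+")
        )
        with pytest.raises(ValueError):
            simulate_dual_deletion(site_a, other, SimConfig(), seed=5)

    def test_join_fraction_controls_midpoint_loss(self, dual_setup):
        genome, _, site_a, site_b = dual_setup
        cfg = SimConfig(p_join=0.3)
        rng = np.random.default_rng(6)
        midpoint = (site_a.anchor + site_b.anchor) // 2
        n_clones = 1_000
        missing = 0
        for _ in range(n_clones):
            events = simulate_dual_deletion(site_a, site_b, cfg, rng,
                                            contig_length=genome.length("chrSim"))
            if any(e.interval.contains_point(midpoint) for e in events):
                missing += 1
        frac = missing / n_clones
        se = math.sqrt(0.3 * 0.7 / n_clones)
        assert abs(frac - 0.3) <= 4 * se


class TestBackground:
    def test_zero_passages_empty(self):
        assert simulate_background(SimConfig(), 0, seed=1) == []

    def test_cnv_rate_calibration(self):
        # rate 13/18 per passage, 18 passages -> mean 13 CNVs
        cfg = SimConfig()
        rng = np.random.default_rng(7)
        counts = [
            sum(1 for c in simulate_background(cfg, 18, rng) if c.is_cnv)
            for _ in range(2_000)
        ]
        assert abs(np.mean(counts) - 13.0) <= 0.25

    def test_uniform_placement_chi_squared(self):
        cfg = SimConfig(genome_length=1_000_000, snv_indel_rate_per_passage=600)
        rng = np.random.default_rng(8)
        calls = [c for c in simulate_background(cfg, 18, rng) if not c.is_cnv]
        positions = np.array([c.position for c in calls[:10_000]])
        counts, _ = np.histogram(positions, bins=10, range=(0, 1_000_000))
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01


class TestEmitCallsets:
    def test_spanning_deletion_appears_as_cnv_loss(self, dual_setup, tmp_path):
        genome, cfg, site_a, site_b = dual_setup
        (event,) = simulate_dual_deletion(
            site_a, site_b, SimConfig(p_join=1.0), seed=9, scatter=False
        )
        clone = CloneGenotype(name="c0", deletions=[event], background=[])
        region = GenomicInterval("chrSim", site_a.anchor, site_b.anchor)
        panel = panel_layout(region, 7, reference_offset_bp=50_000)
        paths = emit_callsets(clone, genome, panel, tmp_path, cfg, seed=10)
        cnvs = read_variants(paths["cnv"], "cnv")
        assert len(cnvs) == 1
        assert (cnvs[0].interval.start, cnvs[0].interval.end) == (
            event.interval.start,
            event.interval.end,
        )

    def test_emitted_files_readable_and_labels_preserved(self, dual_setup, tmp_path):
        genome, cfg, site_a, site_b = dual_setup
        rng = np.random.default_rng(11)
        events = simulate_dual_deletion(site_a, site_b, SimConfig(p_join=1.0), rng,
                                        contig_length=genome.length("chrSim"))
        background = simulate_background(cfg, 18, rng, genome.length("chrSim"))
        clone = CloneGenotype(name="c1", deletions=events, background=background)
        region = GenomicInterval("chrSim", site_a.anchor, site_b.anchor)
        panel = panel_layout(region, 7, reference_offset_bp=50_000)
        paths = emit_callsets(clone, genome, panel, tmp_path, cfg, rng)
        cnvs = read_variants(paths["cnv"], "cnv")
        points = read_variants(paths["vcf"], "snv_indel")
        n_bg_cnv = sum(1 for c in background if c.is_cnv)
        n_bg_pt = sum(1 for c in background if not c.is_cnv)
        assert len(cnvs) == len(events) + n_bg_cnv
        assert len(points) == n_bg_pt

    def test_junction_reads_remap_to_event_breakpoints(self, dual_setup, tmp_path):
        from Bio import SeqIO

        genome, cfg, site_a, site_b = dual_setup
        rng = np.random.default_rng(12)
        events = simulate_dual_deletion(site_a, site_b, SimConfig(p_join=1.0), rng,
                                        contig_length=genome.length("chrSim"))
        clone = CloneGenotype(name="c2", deletions=events, background=[])
        region = GenomicInterval("chrSim", site_a.anchor, site_b.anchor)
        panel = panel_layout(region, 7, reference_offset_bp=50_000)
        paths = emit_callsets(clone, genome, panel, tmp_path, cfg, rng)
        ref = genome.contigs["chrSim"]
        reads = list(SeqIO.parse(paths["junctions"], "fasta"))
        assert len(reads) == len(events)
        for rec, event in zip(reads, events):
            call = map_junction(JunctionRead(rec.id, str(rec.seq)), ref, "chrSim")
            want = left_normalize(ref, event.interval.start, event.interval.end)[:2]
            assert (call.deletion.start, call.deletion.end) == want

    def test_attribution_round_trip_recovers_labels(self, dual_setup, tmp_path):
        genome, cfg, site_a, site_b = dual_setup
        rng = np.random.default_rng(13)
        sites = [site_a, site_b]
        events = simulate_dual_deletion(site_a, site_b, SimConfig(p_join=1.0), rng,
                                        contig_length=genome.length("chrSim"))
        clone = CloneGenotype(name="c3", deletions=events, background=[])
        region = GenomicInterval("chrSim", site_a.anchor, site_b.anchor)
        panel = panel_layout(region, 7, reference_offset_bp=50_000)
        paths = emit_callsets(clone, genome, panel, tmp_path, cfg, rng)
        cnvs = read_variants(paths["cnv"], "cnv")
        records = attribute_variants(cnvs, sites, window_bp=5_000)
        for rec, event in zip(records, events):
            if abs(event.start_offset_bp) <= 5_000:
                assert rec.verdict == "candidate"
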