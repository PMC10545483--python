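"""Off-target attribution of variant calls to putative guide-binding sites.

The central rule: Cas3-mediated deletion events start within 5 kb of a
crRNA binding site in ~99% of cases, so a variant whose distance to the
nearest putative site exceeds the 5-kb window is attributed to background
(culture/subcloning) rather than nuclease activity. Distance is measured
from a site's anchor point (PAM-proximal protospacer boundary) to an SNV's
position or to the nearer of a CNV's two breakpoints. A site falling inside
a CNV still scores by breakpoint distance; the ``inside_cnv`` flag records
the containment separately.

Two optional post-hoc filters mirror the biological arguments used to
dismiss residual in-window hits: seed-mismatch incompatibility (even one
seed mismatch nearly abolishes Cas3 activity) and degradation-direction
inconsistency (the variant lies on the side the nuclease does not reach).
Both default off for verdict counting and are always reported as
annotations.

Enrichment statistics: a two-sided Fisher exact test between a treated
clone and a passage control, and an exact binomial test of the in-window
count against the genome-fraction null (window span / genome size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, VariantCall
from .sites import BindingSite, degradation_direction

__all__ = [
    "AttributionRecord",
    "EnrichmentResult",
    "variant_site_distance",
    "make_record",
    "classify",
    "attribute_variants",
    "window_span",
    "fisher_enrichment",
    "binomial_expectation",
]

DEFAULT_WINDOW_BP = 5_000


@dataclass(frozen=True)
class AttributionRecord:
    """A variant call and its relationship to the nearest putative site."""

    variant: VariantCall
    nearest_site: BindingSite | None
    distance_bp: float  # inf when no site shares the variant's contig
    within_window: bool
    inside_cnv: bool
    direction_consistent: bool
    seed_compatible: bool
    verdict: str = ""  # candidate | excluded_distance | excluded_seed | excluded_direction


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher 2x2 comparison plus the genome-fraction binomial null."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    expected_in_window: float | None = None
    binomial_p: float | None = None


def _variant_points(variant: VariantCall) -> list[int]:
    """Coordinates at which distance is evaluated: both breakpoints for a
    CNV, the left-aligned start for point variants."""
    if variant.is_cnv:
        return [variant.interval.start, variant.interval.end]
    return [variant.position]


def variant_site_distance(
    variant: VariantCall, sites: Sequence[BindingSite]
) -> tuple[BindingSite | None, float, bool]:
    """Nearest site and its distance in bp.

    Returns ``(nearest_site, distance_bp, inside_cnv)``. For CNVs the
    distance is the minimum over both breakpoints and all site anchors;
    ``inside_cnv`` is true when some site anchor lies within the CNV
    interval (the distance is then still to the nearer breakpoint). A
    variant on a contig with no sites gets distance ``inf``.
    """
    if not sites:
        raise ValueError("empty site index")
    contig = variant.interval.contig
    candidates = [s for s in sites if s.interval.contig == contig]
    if not candidates:
        return None, math.inf, False
    points = _variant_points(variant)
    best_site, best_dist = None, math.inf
    inside = False
    for site in candidates:
        if variant.is_cnv and variant.interval.contains_point(site.anchor):
            inside = True
        d = min(abs(p - site.anchor) for p in points)
        if d < best_dist:
            best_site, best_dist = site, d
    return best_site, best_dist, inside


def _direction_consistent(variant: VariantCall, site: BindingSite) -> bool:
    """True when the variant lies on the site's degradation side.

    Only meaningful for cas3 sites; cas9 sites count as consistent (the
    filter has no semantics there). Distance-0 coincidence is consistent.
    """
    if site.system != "cas3":
        return True
    direction = degradation_direction(site)
    points = _variant_points(variant)
    nearest_point = min(points, key=lambda p: abs(p - site.anchor))
    if direction == "left":
        return nearest_point <= site.anchor
    return nearest_point >= site.anchor


def make_record(
    variant: VariantCall,
    sites: Sequence[BindingSite],
    window_bp: int = DEFAULT_WINDOW_BP,
    seed_max: int = 0,
) -> AttributionRecord:
    """Populate an (unclassified) attribution record for one variant."""
    site, dist, inside = variant_site_distance(variant, sites)
    return AttributionRecord(
        variant=variant,
        nearest_site=site,
        distance_bp=dist,
        within_window=dist <= window_bp,
        inside_cnv=inside,
        direction_consistent=(site is not None and _direction_consistent(variant, site)),
        seed_compatible=(site is not None and site.seed_mismatch_count <= seed_max),
    )


def classify(
    record: AttributionRecord,
    window_bp: int = DEFAULT_WINDOW_BP,
    seed_max: int = 0,
    require_seed: bool = False,
    require_direction: bool = False,
) -> str:
    """Apply the distance rule, then the optional seed/direction filters.

    Verdict is ``candidate`` only when every enabled filter passes; the
    distance rule is always applied.
    """
    if window_bp < 0:
        raise ValueError("window must be non-negative")
    if record.distance_bp > window_bp:
        return "excluded_distance"
    site = record.nearest_site
    if require_seed and site is not None and site.seed_mismatch_count > seed_max:
        return "excluded_seed"
    if require_direction and not record.direction_consistent:
        return "excluded_direction"
    return "candidate"


def attribute_variants(
    variants: Iterable[VariantCall],
    sites: Sequence[BindingSite],
    window_bp: int = DEFAULT_WINDOW_BP,
    seed_max: int = 0,
    require_seed: bool = False,
    require_direction: bool = False,
) -> list[AttributionRecord]:
    """Build and classify a record for every variant."""
    out = []
    for v in variants:
        rec = make_record(v, sites, window_bp=window_bp, seed_max=seed_max)
        verdict = classify(
            rec,
            window_bp=window_bp,
            seed_max=seed_max,
            require_seed=require_seed,
            require_direction=require_direction,
        )
        out.append(replace(rec, verdict=verdict))
    return out


def window_span(
    n_sites: int,
    window_bp: int,
    mode: str = "naive",
    sites: Sequence[BindingSite] | None = None,
) -> int:
    """Total genomic span covered by ±window_bp around each site anchor.

    ``naive`` multiplies out n_sites x 2w (the arithmetic behind
    "714 crRNAs, ±5 kb" = 7.14 Mb); ``merged`` takes the union of the
    per-site windows and therefore never exceeds the naive span.
    """
    if mode == "naive":
        return n_sites * 2 * window_bp
    if mode != "merged":
        raise ValueError(f"mode must be 'naive' or 'merged', got {mode!r}")
    if sites is None:
        raise ValueError("merged mode requires the site list")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        by_contig.setdefault(s.interval.contig, []).append(
            (s.anchor - window_bp, s.anchor + window_bp)
        )
    total = 0
    for ivs in by_contig.values():
        ivs.sort()
        cur_start, cur_end = ivs[0]
        for a, b in ivs[1:]:
            if a > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = a, b
            else:
                cur_end = max(cur_end, b)
        total += cur_end - cur_start
    return total


def fisher_enrichment(
    clone_in: int,
    clone_total: int,
    control_in: int,
    control_total: int,
    span_bp: int | None = None,
    genome_bp: int | None = None,
) -> EnrichmentResult:
    """Two-sided Fisher exact test of in-window counts, clone vs control.

    The odds ratio uses a Haldane 0.5 correction when any cell is zero.
    When ``span_bp`` and ``genome_bp`` are given, the clone's in-window
    count is also tested against the genome-fraction binomial null.
    """
    if clone_total <= 0 or control_total <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= clone_in <= clone_total and 0 <= control_in <= control_total):
        raise ValueError("in-window counts must lie within their totals")
    table = (
        (clone_in, clone_total - clone_in),
        (control_in, control_total - control_in),
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    expected = binom_p = None
    if span_bp is not None and genome_bp is not None:
        expected, binom_p = binomial_expectation(clone_total, span_bp, genome_bp, clone_in)
    return EnrichmentResult(
        table=table,
        odds_ratio=odds,
        p_value=float(p),
        expected_in_window=expected,
        binomial_p=binom_p,
    )


def binomial_expectation(
    n_variants: int, span_bp: int, genome_bp: int, observed: int = 0
) -> tuple[float, float]:
    """Expected in-window count under uniform placement, and the exact
    upper-tail binomial p-value P(X >= observed)."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    if span_bp > genome_bp:
        raise ValueError("window span cannot exceed the genome size")
    frac = span_bp / genome_bp
    expected = n_variants * frac
    if observed <= 0:
        return expected, 1.0
    p = float(stats.binom.sf(observed - 1, n_variants, frac))
    return expected, min(1.0, p)
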