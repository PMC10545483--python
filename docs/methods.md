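# Methods

`dualcas3` models the computational side of a dual-crRNA CRISPR-Cas3
experiment that deletes a multi-hundred-kilobase genomic region (the
motivating application is removal of dystrophin exons 45–55 to restore the
DMD reading frame). This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data does and does
not capture.

## Binding-site model

A guide is a spacer sequence plus a PAM pattern and a mismatch budget. A
binding site is any genomic position, on either strand, where

1. the PAM matches **exactly** under IUPAC semantics, and
2. the Hamming distance between spacer and protospacer over non-masked
   positions is at most `max_mismatches`.

Defaults encode the two systems analysed: type I-E Cas3 (27-nt spacer,
5′ PAM, allowance 8) and SpCas9 (20-nt spacer, 3′ `NGG` PAM, allowance 5).
Choices that were genuinely open:

* **Cas3 PAM = 5′-`AAG`.** The canonical type I-E PAM; it is configurable
  because different Cascade variants read different PAMs.
* **PAM mismatches are not counted against the budget.** This reproduces a
  substring-search tool's protospacer-only mismatch counting.
* **No default position mask.** Periodic spacer positions (every sixth
  base) are not read by Cascade, which motivates the generous 8-mismatch
  allowance; a mask mode (`mask_positions={6,12,18,24}`, 1-based from the
  PAM-proximal end) is provided for sensitivity analyses but is off by
  default, matching a plain mismatch-allowance search. Enabling the mask
  can only add sites at equal allowance (property-tested).
* **`N` in the genome matches nothing**, neither a spacer base nor a PAM
  letter. Conservative: ambiguous reference sequence never produces a site.
* Overlapping sites on opposite strands are both kept; deduplication is on
  exact `(contig, start, strand)`.

Mismatch positions are reported 1-based from the PAM-proximal end, so the
seed region (where a single mismatch nearly abolishes Cas3 activity) is
positions 1..`seed_length` (default 8).

Each site carries an **anchor** — the PAM-proximal protospacer boundary —
used as the single reference point for every distance computation, and a
**degradation direction**: Cas3 degrades processively toward the PAM, i.e.
leftward on the reference for a `+`-strand site with a 5′ PAM, rightward
for a `−`-strand site (an inversion flag exists for probing the opposite
convention).

The production scanner (`scan_genome`) is vectorised over genome windows;
`brute_force_scan` implements the identical contract by walking every
position with no indexing or early exit and exists only as an independent
oracle. The suite asserts their equivalence on dozens of random genomes,
plus monotonicity in the allowance and reverse-complement symmetry.

## Off-target attribution

The attribution rule is distance-based: Cas3 deletion events start within
5 kb of the binding site in ~99% of cases, so a variant farther than the
window (default `window_bp = 5000`) from every site anchor is attributed
to background. Distances:

* SNV/indel: `|position − anchor|`, with the left-aligned start as the
  representative indel coordinate (deterministic, convention-stable).
* CNV: minimum over **both breakpoints** and all anchors. A site anchor
  falling inside the CNV sets `inside_cnv` but the distance is still to
  the nearer breakpoint, mirroring how a megabase-scale CNV containing a
  degenerate site is treated (by edge distance, not containment).

Two post-hoc filters are annotated on every record but default **off** for
verdict counting, because the 5-kb rule is the primary criterion and seed/
direction arguments were used only to dismiss residual in-window hits:
`require_seed` excludes sites with more than `seed_max` seed mismatches;
`require_direction` excludes variants lying opposite the degradation
direction (cas9 sites pass trivially — the filter has no semantics there).

Enrichment statistics: a two-sided Fisher exact test between clone and
control in-window counts (scipy's hypergeometric implementation; odds
ratio with Haldane 0.5 correction on zero cells; no multiple-testing
adjustment — raw per-comparison p-values are reported), and an exact
upper-tail binomial test of the observed in-window count against the
genome-fraction null `span/genome`. The window span is available in
`naive` mode (`n_sites × 2w`, the arithmetic behind "714 sites × ±5 kb =
7.14 Mb") and `merged` mode (length of the union of windows, always ≤
naive; windows are not clipped at contig ends, which preserves the
inequality and keeps the null conservative).

## ddPCR quantification

Standard limiting-dilution Poisson model: with positive-droplet fraction
`p̂`, the per-droplet copy mean is `λ = −ln(1 − p̂)` and the concentration
is `λ / v` with droplet volume `v = 0.85 nl` (QX200 convention; the value
is configurable since instruments differ). Saturated wells are rejected.

Deletion efficiency at a probe is
`loss = 1 − (target/reference) / control_ratio`, clipped to [0, 1], where
`control_ratio` is the target/reference ratio of an untreated sample
(default 1.0 when absent) and ploidy arguments correct unequal copy
numbers (both default 1 — the hemizygous X-linked case, where target and
reference sit on the same chromosome). The 95% CI uses the delta method on
the log-ratio, `Var(log λ̂) ≈ p / (n(1−p) λ²)` per well, with a half-count
pseudo-positive stabilising zero-positive wells; a zero-positive target
well yields loss exactly 1 with a rule-of-three upper bound on the ratio.
Exact Poisson intervals are out of scope.

Probe panels follow the published geometry: `n` target probes equally
spaced across the region including both ends (7 probes over 344 kb gives
the ~57-kb spacing, 344/6), labels as offsets from the region start
rounded to the nearest kb, and one reference probe 160 kb upstream.

## Junction mapping and frame arithmetic

A junction amplicon is mapped by exact anchors: the longest read prefix
matching the reference left flank and longest suffix matching the right
flank (each at least `anchor_min = 20` bases, located by exact substring
search). The unexplained middle is the insertion; if the anchors overlap
on the read the junction is purely microhomologous. Calls are
**left-normalised**: the deletion start is shifted 5′-ward as long as the
edited sequence is unchanged (rotating the insertion when non-empty),
the standard left-alignment convention — chosen because the assay itself
cannot distinguish the equivalent representations. Microhomology length is
the number of shifts applied (zero whenever an insertion remains, since
insertion and microhomology are mutually exclusive descriptions after
normalisation). Mapping is exact-match only: Sanger amplicons are high
quality and a mismatch-tolerant mode is out of scope. A read with no gap
(unedited amplicon) or without both anchors raises `UnmappableJunction`.

Frame analysis uses the mod-3 rule: skipping a contiguous internal exon
run preserves the reading frame iff the summed skipped length is divisible
by 3 (sufficient for contiguous internal skips; per-exon codon phases
follow from cumulative lengths). `mes_applicability` reduces the patient
question to the same rule on the **union** of the patient's missing exons
and the skip set: the final transcript joins the exons flanking that
union, so the outcome depends only on the full-model lengths inside it —
not on the patient's (already frameshifted) intermediate transcript.

## Synthetic-data generator

The generator encodes the study conditions as defaults, collected in one
block of constants at the top of `simulate.py` so they are auditable as
assumptions:

| parameter | default | rationale |
| --- | --- | --- |
| start-offset law | Exp(mean 5000/ln 100 ≈ 1085.7 bp) | one-parameter fit to the single published constraint: 99th percentile = 5 kb |
| deletion length | log-uniform [200 bp, 100 kb] | "a few hundred bp to a hundred kb" with no further shape information |
| `p_join` | 0.3 | fraction of cells where both crRNAs fire and fuse; not measurable from published data, free parameter |
| CNV background rate | 13/18 per passage | ~13 de novo CNVs over an 18-passage difference |
| SNV/indel background rate | 40 per passage | order of magnitude of published clone totals (~700–2000 over tens of passages) |
| droplets per well | 20,000 | QX200 scale |
| copies per droplet | 1.0 | mid-dynamic-range loading |

Deletions are strictly unidirectional from the anchor on the degradation
side; dual-guide events fuse into one spanning deletion with probability
`p_join`, endpoints scattered **outward** from each protospacer by the
start-offset law (so both protospacers are usually lost, as sequenced
junction clones show). Events are truncated at contig ends with a flag.
Background variants are uniform over the genome — a deliberately
length-proportional null with no mutational hotspots, matching the
chance-occurrence reasoning the attribution statistics implement.

What the simulator does **not** emulate: read-level sequencing (reads,
errors, coverage), variant-caller artefacts, mutational signatures or
hotspots, cell-population dynamics, and droplet fluorescence thresholding.
Passing tests therefore demonstrate correctness of the analysis given
faithful call sets and droplet counts, not robustness to upstream calling
noise.

## Problem sizes and numerical choices

The test and acceptance workloads are desk-scale by design: oracle
equivalence runs on dozens of random genomes of tens of kilobases (the
brute-force oracle is quadratic-ish and exists for verification, not
production), ddPCR recovery uses 200 replicates of 20,000-droplet wells,
the distance-filter calibration uses 10,000 events, and the Fisher
comparison enumerates every 2×2 table with row totals ≤ 30. The vectorised
scanner handles megabase genomes in well under a second per guide.

Tie-breaks and degenerate inputs: sites sort by `(contig, start, strand)`;
a spacer longer than every contig yields an empty result, not an error;
identical Fisher rows give p = 1; an observed in-window count of 0 gives
binomial p = 1; `window_span` merged mode requires the site list. All
stochastic behaviour flows through explicit `numpy` generators seeded at
the call boundary; identical seeds reproduce outputs byte-for-byte
(asserted end-to-end in the CLI tests).

## Known limitations

* The scanner is Hamming-only: guide–target bulges (indel-tolerant
  alignment) are not modelled, so sites detectable only with bulges are
  missed — consistent with the substring-search methodology it mirrors.
* The Cas3 PAM and the one-strand/both-strand question for the original
  site search are documented assumptions (both strands, PAM required,
  configurable), not published facts.
* The delta-method CI degrades for wells near saturation or with very few
  positives; the estimator itself is unbiased only asymptotically.
* `mes_applicability` assumes whole-exon patient deletions; intra-exonic
  breakpoints would need base-level bookkeeping that the exon model does
  not carry.
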