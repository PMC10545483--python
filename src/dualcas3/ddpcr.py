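"""Droplet digital PCR copy-number quantification of large deletions.

A ddPCR well partitions the sample into ~20,000 droplets; template copies
land in droplets as a Poisson process, so the copy concentration follows
from the fraction of positive droplets:

    lambda = -ln(1 - n_positive / n_droplets)        [copies per droplet]
    concentration = lambda / droplet_volume          [copies per µl]

Deletion efficiency at a probe is the copy-number loss of the target probe
relative to a reference probe outside the deletable region (dystrophin
exon 7 in the assay this models), normalised by the untreated sample's
target/reference ratio:

    loss_fraction = 1 - (target/reference) / control_ratio

Confidence intervals come from the delta method on the log-ratio.
The probe panel mirrors the published geometry: equally spaced target
probes across the deletion region (seven probes every ~57 kb over 344 kb)
plus one distal reference probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import GenomicInterval

__all__ = [
    "DropletAssay",
    "CopyNumberResult",
    "ProbePanel",
    "poisson_concentration",
    "deletion_efficiency",
    "panel_layout",
]

DEFAULT_DROPLET_VOLUME_NL = 0.85  # QX200 droplet volume
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class DropletAssay:
    """Raw droplet counts for one well/probe."""

    sample: str
    probe: str
    n_droplets: int
    n_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("well has no droplets")
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValueError("positive count outside 0..n_droplets")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_droplets


@dataclass(frozen=True)
class CopyNumberResult:
    """Derived concentrations and deletion efficiency for one probe."""

    sample: str
    probe: str
    target_concentration: float  # copies/µl
    reference_concentration: float
    ratio: float
    loss_fraction: float  # deletion efficiency, clipped to [0, 1]
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ProbePanel:
    """Equally spaced target probes plus a distal reference probe."""

    target_probes: tuple[tuple[str, int, str], ...]  # (name, position, offset label)
    reference_probe: tuple[str, int]

    def probe_positions(self) -> dict[str, int]:
        out = {name: pos for name, pos, _ in self.target_probes}
        out[self.reference_probe[0]] = self.reference_probe[1]
        return out


def poisson_concentration(assay: DropletAssay) -> float:
    """Copy concentration in copies/µl from the positive-droplet fraction.

    Saturated wells (every droplet positive) carry no information about the
    concentration and are rejected.
    """
    if assay.n_positive == assay.n_droplets:
        raise ValueError(
            f"well {assay.sample}/{assay.probe} is saturated "
            f"({assay.n_positive}/{assay.n_droplets} positive)"
        )
    lam = max(0.0, -math.log(1.0 - assay.positive_fraction))
    return lam / (assay.droplet_volume_nl * 1e-3)


def _lambda_and_logvar(assay: DropletAssay) -> tuple[float, float]:
    """Poisson mean per droplet and the delta-method variance of its log.

    A half-count pseudo-positive stabilises the variance for wells with
    zero positives (the point estimate is unchanged).
    """
    p = assay.positive_fraction
    lam = -math.log(1.0 - p)
    p_var = max(p, 0.5 / assay.n_droplets)
    var_lam = p_var / (assay.n_droplets * (1.0 - p_var))
    lam_for_var = -math.log(1.0 - p_var)
    return lam, var_lam / (lam_for_var**2)


def deletion_efficiency(
    target_assay: DropletAssay,
    reference_assay: DropletAssay,
    control_ratio: float = 1.0,
    target_ploidy: int = 1,
    reference_ploidy: int = 1,
) -> CopyNumberResult:
    """Copy-number loss at the target probe relative to the reference probe.

    ``control_ratio`` is the target/reference ratio measured in an untreated
    sample (1.0 when absent). Ploidy arguments correct for unequal copy
    numbers per genome (both default to 1, the hemizygous X-linked case).
    The 95% CI uses the delta method on the log-ratio; with zero target
    positives the loss is exactly 1 and the CI collapses to its upper bound.
    """
    if control_ratio <= 0:
        raise ValueError("control_ratio must be positive")
    target_conc = poisson_concentration(target_assay)
    ref_conc = poisson_concentration(reference_assay)
    if ref_conc == 0:
        raise ValueError("reference concentration is zero")
    ploidy_corr = reference_ploidy / target_ploidy
    ratio = (target_conc / ref_conc) * ploidy_corr
    loss = min(1.0, max(0.0, 1.0 - ratio / control_ratio))
    if target_conc == 0:
        return CopyNumberResult(
            sample=target_assay.sample,
            probe=target_assay.probe,
            target_concentration=0.0,
            reference_concentration=ref_conc,
            ratio=0.0,
            loss_fraction=1.0,
            ci_low=_loss_from_ratio(_upper_ratio_zero(target_assay, reference_assay, ploidy_corr), control_ratio),
            ci_high=1.0,
        )
    _, var_log_t = _lambda_and_logvar(target_assay)
    _, var_log_r = _lambda_and_logvar(reference_assay)
    sd = math.sqrt(var_log_t + var_log_r)
    ratio_low = ratio * math.exp(-_Z95 * sd)
    ratio_high = ratio * math.exp(_Z95 * sd)
    return CopyNumberResult(
        sample=target_assay.sample,
        probe=target_assay.probe,
        target_concentration=target_conc,
        reference_concentration=ref_conc,
        ratio=ratio,
        loss_fraction=loss,
        ci_low=_loss_from_ratio(ratio_high, control_ratio),
        ci_high=_loss_from_ratio(ratio_low, control_ratio),
    )


def _loss_from_ratio(ratio: float, control_ratio: float) -> float:
    return min(1.0, max(0.0, 1.0 - ratio / control_ratio))


def _upper_ratio_zero(
    target_assay: DropletAssay, reference_assay: DropletAssay, ploidy_corr: float
) -> float:
    """Upper ratio bound when the target well has zero positives (rule of three)."""
    lam_upper = 3.0 / target_assay.n_droplets
    ref_lam = -math.log(1.0 - reference_assay.positive_fraction)
    vol_ratio = reference_assay.droplet_volume_nl / target_assay.droplet_volume_nl
    return (lam_upper / ref_lam) * vol_ratio * ploidy_corr


def panel_layout(
    region: GenomicInterval,
    n_probes: int,
    reference_offset_bp: int = 160_000,
    name_prefix: str = "probe",
) -> ProbePanel:
    """Place ``n_probes`` equally spaced target probes across ``region``.

    Probes sit at both region ends and at equal intervals between (seven
    probes over 344 kb gives the published ~57-kb spacing); a single probe
    sits at the midpoint. Offset labels are relative to the region start and
    round to the nearest kb ("+16 kb" style). The reference probe is placed
    ``reference_offset_bp`` upstream of the region (clamped at 0).
    """
    if n_probes < 1:
        raise ValueError("need at least one probe")
    if region.length < n_probes:
        raise ValueError("region shorter than the probe count")
    if n_probes == 1:
        positions = [region.start + region.length // 2]
    else:
        span = region.length
        positions = [
            region.start + round(i * span / (n_probes - 1)) for i in range(n_probes)
        ]
    probes = []
    for i, pos in enumerate(positions):
        offset_kb = round((pos - region.start) / 1000)
        probes.append((f"{name_prefix}_{i + 1}", pos, f"+{offset_kb} kb"))
    ref_pos = max(0, region.start - reference_offset_bp)
    return ProbePanel(
        target_probes=tuple(probes),
        reference_probe=(f"{name_prefix}_ref", ref_pos),
    )
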