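"""Rare-CNV selection rules.

A call survives when it is large enough, well supported by probes, not
mostly inside masked regions (segmental duplications, centromeres, HLA),
autosomal, and rare against a population frequency panel. Rarity has two
parts: (a) no sufficiently frequent panel entry of the same dosage matches
the call at high reciprocal overlap, and (b) the call is not mostly covered
by the union of common panel regions.

Rules are evaluated in a fixed order (size, probes, mask, autosome,
rare-a, rare-b) and each excluded call is attributed to the first rule it
fails, which makes the per-rule tally reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import (
    CnvCall,
    FrequencyPanelEntry,
    GenomicInterval,
    covered_fraction,
    is_autosome,
    one_way_overlap,
    reciprocal_overlap,
)

RULE_ORDER = ["size", "probes", "mask", "autosome", "rare_a", "rare_b"]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for rare-CNV selection.

    Defaults follow the conventional rare-CNV pipeline: calls >= 50 kb with
    >= 10 probes, < 50% overlap with masked regions, autosomal only; "rare"
    means frequency < 1/1000 in the panel at 70% reciprocal overlap, and
    < 50% of the call covered by panel regions at > 1% frequency.
    """

    min_size_bp: int = 50_000
    min_probes: int = 10
    max_mask_fraction: float = 0.5
    rare_freq_threshold: float = 0.001
    rare_overlap_threshold: float = 0.7
    common_freq_threshold: float = 0.01
    max_common_covered_fraction: float = 0.5
    autosomes_only: bool = True
    # "reciprocal" requires both mutual fractions >= threshold; "one_way"
    # only requires the call itself to be covered.
    overlap_mode: str = "reciprocal"
    # pool DEL and DUP panel entries when testing rarity (off by default:
    # population frequencies differ by dosage type)
    pool_dosages: bool = False

    def __post_init__(self):
        for name in (
            "max_mask_fraction",
            "rare_freq_threshold",
            "rare_overlap_threshold",
            "common_freq_threshold",
            "max_common_covered_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_size_bp < 0 or self.min_probes < 0:
            raise ValueError("size/probe thresholds must be non-negative")
        if self.overlap_mode not in ("reciprocal", "one_way"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")


def _match_fraction(call: GenomicInterval, entry: GenomicInterval, mode: str) -> float:
    if mode == "reciprocal":
        return reciprocal_overlap(call, entry)
    return one_way_overlap(call, entry)


def is_rare(
    cnv: CnvCall, panel: list[FrequencyPanelEntry], params: FilterParams = FilterParams()
) -> tuple[bool, list[str]]:
    """Test the two-part rarity rule; returns (rare?, failed reason codes).

    Reason codes: "rare_a" — a same-dosage panel entry at or above the
    rarity frequency threshold matches the call at high overlap; "rare_b" —
    common panel regions cover too much of the call.
    """
    reasons = []
    same = [
        e
        for e in panel
        if params.pool_dosages or e.dosage == cnv.dosage
    ]
    for entry in same:
        if entry.frequency >= params.rare_freq_threshold:
            if (
                _match_fraction(cnv.interval, entry.interval, params.overlap_mode)
                >= params.rare_overlap_threshold
            ):
                reasons.append("rare_a")
                break
    common = [e.interval for e in same if e.frequency > params.common_freq_threshold]
    if covered_fraction(cnv.interval, common) >= params.max_common_covered_fraction:
        reasons.append("rare_b")
    return (not reasons, reasons)


def apply_filters(
    calls: list[CnvCall],
    panel: list[FrequencyPanelEntry] | None = None,
    masks: list[GenomicInterval] | None = None,
    params: FilterParams = FilterParams(),
) -> tuple[list[CnvCall], dict[str, int]]:
    """Apply every selection rule; return survivors and a per-rule tally.

    The tally has one entry per rule plus "pass"; exclusions are attributed
    to the first failing rule in RULE_ORDER, so values sum to len(calls).
    """
    panel = panel or []
    masks = masks or []
    tally = {rule: 0 for rule in RULE_ORDER}
    tally["pass"] = 0
    survivors = []
    for call in calls:
        if call.interval.length < params.min_size_bp:
            tally["size"] += 1
            continue
        if call.n_probes < params.min_probes:
            tally["probes"] += 1
            continue
        if covered_fraction(call.interval, masks) > params.max_mask_fraction:
            tally["mask"] += 1
            continue
        if params.autosomes_only and not is_autosome(call.interval.chrom):
            tally["autosome"] += 1
            continue
        rare, reasons = is_rare(call, panel, params)
        if not rare:
            tally[reasons[0]] += 1
            continue
        tally["pass"] += 1
        survivors.append(call)
    return survivors, tally


def exclude_recurrent(
    calls: list[CnvCall],
    recurrent_regions: list[GenomicInterval],
    min_reciprocal: float = 0.4,
) -> list[CnvCall]:
    """Drop calls matching any known recurrent region (sensitivity filter).

    Recurrent neuropsychiatric CNVs (16p11.2, 15q11.2-13.1, ...) arise
    repeatedly at hotspot loci; excluding them checks that a gene-set
    enrichment is not driven by a handful of well-known loci.
    """
    kept = []
    for call in calls:
        hit = any(
            reciprocal_overlap(call.interval, region) >= min_reciprocal
            for region in recurrent_regions
        )
        if not hit:
            kept.append(call)
    return kept
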