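"""Amplicon copy number from SNV allele ratios, and cross-sample VAF shifts.

A heterozygous germline SNV inside an amplified segment had VAF 0.5 before
amplification.  When the amplified haplotype carries the alternative
allele, the tumor's alt:ref read-count ratio approaches C:1 for an
amplicon present at C copies per cell, so the median alt/ref ratio over
such SNVs (the VAF > 0.5 "upper branch") estimates C directly.  Segments
shared by several co-amplified structures estimate the *sum* of their copy
numbers; subtracting the known co-occupants isolates the remaining one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import GenomicSegment, SnvRecord

__all__ = [
    "CopyNumberEstimate",
    "compute_vaf",
    "assign_snvs_to_segments",
    "select_amplified_alt_branch",
    "filter_informative_snvs",
    "estimate_copies_from_ratios",
    "shared_segment_subtraction",
    "fraction_by_subsegment_presence",
    "intersect_snvs_by_location",
    "detect_vaf_shift",
]

log = logging.getLogger(__name__)


@dataclass
class CopyNumberEstimate:
    target: str
    copies_per_cell: float
    n_snvs: int
    method: str = "unique_segments"  # or shared_subtraction

    def __post_init__(self) -> None:
        if self.copies_per_cell < 0:
            raise ValueError("copies_per_cell must be non-negative")
        if self.method == "unique_segments" and self.n_snvs < 1:
            raise ValueError("unique-segment estimate requires >= 1 SNV")


def compute_vaf(alt_count: int, ref_count: int) -> float:
    """Variant allele frequency = alt / (alt + ref); errors at zero depth."""
    depth = alt_count + ref_count
    if depth <= 0:
        raise ValueError("VAF undefined at zero depth")
    return alt_count / depth


def assign_snvs_to_segments(
    snvs: Sequence[SnvRecord], segments: Sequence[GenomicSegment]
) -> dict[int, list[SnvRecord]]:
    """Map each SNV to the unique segment containing its position.

    Segments must not overlap; SNVs outside every segment are dropped (the
    count is logged).
    """
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(f"overlapping segments {a.id} and {b.id}")
    out: dict[int, list[SnvRecord]] = {s.id: [] for s in segments}
    dropped = 0
    for snv in snvs:
        hit = next(
            (s for s in ordered if s.contains(snv.chrom, snv.pos)), None
        )
        if hit is None:
            dropped += 1
        else:
            out[hit.id].append(snv)
    if dropped:
        log.info("assign_snvs_to_segments: %d SNVs outside all segments dropped", dropped)
    return out


def select_amplified_alt_branch(
    snvs: Sequence[SnvRecord],
) -> tuple[list[SnvRecord], list[SnvRecord]]:
    """Split germline SNVs into the amplified-alt (VAF > 0.5) upper branch
    and the complementary lower branch; exact ties at 0.5 are excluded."""
    upper, lower, ties = [], [], 0
    for snv in snvs:
        if snv.origin != "germline" or snv.depth == 0:
            continue
        v = snv.vaf
        if v > 0.5:
            upper.append(snv)
        elif v < 0.5:
            lower.append(snv)
        else:
            ties += 1
    if ties:
        log.info("select_amplified_alt_branch: %d SNVs at VAF exactly 0.5 excluded", ties)
    return upper, lower


def filter_informative_snvs(
    snvs: Sequence[SnvRecord], min_depth: int = 10
) -> list[SnvRecord]:
    """Minimum-depth filter to stabilize allele ratios."""
    return [s for s in snvs if s.depth >= min_depth]


def estimate_copies_from_ratios(
    snvs: Sequence[SnvRecord], target: str = "dm"
) -> CopyNumberEstimate:
    """Median alt/ref read-count ratio over the selected SNVs.

    SNVs with zero reference reads give an unbounded ratio and are excluded
    (logged); if all are excluded the estimate is undefined.
    """
    ratios = []
    skipped = 0
    for snv in snvs:
        if snv.ref_count == 0:
            skipped += 1
            continue
        ratios.append(snv.alt_count / snv.ref_count)
    if skipped:
        log.info("estimate_copies_from_ratios: %d SNVs with zero ref reads excluded", skipped)
    if not ratios:
        raise ValueError("no SNV with nonzero reference count; estimate unbounded")
    return CopyNumberEstimate(
        target=target,
        copies_per_cell=float(np.median(ratios)),
        n_snvs=len(ratios),
        method="unique_segments",
    )


def shared_segment_subtraction(
    shared_estimate: float, known_estimates: Sequence[float]
) -> float:
    """Copy number of the remaining structure on a shared segment.

    The shared segment's estimate is the sum over all structures carrying
    it; subtracting the known co-occupants leaves the unknown one.  Negative
    results clamp to zero with a warning.
    """
    remaining = shared_estimate - sum(known_estimates)
    if remaining < 0:
        log.warning(
            "shared_segment_subtraction: negative remainder %.2f clamped to 0",
            remaining,
        )
        return 0.0
    return remaining


def fraction_by_subsegment_presence(
    cn_with_feature: float, cn_other_structure: float, cn_total: float
) -> float:
    """Percent of a structure's copies that carry an optional sub-segment.

    = (cn_with_feature - cn_other_structure) / cn_total, as a percentage
    rounded to one decimal.
    """
    if cn_total <= 0:
        raise ValueError("cn_total must be positive")
    return round(100.0 * (cn_with_feature - cn_other_structure) / cn_total, 1)


def intersect_snvs_by_location(
    snvs_a: Sequence[SnvRecord], snvs_b: Sequence[SnvRecord]
) -> list[tuple[SnvRecord, SnvRecord]]:
    """Pair SNVs from two samples matched on (chrom, pos, ref, alt)."""
    index = {
        (s.chrom, s.pos, s.ref_allele, s.alt_allele): s for s in snvs_a
    }
    pairs = []
    for s in snvs_b:
        match = index.get((s.chrom, s.pos, s.ref_allele, s.alt_allele))
        if match is not None:
            pairs.append((match, s))
    log.info(
        "intersect_snvs_by_location: %d shared, %d unique to A, %d unique to B",
        len(pairs),
        len(snvs_a) - len(pairs),
        len(snvs_b) - len(pairs),
    )
    return pairs


def detect_vaf_shift(
    paired_snvs: Sequence[tuple[SnvRecord, SnvRecord]],
    low_max: float = 0.10,
    high_min: float = 0.90,
) -> list[dict]:
    """Flag pairs whose VAF jumps from <= low_max to >= high_min (either
    direction, labeled), the signature of a secondary mutation whose
    carrier structure expanded between time points."""
    flagged = []
    for a, b in paired_snvs:
        va, vb = a.vaf, b.vaf
        if va <= low_max and vb >= high_min:
            direction = "a_to_b_gain"
        elif vb <= low_max and va >= high_min:
            direction = "a_to_b_loss"
        else:
            continue
        flagged.append(
            {
                "chrom": a.chrom,
                "pos": a.pos,
                "vaf_a": va,
                "vaf_b": vb,
                "direction": direction,
                "origin": a.origin,
            }
        )
    return flagged
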