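"""Selection of highly amplified segments and reference-adjacency detection.

The tumor/normal log2 coverage ratio (log2R) of a segment measures its
amplification.  Double-minute segments sit in the far right tail of the
per-sample log2R distribution; the selection rule keeps segments with
log2R above an explicit cutoff, or above mean + 2*sd when the cutoff is
``'auto'``.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import GenomicSegment, Params

__all__ = [
    "amplification_cutoff",
    "select_amplified_segments",
    "find_adjacent_pairs",
    "compute_segment_log2r",
    "apply_boundary_overrides",
]


def amplification_cutoff(segments: Sequence[GenomicSegment], params: Params) -> float:
    """The log2R cutoff in effect: explicit, or mean + 2*sd under 'auto'."""
    if not segments:
        raise ValueError("no segments supplied")
    if params.amplified_log2r_cutoff != "auto":
        return float(params.amplified_log2r_cutoff)
    vals = np.array([s.log2r for s in segments], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite log2R under 'auto' cutoff")
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        raise ValueError(
            "log2R standard deviation is zero; supply an explicit cutoff"
        )
    return float(vals.mean() + 2.0 * sd)


def select_amplified_segments(
    segments: Sequence[GenomicSegment], params: Params
) -> list[GenomicSegment]:
    """Segments with log2R strictly above the (explicit or auto) cutoff.

    The returned list keeps the input segments' ids so that downstream
    boundary names remain stable with respect to the full segment table.
    """
    cutoff = amplification_cutoff(segments, params)
    return [s for s in segments if math.isfinite(s.log2r) and s.log2r > cutoff]


def find_adjacent_pairs(
    amplified: Sequence[GenomicSegment], params: Params
) -> list[tuple[int, int]]:
    """Pairs of amplified segments contiguous on the reference.

    A pair (i, j) is emitted when the segments are consecutive in sorted
    order on the same chromosome with an intervening gap of at most
    ``params.adjacency_max_gap`` bp.  Each pair becomes one *adjacent edge*
    joining boundary iR to boundary jL.
    """
    segs = sorted(amplified, key=lambda s: (s.chrom, s.start, s.end))
    pairs = []
    for a, b in zip(segs, segs[1:]):
        if a.chrom != b.chrom:
            continue
        gap = b.start - a.end - 1
        if gap <= params.adjacency_max_gap:
            pairs.append((a.id, b.id))
    return pairs


def _mean_depths(alignments, segments: Sequence[GenomicSegment]) -> np.ndarray:
    """Mean read depth per segment from reference-consuming aligned bases."""
    from .sv import AlignmentIndex  # local import to avoid a cycle

    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    out = np.zeros(len(segments))
    for i, seg in enumerate(segments):
        total = 0
        for rec in index.fetch(seg.chrom, seg.start, seg.end):
            # covered bases = overlap of the mapped reference span
            lo = max(rec.pos, seg.start)
            hi = min(rec.ref_end, seg.end)
            if hi >= lo:
                total += hi - lo + 1
        out[i] = total / seg.length
    return out


def compute_segment_log2r(
    tumor_alignments,
    normal_alignments,
    segments: Sequence[GenomicSegment],
    epsilon: float = 0.5,
) -> list[GenomicSegment]:
    """Fill per-segment log2R = log2((tumor depth + eps)/(normal depth + eps)).

    Depth is the mean number of reference-consuming aligned bases per
    position.  This is a coverage-ratio convenience for simulated round
    trips, not a change-point segmenter.
    """
    t = _mean_depths(tumor_alignments, segments)
    n = _mean_depths(normal_alignments, segments)
    ratio = np.log2((t + epsilon) / (n + epsilon))
    return [
        GenomicSegment(s.id, s.chrom, s.start, s.end, float(r))
        for s, r in zip(segments, ratio)
    ]


def apply_boundary_overrides(
    segments: Sequence[GenomicSegment],
    overrides: dict[int, tuple[Optional[int], Optional[int]]],
) -> list[GenomicSegment]:
    """Apply user-supplied manual boundary adjustments.

    ``overrides`` maps segment id to (new_start, new_end); ``None`` leaves a
    coordinate unchanged.  This replaces by-eye boundary curation with a
    machine-readable table.
    """
    out = []
    for s in segments:
        if s.id in overrides:
            ns, ne = overrides[s.id]
            out.append(
                GenomicSegment(
                    s.id,
                    s.chrom,
                    ns if ns is not None else s.start,
                    ne if ne is not None else s.end,
                    s.log2r,
                )
            )
        else:
            out.append(s)
    return out
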