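"""Core domain types and coordinate conventions.

Every coordinate inside this package is **1-based inclusive**, matching the
SAM text convention.  Readers convert foreign dialects (0-based half-open
BED, pysam's 0-based positions) at the edge; writers convert back.

A copy-number-alteration (CNA) segment has two *boundaries*: its 5' start
(side ``L``) and its 3' end (side ``R``).  Boundaries are the nodes of the
breakpoint graph; a structural-variant junction joins two boundaries and its
orientation class follows directly from the pair of sides involved:

====================  =============  =========================================
side pair             orientation    meaning (arrows drawn 5'->3' on the
                                     reference)
====================  =============  =========================================
(R, L) or (L, R)      head_to_tail   ``-> ->``  one segment's end to the
                                     other's start
(L, L)                tail_to_tail   ``<- ->``  the two starts fused
(R, R)                head_to_head   ``-> <-``  the two ends fused
====================  =============  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SIDE_L",
    "SIDE_R",
    "HEAD_TO_TAIL",
    "TAIL_TO_TAIL",
    "HEAD_TO_HEAD",
    "ORIENTATIONS",
    "orientation_from_sides",
    "GenomicSegment",
    "Boundary",
    "AlignmentRecord",
    "SnvRecord",
    "Params",
]

SIDE_L = "L"
SIDE_R = "R"

HEAD_TO_TAIL = "head_to_tail"
TAIL_TO_TAIL = "tail_to_tail"
HEAD_TO_HEAD = "head_to_head"
ORIENTATIONS = (HEAD_TO_TAIL, TAIL_TO_TAIL, HEAD_TO_HEAD)


def orientation_from_sides(side_a: str, side_b: str) -> str:
    """Orientation class of a junction using boundary sides ``side_a``/``side_b``.

    A junction breakend uses a segment's R side when the retained sequence
    runs leftward (5'->3') into the junction and the L side when it runs
    rightward, so the unordered side pair determines the arrow diagram.
    """
    pair = frozenset((side_a, side_b))
    if pair == frozenset((SIDE_L, SIDE_R)):
        return HEAD_TO_TAIL
    if pair == frozenset((SIDE_L,)):
        return TAIL_TO_TAIL
    if pair == frozenset((SIDE_R,)):
        return HEAD_TO_HEAD
    raise ValueError(f"invalid boundary sides: {side_a!r}, {side_b!r}")


@dataclass(frozen=True, order=True)
class GenomicSegment:
    """An amplified CNA segment; the breakpoint graph's segment edge.

    ``log2r`` is the log2 tumor/normal coverage ratio over the segment
    (unitless; > 0 means gain).  ``id`` is the 1-based rank of the segment
    after sorting by (chrom, start) within a sample.
    """

    id: int
    chrom: str
    start: int
    end: int
    log2r: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def boundary(self, side: str) -> "Boundary":
        if side == SIDE_L:
            return Boundary(self.id, SIDE_L, self.chrom, self.start)
        if side == SIDE_R:
            return Boundary(self.id, SIDE_R, self.chrom, self.end)
        raise ValueError(f"invalid side {side!r}")

    @property
    def boundaries(self) -> tuple["Boundary", "Boundary"]:
        return (self.boundary(SIDE_L), self.boundary(SIDE_R))


@dataclass(frozen=True, order=True)
class Boundary:
    """One side of a CNA segment: L = 5'/start, R = 3'/end."""

    segment_id: int
    side: str
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.side not in (SIDE_L, SIDE_R):
            raise ValueError(f"invalid side {self.side!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.segment_id, self.side)

    def __str__(self) -> str:  # paper-style "13L" / "18R"
        return f"{self.segment_id}{self.side}"


# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80

_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """A single mapped read, SAM-flavored but format-independent.

    ``pos`` is the 1-based leftmost mapped position; ``cigar`` is a tuple of
    ``(op, length)`` pairs with ops from ``MIDNSHP=X``.  ``barcode`` carries
    the linked-read molecule tag when present (10x ``BX`` by convention).
    """

    name: str
    flag: int
    chrom: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    seq: Optional[str] = None
    mapq: int = 60
    barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seq is not None:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError(
                    f"read {self.name}: CIGAR consumes {qlen} query bases "
                    f"but sequence has {len(self.seq)}"
                )

    # --- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def mate_is_reverse(self) -> bool:
        return bool(self.flag & FLAG_MATE_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    # --- geometry -----------------------------------------------------
    @property
    def ref_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost mapped reference position."""
        return self.pos + self.ref_length - 1

    @property
    def leading_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def is_softclipped(self) -> bool:
        ops = {op for op, _ in self.cigar}
        return "S" in ops and ("M" in ops or "=" in ops or "X" in ops)

    def clipped_seq(self, which: str) -> Optional[str]:
        """Clipped bases on the ``'leading'`` or ``'trailing'`` end."""
        if self.seq is None:
            return None
        if which == "leading":
            n = self.leading_clip
            return self.seq[:n] if n else None
        if which == "trailing":
            n = self.trailing_clip
            return self.seq[len(self.seq) - n :] if n else None
        raise ValueError(which)


@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide variant with allele read counts.

    VAF = alt_count / (ref_count + alt_count); undefined at zero depth.
    ``origin`` is ``germline`` or ``somatic``.
    """

    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    origin: str = "germline"
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(f"SNV {self.chrom}:{self.pos}: negative read count")
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"SNV {self.chrom}:{self.pos}: bad origin {self.origin!r}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValueError(f"SNV {self.chrom}:{self.pos}: VAF undefined at zero depth")
        return self.alt_count / self.depth


@dataclass
class Params:
    """Tunable window and threshold parameters.

    Defaults follow the method's published operating point: +/-50 bp boundary
    flanks for pulling reads, +/-1 kb flanks for placing partners, 800 bp
    minimum mate distance for discordance, 10 kb maximum separation for
    bridging mate clusters.  All are per-sample adjustable.
    """

    boundary_flank: int = 50
    search_flank: int = 1000
    discordant_min_distance: int = 800
    bridge_max_distance: int = 10_000
    amplified_log2r_cutoff: float | str = "auto"
    adjacency_max_gap: int = 10
    min_clip_match: int = 20
    min_clip_identity: float = 0.95
    uniqueness_ratio: float = 1.2
    min_sv_support: int = 2
    min_snv_depth: int = 10
    # linked-read validation
    link_window: int = 10_000
    link_bin_size: int = 1000
    corner_fold: float = 5.0
    corner_min_barcodes: int = 10
    barcode_tag: str = "BX"
    # cycle-explosion guard
    max_cycle_segments: int = 20
    max_candidates: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "boundary_flank",
            "search_flank",
            "discordant_min_distance",
            "bridge_max_distance",
            "min_clip_match",
            "link_window",
            "link_bin_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.adjacency_max_gap < 0:
            raise ValueError("adjacency_max_gap must be non-negative")
        if self.boundary_flank > self.search_flank:
            raise ValueError("boundary_flank must not exceed search_flank")
        if isinstance(self.amplified_log2r_cutoff, str) and (
            self.amplified_log2r_cutoff != "auto"
        ):
            raise ValueError("amplified_log2r_cutoff must be a number or 'auto'")

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)
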