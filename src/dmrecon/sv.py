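"""Junction (structural-variant) evidence around amplified-segment boundaries.

Three evidence classes connect two segment boundaries:

* **soft-clipped reads** — a read anchored at one boundary whose clipped
  bases place uniquely in the +/-1 kb flank of exactly one other boundary
  (the clip is re-aligned with an exact-seed prefilter followed by local
  alignment, the in-process analogue of a BLAT search);
* **discordant read pairs** — a flank read whose mate maps to another
  chromosome or >= 800 bp away, landing in another boundary's +/-1 kb flank;
* **bridging discordant reads** — two boundaries' flank reads whose mates
  cluster near each other (within 10 kb) in a region outside every boundary
  flank, implying the boundaries are joined through a short unanchored
  fragment.

Sides are read off the data: a clip on the 3' end of an anchored alignment
(or a forward-strand discordant anchor) uses the boundary's R side, a 5'
clip (or reverse-strand anchor) the L side; the side pair fixes the
junction orientation class.
"""

from __future__ import annotations


from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .io import Reference, revcomp
from .model import (
    SIDE_L,
    SIDE_R,
    AlignmentRecord,
    Boundary,
    GenomicSegment,
    Params,
    orientation_from_sides,
)

__all__ = [
    "SVEvidence",
    "AlignmentIndex",
    "reads_near_boundary",
    "softclip_evidence",
    "discordant_evidence",
    "bridging_evidence",
    "collect_sv_evidence",
    "search_breakpoints_in_sample",
]

_CLUSTER_GAP = 2000  # bp between mate positions that still count as one cluster
_SEED_LEN = 14


# ---------------------------------------------------------------------------
# Spatial index over alignment records
# ---------------------------------------------------------------------------

class AlignmentIndex:
    """Per-chromosome interval lookup over in-memory alignment records."""

    def __init__(self, records: Iterable[AlignmentRecord]):
        self._records = list(records)
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for i, r in enumerate(self._records):
            by_chrom[r.chrom].append(i)
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        self._max_span = 1
        for chrom, idxs in by_chrom.items():
            idxs.sort(key=lambda i: self._records[i].pos)
            starts = np.array([self._records[i].pos for i in idxs], dtype=np.int64)
            ends = np.array([self._records[i].ref_end for i in idxs], dtype=np.int64)
            if len(idxs):
                self._max_span = max(self._max_span, int((ends - starts).max()) + 1)
            self._chrom[chrom] = (starts, ends, idxs)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def fetch(self, chrom: str, start: int, end: int) -> list[AlignmentRecord]:
        """Records whose mapped reference span overlaps [start, end]."""
        entry = self._chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, idxs = entry
        lo = int(np.searchsorted(starts, start - self._max_span, side="left"))
        hi = int(np.searchsorted(starts, end, side="right"))
        return [
            self._records[idxs[i]]
            for i in range(lo, hi)
            if ends[i] >= start
        ]


def reads_near_boundary(alignments, boundary: Boundary, params: Params) -> list[AlignmentRecord]:
    """Reads whose mapped span overlaps the boundary's +/-``boundary_flank`` window."""
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    return index.fetch(
        boundary.chrom,
        boundary.position - params.boundary_flank,
        boundary.position + params.boundary_flank,
    )


# ---------------------------------------------------------------------------
# Evidence containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidenceIncrement:
    kind: str  # softclip | discordant
    boundary_a: Boundary
    boundary_b: Boundary
    orientation: str
    read_name: str
    breakpoint_a: Optional[int] = None
    breakpoint_b: Optional[int] = None


@dataclass
class SVEvidence:
    """An oriented junction between two boundaries with per-class read counts."""

    boundary_a: Boundary
    boundary_b: Boundary
    orientation: str
    softclip_count: int = 0
    discordant_count: int = 0
    bridging_count: int = 0
    breakpoint_a: Optional[int] = None
    breakpoint_b: Optional[int] = None
    support: dict = field(default_factory=dict)  # class -> sorted read names

    def __post_init__(self) -> None:
        if self.boundary_a.key == self.boundary_b.key:
            raise ValueError("SV evidence must join two distinct boundaries")

    @property
    def total_support(self) -> int:
        return self.softclip_count + self.discordant_count + self.bridging_count

    @property
    def pair_key(self) -> tuple:
        return (self.boundary_a.key, self.boundary_b.key, self.orientation)

    def describe(self) -> str:
        return f"{self.boundary_a}-{self.boundary_b} ({self.orientation})"


def _ordered(a: Boundary, b: Boundary) -> tuple[Boundary, Boundary, bool]:
    """Canonical order for an unordered boundary pair; True when swapped."""
    if (a.key) <= (b.key):
        return a, b, False
    return b, a, True


# ---------------------------------------------------------------------------
# Flank sequence library + clip placement
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


class FlankLibrary:
    """Cached +/-``search_flank`` reference sequence around each boundary."""

    def __init__(self, boundaries: Sequence[Boundary], reference: Reference, params: Params):
        self.params = params
        self.boundaries = list(boundaries)
        self._seq: dict[tuple[int, str], tuple[int, str]] = {}
        for b in boundaries:
            start = max(1, b.position - params.search_flank)
            end = b.position + params.search_flank
            seq = reference.fetch(b.chrom, start, end)
            self._seq[b.key] = (start, seq)
        self._aligner = _make_aligner()

    def flank(self, boundary: Boundary) -> tuple[int, str]:
        """(window start coordinate, window sequence)."""
        return self._seq[boundary.key]

    # -- clip placement ------------------------------------------------
    def _hit_one_strand(self, query: str, flank: str):
        """Best local hit of query in flank, or None.

        An exact seed (ends or middle of the clip) must occur in the flank
        before the local aligner runs — the same seed-and-extend shortcut a
        BLAT-style search applies.
        """
        k = min(len(query), _SEED_LEN)
        mid = max(0, len(query) // 2 - k // 2)
        seeds = {query[:k], query[-k:], query[mid : mid + k]}
        if not any(s in flank for s in seeds):
            return None
        aln = self._aligner.align(flank, query)
        if len(aln) == 0:
            return None
        best = aln[0]
        t_blocks, q_blocks = best.aligned
        if len(t_blocks) == 0:
            return None
        qlen = int(sum(b - a for a, b in q_blocks))
        matches = 0
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            matches += sum(1 for x, y in zip(flank[t0:t1], query[q0:q1]) if x == y)
        identity = matches / qlen if qlen else 0.0
        t_lo = int(t_blocks[0][0])
        t_hi = int(t_blocks[-1][1])  # half-open
        return float(best.score), t_lo, t_hi, identity, qlen

    def place_clip(self, clip: str, boundary: Boundary):
        """Best qualifying placement of a clipped sequence in one flank.

        Returns (score, strand, ref_lo, ref_hi) on the reference (1-based
        inclusive), or None when no placement meets the length/identity bar.
        """
        p = self.params
        win_start, flank = self.flank(boundary)
        best = None
        for strand, query in (("+", clip), ("-", revcomp(clip))):
            hit = self._hit_one_strand(query, flank)
            if hit is None:
                continue
            score, t_lo, t_hi, identity, qlen = hit
            if qlen < p.min_clip_match or identity < p.min_clip_identity:
                continue
            ref_lo = win_start + t_lo
            ref_hi = win_start + t_hi - 1
            if best is None or score > best[0]:
                best = (score, strand, ref_lo, ref_hi)
        return best


def _partner_side(anchor_side: str, strand: str) -> str:
    """Side of the partner boundary implied by the clip's hit strand."""
    if anchor_side == SIDE_R:
        return SIDE_L if strand == "+" else SIDE_R
    return SIDE_R if strand == "+" else SIDE_L


def softclip_evidence(
    read: AlignmentRecord,
    boundaries: Sequence[Boundary],
    reference,
    params: Params,
    flanks: Optional[FlankLibrary] = None,
) -> Optional[EvidenceIncrement]:
    """Soft-clip increment for one read, or None.

    The clipped subsequence (>= ``min_clip_match`` bases) is placed against
    the +/-1 kb flank of every other boundary on both strands; evidence is
    emitted only when the placement is unique (distinct best location, or
    best score >= ``uniqueness_ratio`` x the runner-up).
    """
    if flanks is None:
        flanks = FlankLibrary(boundaries, Reference(reference) if not isinstance(reference, Reference) else reference, params)
    if not read.is_softclipped or read.seq is None:
        return None
    for which, anchor_side in (("trailing", SIDE_R), ("leading", SIDE_L)):
        clip = read.clipped_seq(which)
        if clip is None or len(clip) < params.min_clip_match:
            continue
        breakpoint_a = read.ref_end if anchor_side == SIDE_R else read.pos
        anchor = _nearest_boundary(
            boundaries, read.chrom, breakpoint_a, anchor_side, params.boundary_flank
        )
        if anchor is None:
            continue
        hits = []
        for b in boundaries:
            if b.key == anchor.key:
                continue
            placed = flanks.place_clip(clip, b)
            if placed is not None:
                hits.append((b, placed))
        chosen = _resolve_unique_hit(hits, params, anchor_side)
        if chosen is None:
            continue
        partner, (score, strand, ref_lo, ref_hi) = chosen
        side_b = _partner_side(anchor_side, strand)
        breakpoint_b = ref_lo if side_b == SIDE_L else ref_hi
        a, b, swapped = _ordered(anchor, partner)
        bp_a, bp_b = (breakpoint_b, breakpoint_a) if swapped else (breakpoint_a, breakpoint_b)
        return EvidenceIncrement(
            kind="softclip",
            boundary_a=a,
            boundary_b=b,
            orientation=orientation_from_sides(anchor.side, side_b),
            read_name=read.name,
            breakpoint_a=bp_a,
            breakpoint_b=bp_b,
        )
    return None


def _nearest_boundary(
    boundaries: Sequence[Boundary],
    chrom: str,
    pos: int,
    side: str,
    max_dist: int,
) -> Optional[Boundary]:
    best = None
    for b in boundaries:
        if b.chrom != chrom or b.side != side:
            continue
        d = abs(b.position - pos)
        if d <= max_dist and (best is None or d < best[0]):
            best = (d, b)
    return best[1] if best else None


def _resolve_unique_hit(hits, params: Params, anchor_side: str):
    """Pick the unique qualifying clip placement among boundary flanks.

    Flank windows of nearby boundaries overlap, so one genomic placement may
    surface from several windows; placements at the same location collapse
    to the boundary nearest that location.  Distinct locations compete by
    score with the ``uniqueness_ratio`` rule.
    """
    if not hits:
        return None
    by_loc: dict[tuple, list] = defaultdict(list)
    for b, placed in hits:
        score, strand, ref_lo, ref_hi = placed
        by_loc[(b.chrom, strand, ref_lo, ref_hi)].append((b, placed))
    groups = []
    for loc, members in by_loc.items():
        def edge_dist(item):
            b, (_s, strand, lo, hi) = item
            side_b = _partner_side(anchor_side, strand)
            edge = lo if side_b == SIDE_L else hi
            return abs(b.position - edge)
        members.sort(key=lambda it: (edge_dist(it), it[0].key))
        groups.append(members[0])
    groups.sort(key=lambda it: -it[1][0])
    if len(groups) == 1:
        return groups[0]
    best_score = groups[0][1][0]
    second = groups[1][1][0]
    if best_score >= params.uniqueness_ratio * second:
        return groups[0]
    return None


# ---------------------------------------------------------------------------
# Discordant pairs
# ---------------------------------------------------------------------------

def _is_discordant(read: AlignmentRecord, params: Params) -> bool:
    if not read.is_paired or read.mate_unmapped or read.mate_pos is None:
        return False
    if read.mate_chrom != read.chrom:
        return True
    return abs(read.mate_pos - read.pos) >= params.discordant_min_distance


def discordant_evidence(
    flank_reads: Sequence[AlignmentRecord],
    boundary: Boundary,
    boundaries: Sequence[Boundary],
    params: Params,
) -> list[EvidenceIncrement]:
    """Discordant-pair increments for reads in one boundary's flank.

    The anchored read must point into the junction (strand matches the
    boundary side); the mate must land within ``search_flank`` of another
    boundary, whose side is read off the mate strand.  Deduplication by read
    name happens at aggregation.
    """
    out = []
    for read in flank_reads:
        if not _is_discordant(read, params):
            continue
        anchor_side = SIDE_L if read.is_reverse else SIDE_R
        if anchor_side != boundary.side:
            continue
        mate_side = SIDE_L if read.mate_is_reverse else SIDE_R
        partner = _nearest_boundary(
            boundaries, read.mate_chrom, read.mate_pos, mate_side, params.search_flank
        )
        if partner is None or partner.key == boundary.key:
            continue
        a, b, _ = _ordered(boundary, partner)
        out.append(
            EvidenceIncrement(
                kind="discordant",
                boundary_a=a,
                boundary_b=b,
                orientation=orientation_from_sides(boundary.side, mate_side),
                read_name=read.name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bridging discordant reads
# ---------------------------------------------------------------------------

def _orphan_mates(
    flank_reads: Sequence[AlignmentRecord],
    boundary: Boundary,
    boundaries: Sequence[Boundary],
    params: Params,
) -> list[tuple[str, str, int, str]]:
    """(read_name, mate_chrom, mate_pos, mate_strand) for flank reads whose
    discordant mates fall outside every boundary's +/-search_flank window."""
    out = []
    for read in flank_reads:
        if not _is_discordant(read, params):
            continue
        anchor_side = SIDE_L if read.is_reverse else SIDE_R
        if anchor_side != boundary.side:
            continue
        near_any = any(
            b.chrom == read.mate_chrom
            and abs(b.position - read.mate_pos) <= params.search_flank
            for b in boundaries
        )
        if near_any:
            continue
        out.append(
            (read.name, read.mate_chrom, read.mate_pos, "-" if read.mate_is_reverse else "+")
        )
    return out


def _main_cluster(mates: list[tuple[str, str, int, str]]):
    """Largest same-chromosome positional cluster (gap <= _CLUSTER_GAP)."""
    if not mates:
        return None
    by_chrom: dict[str, list] = defaultdict(list)
    for m in mates:
        by_chrom[m[1]].append(m)
    best = None
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda m: m[2])
        cluster = [ms[0]]
        clusters = [cluster]
        for m in ms[1:]:
            if m[2] - cluster[-1][2] <= _CLUSTER_GAP:
                cluster.append(m)
            else:
                cluster = [m]
                clusters.append(cluster)
        top = max(clusters, key=len)
        if best is None or len(top) > len(best[1]):
            best = (chrom, top)
    chrom, members = best
    positions = [m[2] for m in members]
    strands = Counter(m[3] for m in members)
    strand = strands.most_common(1)[0][0]
    median = positions[len(positions) // 2]
    names = [m[0] for m in members]
    return {"chrom": chrom, "median": median, "strand": strand, "names": names}


def bridging_evidence(
    orphans_a: list,
    orphans_b: list,
    boundary_a: Boundary,
    boundary_b: Boundary,
    params: Params,
) -> Optional[SVEvidence]:
    """Bridging increment between two boundaries from their orphan mates.

    The two mate clusters must sit on the same chromosome within
    ``bridge_max_distance`` of each other, on opposite strands pointing away
    from the intervening fragment (the reverse-strand cluster left of the
    forward one) — the configuration a single unanchored fragment joining
    a -> fragment -> b would produce.  Breakpoints stay unresolved.
    """
    ca = _main_cluster(orphans_a)
    cb = _main_cluster(orphans_b)
    if ca is None or cb is None:
        return None
    if ca["chrom"] != cb["chrom"]:
        return None
    if abs(ca["median"] - cb["median"]) > params.bridge_max_distance:
        return None
    if ca["strand"] == cb["strand"]:
        return None
    minus = ca if ca["strand"] == "-" else cb
    plus = cb if minus is ca else ca
    if minus["median"] > plus["median"]:
        return None
    count = min(len(ca["names"]), len(cb["names"]))
    if count < 1:
        return None
    a, b, swapped = _ordered(boundary_a, boundary_b)
    names = sorted(set(ca["names"]) | set(cb["names"]))
    return SVEvidence(
        boundary_a=a,
        boundary_b=b,
        orientation=orientation_from_sides(boundary_a.side, boundary_b.side),
        bridging_count=count,
        support={"bridging": names},
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def collect_sv_evidence(
    alignments,
    amplified_segments: Sequence[GenomicSegment],
    reference,
    params: Params,
) -> list[SVEvidence]:
    """All junction evidence among the amplified segments' boundaries.

    Scans every boundary's +/-``boundary_flank`` window once, aggregates
    increments into one record per (unordered boundary pair, orientation),
    deduplicates by read name within each evidence class, and keeps records
    with total support >= ``min_sv_support``.
    """
    ref = reference if isinstance(reference, Reference) else Reference(reference)
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    boundaries = [b for seg in amplified_segments for b in seg.boundaries]
    flanks = FlankLibrary(boundaries, ref, params)

    support: dict[tuple, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    breakpoints: dict[tuple, list] = defaultdict(list)
    orphans: dict[tuple, list] = {}

    for boundary in boundaries:
        reads = reads_near_boundary(index, boundary, params)
        for read in reads:
            inc = softclip_evidence(read, boundaries, ref, params, flanks=flanks)
            if inc is not None and boundary.key in (inc.boundary_a.key, inc.boundary_b.key):
                key = (inc.boundary_a, inc.boundary_b, inc.orientation)
                support[key]["softclip"].add(inc.read_name)
                breakpoints[key].append((inc.breakpoint_a, inc.breakpoint_b))
        for inc in discordant_evidence(reads, boundary, boundaries, params):
            key = (inc.boundary_a, inc.boundary_b, inc.orientation)
            support[key]["discordant"].add(inc.read_name)
        orphans[boundary.key] = _orphan_mates(reads, boundary, boundaries, params)

    bridges: dict[tuple, SVEvidence] = {}
    for i, a in enumerate(boundaries):
        for b in boundaries[i + 1 :]:
            if a.key == b.key:
                continue
            ev = bridging_evidence(orphans[a.key], orphans[b.key], a, b, params)
            if ev is not None:
                bridges[(ev.boundary_a, ev.boundary_b, ev.orientation)] = ev

    out: list[SVEvidence] = []
    keys = set(support) | set(bridges)
    for key in sorted(keys, key=lambda k: (k[0].key, k[1].key, k[2])):
        a, b, orientation = key
        classes = support.get(key, {})
        soft = sorted(classes.get("softclip", ()))
        disc = sorted(classes.get("discordant", ()))
        bridge = bridges.get(key)
        bp_a = bp_b = None
        if breakpoints.get(key):
            bp_a = Counter(x for x, _ in breakpoints[key]).most_common(1)[0][0]
            bp_b = Counter(y for _, y in breakpoints[key]).most_common(1)[0][0]
        ev = SVEvidence(
            boundary_a=a,
            boundary_b=b,
            orientation=orientation,
            softclip_count=len(soft),
            discordant_count=len(disc),
            bridging_count=bridge.bridging_count if bridge else 0,
            breakpoint_a=bp_a,
            breakpoint_b=bp_b,
            support={
                "softclip": soft,
                "discordant": disc,
                "bridging": bridge.support.get("bridging", []) if bridge else [],
            },
        )
        if ev.total_support >= params.min_sv_support:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Tabular round trip
# ---------------------------------------------------------------------------

def sv_to_rows(evidence: Sequence[SVEvidence]) -> list[dict]:
    """Flat dict rows for :func:`dmrecon.io.write_report`."""
    rows = []
    for ev in evidence:
        rows.append(
            {
                "segment_a": ev.boundary_a.segment_id,
                "side_a": ev.boundary_a.side,
                "chrom_a": ev.boundary_a.chrom,
                "pos_a": ev.boundary_a.position,
                "segment_b": ev.boundary_b.segment_id,
                "side_b": ev.boundary_b.side,
                "chrom_b": ev.boundary_b.chrom,
                "pos_b": ev.boundary_b.position,
                "orientation": ev.orientation,
                "softclip_count": ev.softclip_count,
                "discordant_count": ev.discordant_count,
                "bridging_count": ev.bridging_count,
                "breakpoint_a": ev.breakpoint_a if ev.breakpoint_a is not None else "unresolved",
                "breakpoint_b": ev.breakpoint_b if ev.breakpoint_b is not None else "unresolved",
            }
        )
    return rows


def read_sv_table(path) -> list[SVEvidence]:
    """Read back an SV table written via :func:`sv_to_rows`."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip():
                continue

            def col(name):
                return f[idx[name]]

            def bp(name):
                v = col(name)
                return None if v == "unresolved" else int(v)

            out.append(
                SVEvidence(
                    boundary_a=Boundary(int(col("segment_a")), col("side_a"), col("chrom_a"), int(col("pos_a"))),
                    boundary_b=Boundary(int(col("segment_b")), col("side_b"), col("chrom_b"), int(col("pos_b"))),
                    orientation=col("orientation"),
                    softclip_count=int(col("softclip_count")),
                    discordant_count=int(col("discordant_count")),
                    bridging_count=int(col("bridging_count")),
                    breakpoint_a=bp("breakpoint_a"),
                    breakpoint_b=bp("breakpoint_b"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cross-sample breakpoint search
# ---------------------------------------------------------------------------

def search_breakpoints_in_sample(
    alignments,
    sv_list: Sequence[SVEvidence],
    reference,
    params: Params,
) -> list[dict]:
    """Count support for known junctions in another sample's alignments.

    For each junction, soft-clipped reads at either breakpoint whose clip
    places in the partner's flank are counted, plus discordant pairs linking
    the two boundary flanks; a junction with zero support is ``absent``.
    Uniqueness against all boundaries is not required here — the junction is
    given, the question is only whether this sample contains reads for it.
    """
    ref = reference if isinstance(reference, Reference) else Reference(reference)
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    results = []
    for sv in sv_list:
        pair = (sv.boundary_a, sv.boundary_b)
        flanks = FlankLibrary(list(pair), ref, params)
        soft_names: set[str] = set()
        disc_names: set[str] = set()
        for anchor, partner in (pair, pair[::-1]):
            for read in reads_near_boundary(index, anchor, params):
                which = "trailing" if anchor.side == SIDE_R else "leading"
                clip = read.clipped_seq(which)
                if clip is not None and len(clip) >= params.min_clip_match:
                    bp = read.ref_end if anchor.side == SIDE_R else read.pos
                    if abs(bp - anchor.position) <= params.boundary_flank:
                        placed = flanks.place_clip(clip, partner)
                        if placed is not None:
                            _score, strand, _lo, _hi = placed
                            if _partner_side(anchor.side, strand) == partner.side:
                                soft_names.add(read.name)
                if _is_discordant(read, params):
                    anchor_side = SIDE_L if read.is_reverse else SIDE_R
                    mate_side = SIDE_L if read.mate_is_reverse else SIDE_R
                    if (
                        anchor_side == anchor.side
                        and mate_side == partner.side
                        and read.mate_chrom == partner.chrom
                        and abs(read.mate_pos - partner.position) <= params.search_flank
                    ):
                        disc_names.add(read.name)
        n_soft, n_disc = len(soft_names), len(disc_names)
        results.append(
            {
                "boundary_a": str(sv.boundary_a),
                "boundary_b": str(sv.boundary_b),
                "orientation": sv.orientation,
                "softclip_support": n_soft,
                "discordant_support": n_disc,
                "status": "present" if (n_soft + n_disc) > 0 else "absent",
            }
        )
    return results
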