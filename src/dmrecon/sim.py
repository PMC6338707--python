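"""Ground-truthed synthetic data for every pipeline stage.

The simulator plants one or more circular amplicons (ordered, oriented
segments of a synthetic reference) in a tumor genome and emits:

* paired-end tumor/normal alignments, **pre-aligned**: reads crossing a
  planted junction carry the correct soft-clip CIGAR, position and strand,
  and pairs straddling a junction become discordant records with correct
  mate fields — no external aligner is involved, keeping tests hermetic;
* SNV tables whose allele counts are binomially sampled around the planted
  copy number (alt:ref expectation C:1 on the amplified-alt branch);
* linked-read records: long molecules drawn along the amplicon circles and
  the diploid background, each molecule's reads sharing a barcode.

A *bridged* junction inserts a copy of a distal reference region between
two segments: junction clips then match no boundary flank (the soft-clip
route is blind) while the mates of boundary-flank reads map into the distal
source region, producing exactly the bridging-discordant configuration.

Everything is driven by one integer seed; identical seeds give identical
output, byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import Reference, revcomp, write_alignments, write_segment_table, write_snv_table
from .model import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    SIDE_L,
    SIDE_R,
    AlignmentRecord,
    GenomicSegment,
    Params,
    SnvRecord,
    orientation_from_sides,
)

__all__ = [
    "SegmentDef",
    "StructureDef",
    "ShiftSpec",
    "AmpliconPlan",
    "SimSample",
    "Fixture",
    "build_reference",
    "simulate_alignments",
    "simulate_snvs",
    "simulate_linked_reads",
    "make_fixture",
    "FIXTURE_NAMES",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentDef:
    chrom: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class ShiftSpec:
    """Somatic SNVs planted on one segment at a fixed sample VAF."""

    segment_index: int  # 1-based index into plan.segments
    count: int
    vaf: float


@dataclass(frozen=True)
class StructureDef:
    """One circular amplicon: ordered oriented segments + junction flavors.

    ``bridged`` maps the junction index (junction i sits after part i,
    wrapping) to the reference interval whose copy fills the gap.
    """

    name: str
    parts: tuple[tuple[int, str], ...]  # (segment index 1-based, '+'|'-')
    copies: float
    bridged: dict[int, tuple[str, int, int]] = field(default_factory=dict)


@dataclass
class AmpliconPlan:
    chrom_lengths: dict[str, int]
    segments: list[SegmentDef]
    structures: list[StructureDef]
    snvs_per_segment: int = 30
    somatic_shifts: list[ShiftSpec] = field(default_factory=list)
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 40.0
    normal_depth: float = 16.0
    molecule_mean_length: float = 4000.0
    molecule_coverage_per_copy: float = 4.0
    molecule_reads_per_kb: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        ordered = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        if ordered != list(self.segments):
            raise ValueError("plan segments must be pre-sorted by (chrom, start)")
        for a, b in zip(ordered, ordered[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError("plan segments overlap")
        for st in self.structures:
            for idx, orient in st.parts:
                if not (1 <= idx <= len(self.segments)):
                    raise ValueError(f"structure {st.name}: bad segment index {idx}")
                if orient not in "+-":
                    raise ValueError(f"structure {st.name}: bad orientation {orient}")

    def segment_copies(self, index: int) -> float:
        """Total amplicon copies carrying segment ``index`` (1-based)."""
        return sum(
            st.copies for st in self.structures if any(i == index for i, _ in st.parts)
        )


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def build_reference(plan: AmpliconPlan, rng: Optional[np.random.Generator] = None):
    """Synthetic reference plus per-segment truth (expected log2R, junctions)."""
    rng = rng or np.random.default_rng([plan.seed, 101])
    reference = {c: _random_seq(rng, n) for c, n in plan.chrom_lengths.items()}
    for seg in plan.segments:
        if seg.chrom not in reference or seg.end > plan.chrom_lengths[seg.chrom]:
            raise ValueError(f"segment {seg} outside reference")
    expected_log2r = {
        i + 1: math.log2((2.0 + plan.segment_copies(i + 1)) / 2.0)
        for i in range(len(plan.segments))
    }
    return reference, {"expected_log2r": expected_log2r, "junctions": plan_junctions(plan)}


def plan_junctions(plan: AmpliconPlan) -> list[dict]:
    """Planted junction truth: boundary pair, orientation and evidence class.

    Reference-contiguous same-orientation consecutive parts are *adjacent*
    junctions (no SV signal); bridged junctions carry bridging evidence
    only; everything else is a clean SV junction (soft-clip + discordant).
    """
    out: dict[tuple, dict] = {}
    for st in plan.structures:
        n = len(st.parts)
        for i in range(n):
            xi, xo = st.parts[i]
            yi, yo = st.parts[(i + 1) % n]
            sx, sy = plan.segments[xi - 1], plan.segments[yi - 1]
            side_x = SIDE_R if xo == "+" else SIDE_L
            side_y = SIDE_L if yo == "+" else SIDE_R
            if i in st.bridged:
                kind = "sv_bridged"
            elif (
                xo == yo == "+"
                and sx.chrom == sy.chrom
                and sy.start == sx.end + 1
            ):
                kind = "adjacent"
            elif (
                xo == yo == "-"
                and sx.chrom == sy.chrom
                and sx.start == sy.end + 1
            ):
                kind = "adjacent"
            else:
                kind = "sv_clean"
            a, b = sorted([(xi, side_x), (yi, side_y)])
            key = (a, b, orientation_from_sides(side_x, side_y))
            entry = out.setdefault(
                key,
                {
                    "a": a,
                    "b": b,
                    "orientation": key[2],
                    "kind": kind,
                    "structures": [],
                },
            )
            entry["structures"].append(st.name)
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# Circle assembly
# ---------------------------------------------------------------------------

@dataclass
class _Part:
    circle_start: int
    length: int
    chrom: str
    ref_start: int  # 1-based lower coordinate
    orient: str
    is_gap: bool
    junction_index: Optional[int] = None  # for gap parts: which junction
    junction_after: Optional[int] = None  # structure junction following this part

    @property
    def circle_end(self) -> int:
        return self.circle_start + self.length  # half-open

    def ref_of(self, circle_pos: int) -> int:
        off = circle_pos - self.circle_start
        if self.orient == "+":
            return self.ref_start + off
        return self.ref_start + self.length - 1 - off


@dataclass
class _Circle:
    name: str
    seq: str
    parts: list[_Part]

    @property
    def length(self) -> int:
        return len(self.seq)


def _build_circle(plan: AmpliconPlan, st: StructureDef, reference: dict) -> _Circle:
    parts: list[_Part] = []
    chunks: list[str] = []
    pos = 0

    def add(chrom, ref_start, length, orient, is_gap, junction_index=None):
        nonlocal pos
        raw = reference[chrom][ref_start - 1 : ref_start - 1 + length]
        chunks.append(raw if orient == "+" else revcomp(raw))
        # merge reference-contiguous same-orientation segment parts: a read
        # crossing that boundary maps as one plain block
        if parts and not is_gap and not parts[-1].is_gap:
            prev = parts[-1]
            if (
                prev.orient == orient == "+"
                and prev.chrom == chrom
                and prev.ref_start + prev.length == ref_start
            ):
                prev.length += length
                pos += length
                return
            if (
                prev.orient == orient == "-"
                and prev.chrom == chrom
                and ref_start + length == prev.ref_start
            ):
                prev.ref_start = ref_start
                prev.length += length
                pos += length
                return
        parts.append(
            _Part(pos, length, chrom, ref_start, orient, is_gap, junction_index)
        )
        pos += length

    n = len(st.parts)
    for i, (idx, orient) in enumerate(st.parts):
        seg = plan.segments[idx - 1]
        add(seg.chrom, seg.start, seg.end - seg.start + 1, orient, is_gap=False)
        if i in st.bridged:
            gchrom, gstart, gend = st.bridged[i]
            add(gchrom, gstart, gend - gstart + 1, "+", is_gap=True, junction_index=i)
    return _Circle(st.name, "".join(chunks), parts)


# ---------------------------------------------------------------------------
# Read mapping on a circle
# ---------------------------------------------------------------------------

def _pieces(circle: _Circle, p: int, length: int):
    """Split circle interval [p, p+length) at part boundaries.

    Returns [(q0, q1, part)] with q offsets in read-local circle-forward
    order (0 .. length)."""
    out = []
    starts = [part.circle_start for part in circle.parts]
    import bisect

    remaining = length
    q = 0
    pos = p % circle.length
    while remaining > 0:
        i = bisect.bisect_right(starts, pos) - 1
        part = circle.parts[i]
        take = min(remaining, part.circle_end - pos)
        out.append((q, q + take, part, pos))
        q += take
        remaining -= take
        pos = (pos + take) % circle.length
    return out


def _map_read(circle: _Circle, p: int, length: int, o: str):
    """Map a read occupying circle interval [p, p+length) (orientation ``o``)
    to reference coordinates.

    Returns (chrom, pos, cigar, seq, strand, anchor_part, crossed) where
    ``crossed`` lists (left_part, right_part) adjacencies the read spans
    with the flanking lengths on each side.
    """
    pieces = _pieces(circle, p, length)
    # read sequence in circle-forward frame
    pp = p % circle.length
    if pp + length <= circle.length:
        fwd = circle.seq[pp : pp + length]
    else:
        fwd = circle.seq[pp:] + circle.seq[: (pp + length) % circle.length]
    non_gap = [pc for pc in pieces if not pc[2].is_gap]
    pool = non_gap if non_gap else pieces
    anchor = max(pool, key=lambda pc: (pc[1] - pc[0], -pc[0]))
    q0, q1, part, abs0 = anchor
    po = part.orient
    ref_positions = (part.ref_of(abs0), part.ref_of(abs0 + (q1 - q0) - 1))
    ref_lo = min(ref_positions)
    seq = fwd if po == "+" else revcomp(fwd)
    lead = q0 if po == "+" else length - q1
    trail = length - q1 if po == "+" else q0
    cigar = []
    if lead:
        cigar.append(("S", lead))
    cigar.append(("M", q1 - q0))
    if trail:
        cigar.append(("S", trail))
    strand = "+" if o == po else "-"
    crossed = []
    for (a0, a1, pa, _), (b0, b1, pb, _) in zip(pieces, pieces[1:]):
        crossed.append((pa, pb, a1 - a0, b1 - b0))
    return part.chrom, ref_lo, tuple(cigar), seq, strand, part, crossed


def _junction_key(plan: AmpliconPlan, st: StructureDef, jidx: int):
    xi, xo = st.parts[jidx]
    yi, yo = st.parts[(jidx + 1) % len(st.parts)]
    side_x = SIDE_R if xo == "+" else SIDE_L
    side_y = SIDE_L if yo == "+" else SIDE_R
    a, b = sorted([(xi, side_x), (yi, side_y)])
    return (a, b, orientation_from_sides(side_x, side_y))


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimAlignments:
    tumor: list[AlignmentRecord]
    normal: list[AlignmentRecord]
    junction_reads: dict  # junction key -> {"softclip": n, "discordant": n, "bridging": n}


def _sample_fragments(rng, source_len: int, depth: float, read_len: int, insert_mean, insert_sd, circular: bool):
    n = int(round(depth * source_len / (2.0 * read_len)))
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    inserts = np.clip(
        rng.normal(insert_mean, insert_sd, size=n).round().astype(np.int64),
        2 * read_len,
        int(insert_mean + 4 * insert_sd),
    )
    if circular:
        starts = rng.integers(0, source_len, size=n)
    else:
        starts = rng.integers(0, np.maximum(1, source_len - inserts.max()), size=n)
    return starts, inserts


def _pair_records(name, rec1, rec2, proper_cutoff):
    """Combine two mapped ends into flagged records with mate fields."""
    (c1, p1, cg1, sq1, s1) = rec1
    (c2, p2, cg2, sq2, s2) = rec2
    proper = c1 == c2 and abs(p1 - p2) < proper_cutoff and s1 != s2
    base = FLAG_PAIRED | (FLAG_PROPER if proper else 0)
    f1 = base | FLAG_READ1 | (FLAG_REVERSE if s1 == "-" else 0) | (
        FLAG_MATE_REVERSE if s2 == "-" else 0
    )
    f2 = base | FLAG_READ2 | (FLAG_REVERSE if s2 == "-" else 0) | (
        FLAG_MATE_REVERSE if s1 == "-" else 0
    )
    a = AlignmentRecord(name, f1, c1, p1, cg1, mate_chrom=c2, mate_pos=p2, seq=sq1)
    b = AlignmentRecord(name, f2, c2, p2, cg2, mate_chrom=c1, mate_pos=p1, seq=sq2)
    return a, b


def _background_reads(rng, reference, depth, plan, sample_tag, out):
    rl = plan.read_length
    for chrom in sorted(reference):
        seq = reference[chrom]
        L = len(seq)
        starts, inserts = _sample_fragments(
            rng, L, depth, rl, plan.insert_mean, plan.insert_sd, circular=False
        )
        for i in range(len(starts)):
            s, ins = int(starts[i]), int(inserts[i])
            if s + ins > L:
                continue
            name = f"{sample_tag}:bg:{chrom}:{i}"
            r1 = (chrom, s + 1, (("M", rl),), seq[s : s + rl], "+")
            e = s + ins - rl
            r2 = (chrom, e + 1, (("M", rl),), seq[e : e + rl], "-")
            a, b = _pair_records(name, r1, r2, plan.insert_mean + 5 * plan.insert_sd)
            out.append(a)
            out.append(b)


def _circle_reads(rng, plan, st, circle, depth, sample_tag, out, junction_counts):
    rl = plan.read_length
    min_clip = 20
    starts, inserts = _sample_fragments(
        rng, circle.length, depth, rl, plan.insert_mean, plan.insert_sd, circular=True
    )
    for i in range(len(starts)):
        s, ins = int(starts[i]), int(inserts[i])
        name = f"{sample_tag}:{st.name}:{i}"
        m1 = _map_read(circle, s, rl, "+")
        m2 = _map_read(circle, s + ins - rl, rl, "-")
        rec1, rec2 = m1[:5], m2[:5]
        a, b = _pair_records(name, rec1, rec2, plan.insert_mean + 5 * plan.insert_sd)
        out.append(a)
        out.append(b)
        # --- truth bookkeeping -------------------------------------
        claimed = False
        for m in (m1, m2):
            for pa, pb, left_len, right_len in m[6]:
                j = _part_adjacency_junction(circle, pa, pb)
                if j is None:
                    continue
                key = _junction_key(plan, st, j)
                kind = "sv_bridged" if (pa.is_gap or pb.is_gap) else "sv_clean"
                if (
                    kind == "sv_clean"
                    and left_len >= min_clip
                    and right_len >= min_clip
                ):
                    junction_counts[key]["softclip"] += 1
                    claimed = True
        if not claimed:
            pa, pb = m1[5], m2[5]
            if pa is not pb:
                crossed = _junctions_between(circle, pa, pb)
                for j, through_gap in crossed:
                    key = _junction_key(plan, st, j)
                    junction_counts[key]["bridging" if through_gap else "discordant"] += 1


def _part_adjacency_junction(circle: _Circle, pa: _Part, pb: _Part):
    """Structure junction index for the adjacency between circle parts."""
    if pa.is_gap:
        return pa.junction_index
    if pb.is_gap:
        return pb.junction_index
    return pa.junction_after


def _junctions_between(circle: _Circle, pa: _Part, pb: _Part):
    """Junction indices crossed walking circle-forward from part a to b."""
    order = circle.parts
    ia, ib = order.index(pa), order.index(pb)
    out = []
    i = ia
    while i != ib:
        part = order[i]
        nxt = order[(i + 1) % len(order)]
        j = _part_adjacency_junction(circle, part, nxt)
        if j is not None:
            out.append((j, part.is_gap or nxt.is_gap))
        i = (i + 1) % len(order)
    # collapse duplicate junction ids (seg|gap and gap|seg are one junction)
    seen = {}
    for j, gap in out:
        seen[j] = seen.get(j, False) or gap
    return list(seen.items())


def simulate_alignments(plan: AmpliconPlan, reference: dict) -> SimAlignments:
    """Tumor and normal paired-end records plus per-junction truth counts.

    The normal sample is the diploid background at ``normal_depth``; the
    tumor adds each amplicon circle at ``copies x normal_depth / 2`` (one
    haploid genome's worth of coverage per amplicon copy).
    """
    rng = np.random.default_rng([plan.seed, 202])
    circles = {st.name: _attach_junctions(plan, st, _build_circle(plan, st, reference)) for st in plan.structures}
    from collections import defaultdict

    junction_counts: dict = defaultdict(lambda: {"softclip": 0, "discordant": 0, "bridging": 0})
    normal: list[AlignmentRecord] = []
    tumor: list[AlignmentRecord] = []
    _background_reads(rng, reference, plan.normal_depth, plan, "n", normal)
    _background_reads(rng, reference, plan.normal_depth, plan, "t", tumor)
    for st in plan.structures:
        depth = st.copies * plan.normal_depth / 2.0
        _circle_reads(rng, plan, st, circles[st.name], depth, "t", tumor, junction_counts)
    return SimAlignments(tumor=tumor, normal=normal, junction_reads=dict(junction_counts))


def _attach_junctions(plan: AmpliconPlan, st: StructureDef, circle: _Circle) -> _Circle:
    """Annotate each non-gap circle part with the structure junction index
    that follows it (accounting for merged contiguous segments)."""
    planted = 0
    for part in circle.parts:
        if part.is_gap:
            part.junction_after = None
            continue
        # how many planted segments were merged into this part
        span = 0
        length = 0
        while length < part.length:
            idx, _o = st.parts[(planted + span) % len(st.parts)]
            seg = plan.segments[idx - 1]
            length += seg.end - seg.start + 1
            span += 1
        planted += span
        part.junction_after = (planted - 1) % len(st.parts)
    return circle


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvLocus:
    chrom: str
    pos: int
    segment_index: int
    branch: str  # upper | lower
    ref_allele: str
    alt_allele: str
    origin: str  # germline | somatic
    shift_id: Optional[int] = None


def plant_snv_loci(plan: AmpliconPlan, reference: dict, rng=None) -> list[SnvLocus]:
    """Choose SNV positions, branches and alleles; shared across samples."""
    rng = rng or np.random.default_rng([plan.seed, 303])
    loci: list[SnvLocus] = []
    other = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for i, seg in enumerate(plan.segments, 1):
        n = min(plan.snvs_per_segment, seg.end - seg.start + 1)
        positions = rng.choice(
            np.arange(seg.start, seg.end + 1), size=n, replace=False
        )
        positions.sort()
        branches = rng.random(n) < 0.5
        for pos, up in zip(positions, branches):
            ref_base = reference[seg.chrom][int(pos) - 1]
            loci.append(
                SnvLocus(
                    chrom=seg.chrom,
                    pos=int(pos),
                    segment_index=i,
                    branch="upper" if up else "lower",
                    ref_allele=ref_base,
                    alt_allele=other.get(ref_base, "A"),
                    origin="germline",
                )
            )
    for shift_id, spec in enumerate(plan.somatic_shifts):
        seg = plan.segments[spec.segment_index - 1]
        positions = rng.choice(
            np.arange(seg.start, seg.end + 1), size=spec.count, replace=False
        )
        positions.sort()
        for pos in positions:
            ref_base = reference[seg.chrom][int(pos) - 1]
            loci.append(
                SnvLocus(
                    chrom=seg.chrom,
                    pos=int(pos),
                    segment_index=spec.segment_index,
                    branch="upper",
                    ref_allele=ref_base,
                    alt_allele=other.get(ref_base, "A"),
                    origin="somatic",
                    shift_id=shift_id,
                )
            )
    return loci


def simulate_snvs(
    plan: AmpliconPlan,
    reference: Optional[dict] = None,
    loci: Optional[list[SnvLocus]] = None,
    depth_override: Optional[float] = None,
) -> tuple[list[SnvRecord], list[SnvLocus]]:
    """Binomially sampled allele counts for each SNV locus under this plan.

    Germline loci on a segment carried by C amplicon copies draw alt counts
    with expectation C:1 against ref on the upper branch (1:C on the
    lower); somatic shift loci use the plan's per-sample VAF directly.
    """
    rng = np.random.default_rng([plan.seed, 404])
    if loci is None:
        if reference is None:
            raise ValueError("need a reference to place SNV loci")
        loci = plant_snv_loci(plan, reference)
    out: list[SnvRecord] = []
    for locus in loci:
        c = plan.segment_copies(locus.segment_index)
        if depth_override is not None:
            mean_depth = depth_override
        else:
            mean_depth = plan.normal_depth * (2.0 + c) / 2.0
        depth = int(rng.poisson(mean_depth))
        if depth == 0:
            continue
        if locus.origin == "somatic":
            spec = plan.somatic_shifts[locus.shift_id]
            p = spec.vaf
        elif c > 0:
            p = c / (c + 1.0) if locus.branch == "upper" else 1.0 / (c + 1.0)
        else:
            p = 0.5
        alt = int(rng.binomial(depth, p))
        out.append(
            SnvRecord(
                chrom=locus.chrom,
                pos=locus.pos,
                ref_count=depth - alt,
                alt_count=alt,
                origin=locus.origin,
                ref_allele=locus.ref_allele,
                alt_allele=locus.alt_allele,
            )
        )
    return out, loci


# ---------------------------------------------------------------------------
# Linked reads
# ---------------------------------------------------------------------------

def simulate_linked_reads(plan: AmpliconPlan, reference: dict):
    """Barcode-tagged single-end records from long molecules.

    Molecules are drawn along each amplicon circle (weight = copies) and the
    diploid background (weight 2) with exponentially distributed lengths;
    reads inside one molecule share its barcode.  Returns (records, truth)
    where truth counts molecules crossing each planted junction.
    """
    rng = np.random.default_rng([plan.seed, 505])
    records: list[AlignmentRecord] = []
    from collections import defaultdict

    crossing = defaultdict(int)
    serial = 0
    rl = plan.read_length

    def emit_molecule(source, m_start, m_len, barcode, circle=None, st=None):
        nonlocal serial
        n_reads = max(2, int(rng.poisson(m_len * plan.molecule_reads_per_kb / 1000.0)))
        offsets = np.sort(rng.integers(0, max(1, m_len - rl), size=n_reads))
        for k, off in enumerate(offsets):
            p = m_start + int(off)
            if circle is None:
                chrom, seq = source
                if p + rl > len(seq):
                    continue
                rec = (chrom, p + 1, (("M", rl),), seq[p : p + rl], "+")
                crossed = []
            else:
                m = _map_read(circle, p, rl, "+")
                rec = m[:5]
                crossed = m[6]
            chrom, pos, cigar, seqs, strand = rec
            flag = FLAG_REVERSE if strand == "-" else 0
            records.append(
                AlignmentRecord(
                    f"lr:{serial}:{k}",
                    flag,
                    chrom,
                    pos,
                    cigar,
                    seq=seqs,
                    barcode=barcode,
                )
            )
        serial += 1

    # background molecules (2 chromosomal copies)
    for chrom in sorted(reference):
        seq = reference[chrom]
        L = len(seq)
        n_mol = int(round(2 * plan.molecule_coverage_per_copy * L / plan.molecule_mean_length))
        for i in range(n_mol):
            m_len = int(np.clip(rng.exponential(plan.molecule_mean_length), 1500, 2 * plan.molecule_mean_length))
            m_start = int(rng.integers(0, max(1, L - m_len)))
            emit_molecule((chrom, seq), m_start, m_len, f"BG{chrom}:{i}")

    for st in plan.structures:
        circle = _attach_junctions(plan, st, _build_circle(plan, st, reference))
        n_mol = int(
            round(st.copies * plan.molecule_coverage_per_copy * circle.length / plan.molecule_mean_length)
        )
        for i in range(n_mol):
            m_len = int(
                np.clip(
                    rng.exponential(plan.molecule_mean_length),
                    1500,
                    min(2 * plan.molecule_mean_length, max(2000, circle.length - 1)),
                )
            )
            m_start = int(rng.integers(0, circle.length))
            barcode = f"BX{st.name}:{i}"
            emit_molecule(None, m_start, m_len, barcode, circle=circle, st=st)
            # truth: junctions inside [m_start, m_start + m_len)
            pcs = _pieces(circle, m_start, m_len)
            for (a0, a1, pa, _), (b0, b1, pb, _) in zip(pcs, pcs[1:]):
                j = _part_adjacency_junction(circle, pa, pb)
                if j is not None:
                    crossing[_junction_key(plan, st, j)] += 1
    return records, dict(crossing)


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("tiny", "relapse_like", "bridging", "invalid_cycle", "two_timepoint")

_DECOY_CHUNK = 20_000


@dataclass
class SimSample:
    """One simulated sample: alignments, SNVs, optional linked reads, truth."""

    name: str
    plan: AmpliconPlan
    tumor: list
    normal: list
    snvs: list
    linked: Optional[list]
    junction_truth: list[dict]  # junctions in table-id space
    junction_reads: dict  # table-id junction key -> class counts
    structures: dict  # name -> {copies, tour (table-id space)}


@dataclass
class Fixture:
    """A self-contained, ground-truthed dataset for the whole pipeline."""

    name: str
    seed: int
    reference: dict
    params: Params
    candidate_segments: list[GenomicSegment]
    samples: dict
    id_map: dict  # plan segment index -> candidate-table segment id
    extras: dict = field(default_factory=dict)


def _candidate_table(plan: AmpliconPlan) -> tuple[list[GenomicSegment], dict[int, int]]:
    """Planted segments plus background decoy intervals, sorted and id'd."""
    intervals: list[tuple[str, int, int, Optional[int]]] = []
    for i, seg in enumerate(plan.segments, 1):
        intervals.append((seg.chrom, seg.start, seg.end, i))
    for chrom in sorted(plan.chrom_lengths):
        length = plan.chrom_lengths[chrom]
        planted = sorted(
            (s.start, s.end) for s in plan.segments if s.chrom == chrom
        )
        cursor = 1
        gaps = []
        for s, e in planted:
            if s > cursor:
                gaps.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= length:
            gaps.append((cursor, length))
        for gs, ge in gaps:
            pos = gs
            while pos <= ge:
                end = min(ge, pos + _DECOY_CHUNK - 1)
                if end - pos + 1 >= 1000:  # skip slivers
                    intervals.append((chrom, pos, end, None))
                pos = end + 1
    intervals.sort(key=lambda t: (t[0], t[1]))
    segments = []
    id_map: dict[int, int] = {}
    for table_id, (chrom, start, end, plan_idx) in enumerate(intervals, 1):
        segments.append(GenomicSegment(table_id, chrom, start, end, 0.0))
        if plan_idx is not None:
            id_map[plan_idx] = table_id
    return segments, id_map


def _remap_junctions(junctions: list[dict], id_map: dict[int, int]) -> list[dict]:
    out = []
    for j in junctions:
        a = (id_map[j["a"][0]], j["a"][1])
        b = (id_map[j["b"][0]], j["b"][1])
        out.append({**j, "a": a, "b": b})
    return out


def _remap_key(key, id_map):
    (ai, aside), (bi, bside), orientation = key
    a, b = sorted([(id_map[ai], aside), (id_map[bi], bside)])
    return (a, b, orientation)


def _structure_tours(plan: AmpliconPlan, id_map) -> dict:
    return {
        st.name: {
            "copies": st.copies,
            "tour": [
                (id_map[idx], "forward" if o == "+" else "reverse")
                for idx, o in st.parts
            ],
            "unique_segments": [
                id_map[idx]
                for idx, _o in st.parts
                if sum(
                    1
                    for other in plan.structures
                    if any(i == idx for i, _ in other.parts)
                )
                == 1
            ],
        }
        for st in plan.structures
    }


def _make_sample(
    name: str,
    plan: AmpliconPlan,
    reference: dict,
    id_map: dict,
    with_linked: bool,
    loci=None,
    snv_only: bool = False,
):
    junctions = _remap_junctions(plan_junctions(plan), id_map)
    if snv_only:
        sim = SimAlignments([], [], {})
    else:
        sim = simulate_alignments(plan, reference)
    snvs, loci = simulate_snvs(plan, reference, loci=loci)
    linked = None
    if with_linked:
        linked, _cross = simulate_linked_reads(plan, reference)
    return (
        SimSample(
            name=name,
            plan=plan,
            tumor=sim.tumor,
            normal=sim.normal,
            snvs=snvs,
            linked=linked,
            junction_truth=junctions,
            junction_reads={
                _remap_key(k, id_map): v for k, v in sim.junction_reads.items()
            },
            structures=_structure_tours(plan, id_map),
        ),
        loci,
    )


def _plan_tiny(seed: int) -> AmpliconPlan:
    return AmpliconPlan(
        chrom_lengths={"chr1": 100_000},
        segments=[SegmentDef("chr1", 10_001, 30_000), SegmentDef("chr1", 50_001, 70_000)],
        structures=[StructureDef("dmA", ((1, "+"), (2, "+")), copies=10.0)],
        molecule_coverage_per_copy=5.0,
        seed=seed,
    )


def _plan_bridging(seed: int) -> AmpliconPlan:
    return AmpliconPlan(
        chrom_lengths={"chr1": 110_000},
        segments=[SegmentDef("chr1", 10_001, 30_000), SegmentDef("chr1", 50_001, 70_000)],
        structures=[
            StructureDef(
                "dmA",
                ((1, "+"), (2, "+")),
                copies=12.0,
                bridged={0: ("chr1", 80_001, 82_000)},
            )
        ],
        seed=seed,
    )


def _plan_relapse_like(seed: int) -> AmpliconPlan:
    return AmpliconPlan(
        chrom_lengths={"chr1": 320_000},
        segments=[
            SegmentDef("chr1", 10_001, 30_000),   # s1
            SegmentDef("chr1", 42_001, 58_000),   # s2 (shared dmA/dmD)
            SegmentDef("chr1", 70_001, 84_000),   # s3
            SegmentDef("chr1", 84_001, 87_000),   # s4 (adjacent to s3, short)
            SegmentDef("chr1", 100_001, 120_000), # s5
            SegmentDef("chr1", 132_001, 148_000), # s6
            SegmentDef("chr1", 160_001, 174_000), # s7 (shared dmC/dmE)
            SegmentDef("chr1", 186_001, 202_000), # s8
            SegmentDef("chr1", 214_001, 230_000), # s9
            SegmentDef("chr1", 242_001, 256_000), # s10
        ],
        structures=[
            StructureDef("dmA", ((1, "+"), (2, "+")), copies=20.0),
            StructureDef("dmB", ((3, "+"), (4, "+"), (5, "-")), copies=12.0),
            StructureDef("dmC", ((6, "+"), (7, "+")), copies=8.0),
            StructureDef("dmD", ((8, "+"), (2, "+")), copies=16.0),
            StructureDef("dmE", ((9, "+"), (10, "+"), (7, "-")), copies=5.0),
        ],
        normal_depth=12.0,
        snvs_per_segment=60,
        molecule_coverage_per_copy=5.0,
        seed=seed,
    )


def _plan_invalid_cycle(seed: int) -> AmpliconPlan:
    return AmpliconPlan(
        chrom_lengths={"chr1": 220_000},
        segments=[
            SegmentDef("chr1", 30_001, 50_000),   # s1
            SegmentDef("chr1", 50_001, 66_000),   # s2 (reference-adjacent to s1)
            SegmentDef("chr1", 110_001, 130_000), # s3 (shared by both circles)
        ],
        structures=[
            StructureDef("dmA", ((1, "+"), (3, "+")), copies=18.0),
            StructureDef("dmB", ((3, "+"), (2, "+")), copies=12.0),
        ],
        normal_depth=12.0,
        seed=seed,
    )


def _plans_two_timepoint(seed: int) -> tuple[AmpliconPlan, AmpliconPlan]:
    common = dict(
        chrom_lengths={"chr1": 170_000},
        segments=[
            SegmentDef("chr1", 20_001, 30_000),   # s1 (conserved, carries shift SNVs)
            SegmentDef("chr1", 45_001, 55_000),   # s2 (conserved)
            SegmentDef("chr1", 70_001, 80_000),   # s3 (diagnosis only)
            SegmentDef("chr1", 95_001, 105_000),  # s4 (diagnosis only)
            SegmentDef("chr1", 120_001, 130_000), # s5 (relapse only)
            SegmentDef("chr1", 145_001, 155_000), # s6 (relapse only)
        ],
        seed=seed,
    )
    diagnosis = AmpliconPlan(
        structures=[
            StructureDef("dm1", ((1, "+"), (2, "+")), copies=18.0),
            StructureDef("dm2", ((3, "+"), (4, "+")), copies=12.0),
        ],
        somatic_shifts=[ShiftSpec(1, 4, 0.02)],
        **common,
    )
    relapse = AmpliconPlan(
        structures=[
            StructureDef("dm1", ((1, "+"), (2, "+")), copies=25.0),
            StructureDef("dm3", ((5, "+"), (6, "+")), copies=15.0),
        ],
        somatic_shifts=[ShiftSpec(1, 4, 0.96)],
        **common,
    )
    return diagnosis, relapse


def make_fixture(name: str, seed: int = 0, out_dir=None) -> Fixture:
    """Build one of the bundled ground-truthed fixtures.

    tiny          one 2-segment circle; end-to-end in seconds.
    relapse_like  five circles with distinct copy numbers sharing segments.
    bridging      a junction joined through a 2 kb unanchored fragment.
    invalid_cycle evidence admitting a cycle no molecule supports.
    two_timepoint a conserved circle with a VAF-shift mutation set plus
                  circles unique to each time point.

    When ``out_dir`` is given the fixture is also written to disk (FASTA,
    SAM, TSV, truth JSON).
    """
    if name == "tiny":
        plan = _plan_tiny(seed)
        reference, _ = build_reference(plan)
        segments, id_map = _candidate_table(plan)
        sample, _ = _make_sample("tumor", plan, reference, id_map, with_linked=True)
        samples = {"tumor": sample}
        extras = {}
    elif name == "bridging":
        plan = _plan_bridging(seed)
        reference, _ = build_reference(plan)
        segments, id_map = _candidate_table(plan)
        sample, _ = _make_sample("tumor", plan, reference, id_map, with_linked=False)
        samples = {"tumor": sample}
        extras = {}
    elif name == "relapse_like":
        plan = _plan_relapse_like(seed)
        reference, _ = build_reference(plan)
        segments, id_map = _candidate_table(plan)
        sample, _ = _make_sample("tumor", plan, reference, id_map, with_linked=True)
        samples = {"tumor": sample}
        extras = {}
    elif name == "invalid_cycle":
        plan = _plan_invalid_cycle(seed)
        reference, _ = build_reference(plan)
        segments, id_map = _candidate_table(plan)
        sample, _ = _make_sample("tumor", plan, reference, id_map, with_linked=True)
        samples = {"tumor": sample}
        # the cycle the evidence admits but no molecule supports
        extras = {
            "false_cycle_tour": [
                (id_map[1], "forward"),
                (id_map[2], "forward"),
                (id_map[3], "forward"),
            ]
        }
    elif name == "two_timepoint":
        plan_d, plan_r = _plans_two_timepoint(seed)
        reference, _ = build_reference(plan_d)
        segments, id_map = _candidate_table(plan_d)
        sample_d, loci = _make_sample("diagnosis", plan_d, reference, id_map, with_linked=False)
        sample_r, _ = _make_sample("relapse", plan_r, reference, id_map, with_linked=False, loci=loci)
        samples = {"diagnosis": sample_d, "relapse": sample_r}
        shift_positions = sorted(
            (l.chrom, l.pos) for l in loci if l.origin == "somatic"
        )
        extras = {"shift_positions": shift_positions}
        plan = plan_d
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")

    params = Params(amplified_log2r_cutoff=1.0, link_window=8000, seed=seed)
    fixture = Fixture(
        name=name,
        seed=seed,
        reference=reference,
        params=params,
        candidate_segments=segments,
        samples=samples,
        id_map=id_map,
        extras=extras,
    )
    if out_dir is not None:
        _write_fixture(fixture, Path(out_dir))
    return fixture


def _write_fixture(fx: Fixture, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(fx.reference.items())],
        str(out_dir / "reference.fa"),
        "fasta",
    )
    write_segment_table(fx.candidate_segments, out_dir / "candidate_segments.tsv")
    contigs = {c: len(s) for c, s in sorted(fx.reference.items())}
    truth = {
        "name": fx.name,
        "seed": fx.seed,
        "id_map": {str(k): v for k, v in fx.id_map.items()},
        "extras": fx.extras,
        "samples": {},
    }
    for sname, sample in fx.samples.items():
        write_alignments(sample.tumor, out_dir / f"{sname}.tumor.sam", contigs)
        write_alignments(sample.normal, out_dir / f"{sname}.normal.sam", contigs)
        write_snv_table(sample.snvs, out_dir / f"{sname}.snvs.tsv")
        if sample.linked is not None:
            write_alignments(sample.linked, out_dir / f"{sname}.linked.sam", contigs)
        truth["samples"][sname] = {
            "junctions": [
                {**j, "a": list(j["a"]), "b": list(j["b"])}
                for j in sample.junction_truth
            ],
            "structures": sample.structures,
        }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
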