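"""Junction evidence: clip placement, discordant pairs, bridging clusters."""

import random

import numpy as np
import pytest

from dmrecon.io import Reference, revcomp
from dmrecon.model import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_REVERSE,
    AlignmentRecord,
    GenomicSegment,
    Params,
)
from dmrecon.sv import (
    AlignmentIndex,
    bridging_evidence,
    collect_sv_evidence,
    read_sv_table,
    reads_near_boundary,
    sv_to_rows,
)
from dmrecon.io import write_report


def _random_ref(n=30_000, seed=7):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def setting():
    seq = _random_ref()
    segments = [
        GenomicSegment(1, "chr1", 2001, 8000, 5.0),
        GenomicSegment(2, "chr1", 14_001, 20_000, 5.0),
    ]
    return Reference({"chr1": seq}), seq, segments


PARAMS = Params(amplified_log2r_cutoff=1.0, min_sv_support=1)


def _clip_read(seq, anchor_start, clip_seq, leading=False, name="r"):
    """A 100 bp read: 50 aligned bases + 50 clipped bases."""
    m = seq[anchor_start - 1 : anchor_start + 49]
    if leading:
        return AlignmentRecord(name, 0, "chr1", anchor_start, (("S", 50), ("M", 50)), seq=clip_seq + m)
    return AlignmentRecord(name, 0, "chr1", anchor_start, (("M", 50), ("S", 50)), seq=m + clip_seq)


def test_reads_near_boundary_overlap_window(setting):
    ref, seq, segments = setting
    b = segments[0].boundary("R")  # position 8000
    reads = [
        AlignmentRecord("span", 0, "chr1", 7960, (("M", 100),)),
        AlignmentRecord("far", 0, "chr1", 8200, (("M", 100),)),
    ]
    got = [r.name for r in reads_near_boundary(reads, b, PARAMS)]
    assert got == ["span"]


def test_softclip_head_to_tail_with_exact_breakpoints(setting):
    ref, seq, segments = setting
    # clip carries the forward sequence starting at seg2's start
    read = _clip_read(seq, 7951, seq[14_000:14_050])
    evs = collect_sv_evidence([read], segments, ref, PARAMS)
    (ev,) = evs
    assert (str(ev.boundary_a), str(ev.boundary_b)) == ("1R", "2L")
    assert ev.orientation == "head_to_tail"
    assert ev.softclip_count == 1
    assert (ev.breakpoint_a, ev.breakpoint_b) == (8000, 14_001)


def test_softclip_head_to_head_reverse_strand_hit(setting):
    ref, seq, segments = setting
    # clip is the reverse complement of seg2's terminal 50 bases
    read = _clip_read(seq, 7951, revcomp(seq[19_950:20_000]))
    (ev,) = collect_sv_evidence([read], segments, ref, PARAMS)
    assert (str(ev.boundary_a), str(ev.boundary_b)) == ("1R", "2R")
    assert ev.orientation == "head_to_head"
    assert ev.breakpoint_b == 20_000


def test_softclip_tail_to_tail_from_leading_clip(setting):
    ref, seq, segments = setting
    read = _clip_read(seq, 2001, revcomp(seq[14_000:14_050]), leading=True)
    (ev,) = collect_sv_evidence([read], segments, ref, PARAMS)
    assert (str(ev.boundary_a), str(ev.boundary_b)) == ("1L", "2L")
    assert ev.orientation == "tail_to_tail"


def test_softclip_nonunique_clip_rejected():
    """A clip matching two boundary flanks equally well yields nothing."""
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))
    dup = "".join(bases[rng.integers(0, 4, 200)])
    seq = list(_random_ref(40_000, seed=11))
    seq[14_000:14_200] = dup  # seg2 start
    seq[26_000:26_200] = dup  # seg3 start (identical flank)
    seq = "".join(seq)
    segments = [
        GenomicSegment(1, "chr1", 2001, 8000, 5.0),
        GenomicSegment(2, "chr1", 14_001, 20_000, 5.0),
        GenomicSegment(3, "chr1", 26_001, 32_000, 5.0),
    ]
    read = _clip_read(seq, 7951, seq[14_000:14_050])
    assert collect_sv_evidence([read], segments, Reference({"chr1": seq}), PARAMS) == []


def test_unclipped_read_contributes_nothing(setting):
    ref, seq, segments = setting
    read = AlignmentRecord("plain", 0, "chr1", 7951, (("M", 100),), seq=seq[7950:8050])
    assert collect_sv_evidence([read], segments, ref, PARAMS) == []


def _pair(name, pos_a, rev_a, pos_b, rev_b, seq):
    fa = FLAG_PAIRED | (FLAG_REVERSE if rev_a else 0) | (FLAG_MATE_REVERSE if rev_b else 0)
    fb = FLAG_PAIRED | (FLAG_REVERSE if rev_b else 0) | (FLAG_MATE_REVERSE if rev_a else 0)
    a = AlignmentRecord(name, fa, "chr1", pos_a, (("M", 100),), mate_chrom="chr1", mate_pos=pos_b)
    b = AlignmentRecord(name, fb, "chr1", pos_b, (("M", 100),), mate_chrom="chr1", mate_pos=pos_a)
    return a, b


def test_discordant_pair_counted_once(setting):
    ref, seq, segments = setting
    # forward anchor at 1R flank, reverse mate just inside 2L's 1 kb flank
    a, b = _pair("p1", 7940, False, 14_050, True, seq)
    (ev,) = collect_sv_evidence([a, b], segments, ref, PARAMS)
    assert (str(ev.boundary_a), str(ev.boundary_b), ev.orientation) == ("1R", "2L", "head_to_tail")
    assert ev.discordant_count == 1  # both records of the template, one count


def test_concordant_distance_is_not_discordant(setting):
    ref, seq, segments = setting
    a, b = _pair("p2", 7940, False, 8_300, True, seq)  # 360 bp apart
    assert collect_sv_evidence([a, b], segments, ref, PARAMS) == []


class TestBridgingClusters:
    A = GenomicSegment(1, "chr1", 2001, 8000, 5.0).boundary("R")
    B = GenomicSegment(2, "chr1", 14_001, 20_000, 5.0).boundary("L")

    @staticmethod
    def _orphans(center, strand, n=5):
        return [(f"m{center}:{i}", "chr1", center + 30 * i, strand) for i in range(n)]

    def test_opposite_strand_clusters_within_10kb(self):
        ev = bridging_evidence(
            self._orphans(24_000, "-"), self._orphans(25_800, "+"), self.A, self.B, Params()
        )
        assert ev is not None
        assert ev.orientation == "head_to_tail"
        assert ev.bridging_count == 5
        assert ev.breakpoint_a is None and ev.breakpoint_b is None

    def test_clusters_too_far_apart(self):
        ev = bridging_evidence(
            self._orphans(24_000, "-"), self._orphans(74_000, "+"), self.A, self.B, Params()
        )
        assert ev is None

    def test_same_strand_clusters_rejected(self):
        ev = bridging_evidence(
            self._orphans(24_000, "-"), self._orphans(25_800, "-"), self.A, self.B, Params()
        )
        assert ev is None


def test_evidence_invariant_to_record_order(tiny):
    fx, res = tiny
    s = fx.samples["tumor"]
    shuffled = list(s.tumor)
    random.Random(0).shuffle(shuffled)
    again = collect_sv_evidence(
        AlignmentIndex(shuffled), res.amplified, fx.reference, fx.params
    )
    key = lambda evs: {
        (ev.boundary_a.key, ev.boundary_b.key, ev.orientation): (
            ev.softclip_count,
            ev.discordant_count,
            ev.bridging_count,
        )
        for ev in evs
    }
    assert key(again) == key(res.evidence)


def test_simulated_breakpoints_match_planted_boundaries(tiny):
    """With every junction read traceable, clip-derived breakpoints equal
    the planted segment boundaries exactly."""
    fx, res = tiny
    positions = {b.key: b.position for seg in res.amplified for b in seg.boundaries}
    for ev in res.evidence:
        assert ev.breakpoint_a == positions[ev.boundary_a.key]
        assert ev.breakpoint_b == positions[ev.boundary_b.key]


def test_sv_table_round_trip(tmp_path, tiny):
    fx, res = tiny
    p = tmp_path / "sv.tsv"
    write_report(sv_to_rows(res.evidence), p, "TSV")
    back = read_sv_table(p)
    assert [(ev.boundary_a.key, ev.boundary_b.key, ev.orientation, ev.softclip_count) for ev in back] == [
        (ev.boundary_a.key, ev.boundary_b.key, ev.orientation, ev.softclip_count) for ev in res.evidence
    ]
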