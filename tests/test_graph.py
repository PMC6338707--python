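"""Cycle enumeration, canonicalization and the alternation filter, checked
against independent brute-force oracles on random boundary graphs."""

import itertools
from collections import defaultdict

import numpy as np
import pytest

from dmrecon.graph import (
    BoundaryGraph,
    CandidateCycle,
    build_boundary_graph,
    canonical_key,
    canonical_tour,
    deduplicate_reverse_cycles,
    enumerate_simple_cycles,
    filter_valid_cycles,
    report_structures,
)
from dmrecon.model import Boundary, GenomicSegment
from dmrecon.sv import SVEvidence


def _segments(n, length=1000):
    return [
        GenomicSegment(i, "chr1", 1 + (i - 1) * 10_000, (i - 1) * 10_000 + length, 5.0)
        for i in range(1, n + 1)
    ]


def _sv(segs, a_key, b_key):
    by_id = {s.id: s for s in segs}
    a = by_id[a_key[0]].boundary(a_key[1])
    b = by_id[b_key[0]].boundary(b_key[1])
    a, b = sorted([a, b], key=lambda x: x.key)
    from dmrecon.model import orientation_from_sides

    return SVEvidence(
        boundary_a=a,
        boundary_b=b,
        orientation=orientation_from_sides(a.side, b.side),
        softclip_count=1,
    )


# ---------------------------------------------------------------------------
# Independent oracles (plain DFS, no shared code with dmrecon.graph)
# ---------------------------------------------------------------------------

def _adjacency(graph):
    adj = defaultdict(list)
    for e in graph.edges:
        adj[e.a].append((e.id, e.b, e.kind))
        adj[e.b].append((e.id, e.a, e.kind))
    return adj


def brute_force_simple_cycles(graph):
    """Edge sets of all simple cycles (>= 2 distinct edges)."""
    adj = _adjacency(graph)
    nodes = sorted(graph.nodes)
    found = set()

    def dfs(start, current, visited, used_edges):
        for eid, other, _kind in adj[current]:
            if eid in used_edges:
                continue
            if other == start:
                if len(used_edges) + 1 >= 2:
                    found.add(frozenset(used_edges | {eid}))
                continue
            if other in visited or other < start:
                continue
            dfs(start, other, visited | {other}, used_edges | {eid})

    for start in nodes:
        dfs(start, start, {start}, frozenset())
    return found


def brute_force_alternating_cycles(graph):
    """Edge sets of simple cycles that alternate segment and junction edges."""
    adj = _adjacency(graph)
    nodes = sorted(graph.nodes)
    found = set()

    def dfs(start, current, visited, used_edges, first_kind, last_kind):
        for eid, other, kind in adj[current]:
            if eid in used_edges:
                continue
            is_seg = kind == "segment"
            if last_kind is not None and is_seg == (last_kind == "segment"):
                continue  # must alternate
            if other == start:
                m = len(used_edges) + 1
                if m >= 2 and m % 2 == 0 and kind != first_kind:
                    found.add(frozenset(used_edges | {eid}))
                continue
            if other in visited or other < start:
                continue
            dfs(start, other, visited | {other}, used_edges | {eid}, first_kind or kind, kind)

    for start in nodes:
        dfs(start, start, {start}, frozenset(), None, None)
    return found


def _random_graph(rng, max_segments=8):
    n = int(rng.integers(1, max_segments + 1))
    segs = _segments(n)
    keys = [(i, s) for i in range(1, n + 1) for s in "LR"]
    n_sv = int(rng.integers(0, 2 * n + 1))
    svs = []
    for _ in range(n_sv):
        a, b = rng.choice(len(keys), size=2, replace=False)
        svs.append(_sv(segs, keys[a], keys[b]))
    adjacent = [(i, i + 1) for i in range(1, n) if rng.random() < 0.3]
    return build_boundary_graph(segs, svs, adjacent)


# ---------------------------------------------------------------------------
# Hand-built examples
# ---------------------------------------------------------------------------

def test_single_segment_self_circle():
    """Smallest circularizable graph: one segment whose L and R boundaries
    are joined by one sv edge -> 2 nodes, 2 edges, 2 raw directed cycles."""
    segs = _segments(1)
    graph = build_boundary_graph(segs, [_sv(segs, (1, "L"), (1, "R"))], [])
    assert len(graph.nodes) == 2 and len(graph.edges) == 2
    raw = enumerate_simple_cycles(graph)
    assert len(raw) == 2
    canon = deduplicate_reverse_cycles(raw)
    assert len(canon) == 1
    assert len(filter_valid_cycles(canon, graph)) == 1


def test_node_count_is_twice_segment_count():
    segs = _segments(29)
    svs = [_sv(segs, (i, "R"), (i + 1, "L")) for i in range(1, 18)]
    adjacent = [(i, i + 1) for i in range(11, 29)]
    graph = build_boundary_graph(segs, svs, adjacent)
    assert len(graph.nodes) == 58
    assert sum(1 for e in graph.edges if e.kind == "segment") == 29


def test_duplicate_sv_rows_merge_with_summed_counts():
    segs = _segments(2)
    a = _sv(segs, (1, "R"), (2, "L"))
    b = _sv(segs, (1, "R"), (2, "L"))
    graph = build_boundary_graph(segs, [a, b], [])
    sv_edges = [e for e in graph.edges if e.kind == "sv"]
    assert len(sv_edges) == 1
    assert sv_edges[0].payload.softclip_count == 2


def test_two_segment_double_sv_cycle_matches_dfs_oracle():
    segs = _segments(2)
    svs = [_sv(segs, (1, "L"), (2, "L")), _sv(segs, (1, "R"), (2, "R"))]
    graph = build_boundary_graph(segs, svs, [])
    raw = enumerate_simple_cycles(graph)
    got = {frozenset(e for _, e in steps) for steps in raw}
    assert got == brute_force_simple_cycles(graph)
    valid = filter_valid_cycles(deduplicate_reverse_cycles(raw), graph)
    (cycle,) = valid
    tour = cycle.segment_tour(graph)
    # one segment traversed forward, the other reversed (L-L / R-R joins)
    assert sorted(o for _, o in tour) == ["forward", "reverse"]


def test_unknown_segment_reference_rejected():
    segs = _segments(2)
    stray = _sv(_segments(3), (3, "L"), (1, "R"))
    with pytest.raises(ValueError, match="unknown"):
        build_boundary_graph(segs, [stray], [])


def test_cycle_with_single_boundary_visit_removed():
    """A cycle entering and leaving a segment through junction edges only
    (one boundary pair used, no segment edge) fails the alternation rule."""
    segs = _segments(3)
    svs = [
        _sv(segs, (1, "R"), (2, "L")),
        _sv(segs, (2, "L"), (3, "L")),  # re-uses 2L: invalid path through seg2
        _sv(segs, (3, "R"), (1, "L")),
        _sv(segs, (2, "R"), (1, "L")),
    ]
    graph = build_boundary_graph(segs, svs, [])
    valid = filter_valid_cycles(
        deduplicate_reverse_cycles(enumerate_simple_cycles(graph)), graph
    )
    for cycle in valid:
        assert cycle.is_alternating(graph)
        for sid, _o in cycle.segment_tour(graph):
            assert sid in (1, 2, 3)
    oracle = brute_force_alternating_cycles(graph)
    assert {frozenset(c.edge_ids()) for c in valid} == oracle


def test_canonical_key_rotation_reflection_invariant():
    rng = np.random.default_rng(0)
    for _ in range(50):
        graph = _random_graph(rng, max_segments=6)
        raw = enumerate_simple_cycles(graph)
        for steps in raw[:10]:
            n = len(steps)
            r = int(rng.integers(0, n))
            rotated = tuple(steps[(r + i) % n] for i in range(n))
            nodes = [s[0] for s in steps]
            edges = [s[1] for s in steps]
            reflected = tuple(zip([nodes[0]] + nodes[:0:-1], edges[::-1]))
            assert canonical_key(rotated) == canonical_key(steps)
            assert canonical_key(reflected) == canonical_key(steps)


def test_canonical_tour_invariance():
    tour = [(3, "forward"), (5, "reverse"), (9, "forward")]
    rotated = tour[1:] + tour[:1]
    reflected = [(sid, "forward" if o == "reverse" else "reverse") for sid, o in reversed(tour)]
    assert canonical_tour(tour) == canonical_tour(rotated) == canonical_tour(reflected)


def test_report_total_length_is_sum_of_segments():
    segs = [
        GenomicSegment(1, "chr1", 1, 100_000, 5.0),
        GenomicSegment(2, "chr1", 200_001, 400_000, 5.0),
        GenomicSegment(3, "chr1", 500_001, 603_000, 5.0),
    ]
    svs = [
        _sv(segs, (1, "R"), (2, "L")),
        _sv(segs, (2, "R"), (3, "L")),
        _sv(segs, (3, "R"), (1, "L")),
    ]
    graph = build_boundary_graph(segs, svs, [])
    valid = filter_valid_cycles(
        deduplicate_reverse_cycles(enumerate_simple_cycles(graph)), graph
    )
    (row,) = report_structures(valid, graph)
    assert row["total_length"] == 403_000
    assert row["n_junctions"] == 3


def test_gene_annotation_by_interval_overlap(tmp_path):
    segs = _segments(2, length=5000)
    svs = [_sv(segs, (1, "R"), (2, "L")), _sv(segs, (2, "R"), (1, "L"))]
    graph = build_boundary_graph(segs, svs, [])
    valid = filter_valid_cycles(
        deduplicate_reverse_cycles(enumerate_simple_cycles(graph)), graph
    )
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t1200\t1400\tEGFR\nchr1\t900000\t900100\tMYC\n")
    (row,) = report_structures(valid, graph, gene_bed=bed)
    assert row["genes"] == ["EGFR"]
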