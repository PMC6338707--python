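"""Bidirected boundary graph and candidate-cycle enumeration.

Each amplified segment contributes two nodes (its L and R boundaries) and a
*segment edge* joining them; junction evidence contributes *sv edges* and
reference contiguity *adjacent edges*.  Every edge is traversable in both
directions, so a circular amplicon appears as a simple cycle that
alternates segment edges with junction edges — entering a segment at one
boundary and leaving it at the other.

Enumeration runs Johnson's simple-cycle algorithm (via networkx) on a
directed expansion in which every bidirected edge becomes an intermediate
edge-token node with arcs in both directions; node-simplicity then
guarantees both node- and edge-distinctness and each undirected cycle is
reported exactly once per traversal direction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .model import SIDE_L, SIDE_R, Boundary, GenomicSegment
from .sv import SVEvidence

__all__ = [
    "GraphEdge",
    "BoundaryGraph",
    "CandidateCycle",
    "build_boundary_graph",
    "enumerate_simple_cycles",
    "deduplicate_reverse_cycles",
    "filter_valid_cycles",
    "report_structures",
]

BKey = tuple[int, str]  # (segment_id, side)


@dataclass(frozen=True)
class GraphEdge:
    id: int
    kind: str  # segment | sv | adjacent
    a: BKey
    b: BKey
    payload: object = None

    def other(self, node: BKey) -> BKey:
        if node == self.a:
            return self.b
        if node == self.b:
            return self.a
        raise ValueError(f"{node} not an endpoint of edge {self.id}")


@dataclass
class BoundaryGraph:
    nodes: dict[BKey, Boundary]
    edges: list[GraphEdge]
    segments: dict[int, GenomicSegment]

    def edges_at(self, node: BKey) -> list[GraphEdge]:
        return [e for e in self.edges if node in (e.a, e.b)]


class CycleExplosionError(RuntimeError):
    pass


def build_boundary_graph(
    amplified_segments: Sequence[GenomicSegment],
    sv_evidence: Sequence[SVEvidence],
    adjacent_pairs: Sequence[tuple[int, int]],
) -> BoundaryGraph:
    """Assemble the boundary graph from segments, junctions and adjacencies.

    Duplicate junction rows for the same (boundary pair, orientation) merge
    into a single sv edge with summed evidence counts.
    """
    segments = {s.id: s for s in amplified_segments}
    nodes: dict[BKey, Boundary] = {}
    for seg in amplified_segments:
        for b in seg.boundaries:
            nodes[b.key] = b
    edges: list[GraphEdge] = []
    eid = 0
    for seg in sorted(segments.values(), key=lambda s: s.id):
        edges.append(GraphEdge(eid, "segment", (seg.id, SIDE_L), (seg.id, SIDE_R), seg))
        eid += 1

    merged: dict[tuple, SVEvidence] = {}
    for sv in sv_evidence:
        for b in (sv.boundary_a, sv.boundary_b):
            if b.key not in nodes:
                raise ValueError(f"SV references unknown segment boundary {b}")
        key = sv.pair_key
        if key in merged:
            prev = merged[key]
            merged[key] = SVEvidence(
                boundary_a=prev.boundary_a,
                boundary_b=prev.boundary_b,
                orientation=prev.orientation,
                softclip_count=prev.softclip_count + sv.softclip_count,
                discordant_count=prev.discordant_count + sv.discordant_count,
                bridging_count=prev.bridging_count + sv.bridging_count,
                breakpoint_a=prev.breakpoint_a or sv.breakpoint_a,
                breakpoint_b=prev.breakpoint_b or sv.breakpoint_b,
            )
        else:
            merged[key] = sv
    for key in sorted(merged, key=lambda k: (k[0], k[1], k[2])):
        sv = merged[key]
        edges.append(GraphEdge(eid, "sv", sv.boundary_a.key, sv.boundary_b.key, sv))
        eid += 1

    for i, j in sorted(adjacent_pairs):
        if i not in segments or j not in segments:
            raise ValueError(f"adjacent pair ({i}, {j}) references unknown segment")
        edges.append(GraphEdge(eid, "adjacent", (i, SIDE_R), (j, SIDE_L), (i, j)))
        eid += 1
    return BoundaryGraph(nodes=nodes, edges=edges, segments=segments)


# ---------------------------------------------------------------------------
# Raw cycle enumeration
# ---------------------------------------------------------------------------

RawCycle = tuple[tuple[BKey, int], ...]  # ((node, edge-to-next), ...) cyclic


def enumerate_simple_cycles(
    graph: BoundaryGraph,
    max_candidates: Optional[int] = None,
) -> list[RawCycle]:
    """All simple cycles of the bidirected graph, once per direction.

    A raw cycle is a cyclic tuple of (node, edge id) steps using >= 2
    distinct edges; the degenerate two-step walk out and back over a single
    edge is not a cycle.  Output order is deterministic.
    """
    dg = nx.DiGraph()
    for e in graph.edges:
        na, nb, ne = ("n", e.a), ("n", e.b), ("e", e.id)
        dg.add_edge(na, ne)
        dg.add_edge(ne, na)
        dg.add_edge(nb, ne)
        dg.add_edge(ne, nb)
    out: list[RawCycle] = []
    for cyc in nx.simple_cycles(dg):
        if len(cyc) < 4:  # one edge token: there-and-back artifact
            continue
        # rotate so the cycle starts at the smallest node token
        node_positions = [i for i, t in enumerate(cyc) if t[0] == "n"]
        start = min(node_positions, key=lambda i: cyc[i][1])
        cyc = cyc[start:] + cyc[:start]
        steps = []
        for i in range(0, len(cyc), 2):
            node = cyc[i][1]
            edge_id = cyc[i + 1][1]
            steps.append((node, edge_id))
        out.append(tuple(steps))
        if max_candidates is not None and len(out) > max_candidates:
            raise CycleExplosionError(
                f"more than {max_candidates} raw cycles; raise the guard or "
                "prune the evidence set"
            )
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Canonicalization / dedup
# ---------------------------------------------------------------------------

def canonical_key(steps: RawCycle) -> tuple:
    """Rotation- and reflection-invariant identifier of a cycle.

    The key is the lexicographically minimal rotation over both traversal
    directions of the (node, edge) step sequence.
    """
    n = len(steps)
    variants = []
    for r in range(n):
        variants.append(tuple(steps[(r + i) % n] for i in range(n)))
    # reflection: reverse node order; edge i of the reverse connects
    # node_{i} back to node_{i-1}, i.e. edges shift by one position
    nodes = [s[0] for s in steps]
    edges = [s[1] for s in steps]
    rnodes = [nodes[0]] + nodes[:0:-1]
    redges = edges[::-1]
    rsteps = tuple(zip(rnodes, redges))
    for r in range(n):
        variants.append(tuple(rsteps[(r + i) % n] for i in range(n)))
    return min(variants)


@dataclass
class CandidateCycle:
    """A canonical simple cycle: a putative circular amplicon."""

    steps: RawCycle
    key: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.key = canonical_key(self.steps)

    @property
    def n_edges(self) -> int:
        return len(self.steps)

    def edge_ids(self) -> list[int]:
        return [e for _, e in self.steps]

    def is_alternating(self, graph: BoundaryGraph) -> bool:
        """True when segment edges alternate with junction (sv/adjacent)
        edges, i.e. every visited segment contributes both boundaries."""
        if self.n_edges % 2 != 0:
            return False
        kinds = [
            "segment" if graph.edges[eid].kind == "segment" else "junction"
            for eid in self.edge_ids()
        ]
        for parity in (0, 1):
            if all(
                k == ("segment" if i % 2 == parity else "junction")
                for i, k in enumerate(kinds)
            ):
                return True
        return False

    def segment_tour(self, graph: BoundaryGraph) -> list[tuple[int, str]]:
        """Ordered (segment_id, 'forward'|'reverse') traversal of an
        alternating cycle; forward = entered at L, left at R."""
        if not self.is_alternating(graph):
            raise ValueError("segment tour undefined for non-alternating cycle")
        steps = list(self.steps)
        if graph.edges[steps[0][1]].kind != "segment":
            steps = steps[1:] + steps[:1]
        tour = []
        for i in range(0, len(steps), 2):
            node, eid = steps[i]
            seg = graph.edges[eid].payload
            orient = "forward" if node[1] == SIDE_L else "reverse"
            tour.append((seg.id, orient))
        return tour

    def junction_edges(self, graph: BoundaryGraph) -> list[GraphEdge]:
        """Junction (sv/adjacent) edges in traversal order, aligned with
        :meth:`segment_tour` (edge i follows segment i)."""
        steps = list(self.steps)
        if graph.edges[steps[0][1]].kind != "segment":
            steps = steps[1:] + steps[:1]
        return [graph.edges[steps[i][1]] for i in range(1, len(steps), 2)]

    def total_length(self, graph: BoundaryGraph) -> int:
        return sum(
            graph.edges[eid].payload.length
            for eid in self.edge_ids()
            if graph.edges[eid].kind == "segment"
        )


def canonical_tour(tour: Sequence[tuple[int, str]]) -> tuple:
    """Rotation/reflection-invariant form of a (segment, orientation) tour.

    Reflection reverses the visiting order and flips every orientation —
    the same circle read off the opposite strand.
    """
    tour = list(tour)
    n = len(tour)
    flipped = [
        (sid, "forward" if o == "reverse" else "reverse") for sid, o in reversed(tour)
    ]
    variants = []
    for base in (tour, flipped):
        for r in range(n):
            variants.append(tuple(base[(r + i) % n] for i in range(n)))
    return min(variants)


def deduplicate_reverse_cycles(raw_cycles: Sequence[RawCycle]) -> list[CandidateCycle]:
    """One representative per rotation/reflection equivalence class."""
    seen: dict[tuple, RawCycle] = {}
    for steps in raw_cycles:
        key = canonical_key(steps)
        if key not in seen:
            seen[key] = key  # store the canonical form itself
    return [CandidateCycle(steps=key) for key in sorted(seen)]


def filter_valid_cycles(
    cycles: Sequence[CandidateCycle], graph: BoundaryGraph
) -> list[CandidateCycle]:
    """Drop cycles that pass through only one boundary of some segment.

    Formalized as the alternation predicate: a valid circular structure
    alternates segment edges and junction edges all the way around.
    """
    return [c for c in cycles if c.is_alternating(graph)]


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _tour_string(tour: list[tuple[int, str]]) -> str:
    return "->".join(
        f"seg{sid}{'+' if orient == 'forward' else '-'}" for sid, orient in tour
    )


def _read_gene_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2]), f[3] if len(f) > 3 else "."))
    return out


def report_structures(
    cycles: Sequence[CandidateCycle],
    graph: BoundaryGraph,
    gene_bed=None,
) -> list[dict]:
    """Per-cycle report: ordered segment string, length, junctions, genes.

    Cycles are named dm1, dm2, ... in order of decreasing total length
    (ties broken by canonical key) mirroring how structures are usually
    listed largest-first.
    """
    genes = _read_gene_bed(gene_bed) if gene_bed is not None else []
    ordered = sorted(cycles, key=lambda c: (-c.total_length(graph), c.key))
    rows = []
    for i, cyc in enumerate(ordered, 1):
        tour = cyc.segment_tour(graph)
        junctions = []
        for e in cyc.junction_edges(graph):
            if e.kind == "sv":
                sv: SVEvidence = e.payload
                junctions.append(
                    {
                        "type": "sv",
                        "boundaries": f"{sv.boundary_a}-{sv.boundary_b}",
                        "orientation": sv.orientation,
                        "softclip": sv.softclip_count,
                        "discordant": sv.discordant_count,
                        "bridging": sv.bridging_count,
                    }
                )
            else:
                junctions.append(
                    {"type": "adjacent", "boundaries": f"{e.a[0]}R-{e.b[0]}L"}
                )
        overlapped = []
        for chrom, gstart, gend, name in genes:
            for sid, _orient in tour:
                seg = graph.segments[sid]
                if seg.chrom == chrom and seg.start <= gend and gstart <= seg.end:
                    overlapped.append(name)
                    break
        rows.append(
            {
                "name": f"dm{i}",
                "structure": _tour_string(tour),
                "tour": [list(t) for t in tour],
                "n_segments": len(tour),
                "n_junctions": len(junctions),
                "total_length": cyc.total_length(graph),
                "junctions": junctions,
                "genes": sorted(set(overlapped)),
            }
        )
    return rows
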