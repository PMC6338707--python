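"""End-to-end orchestration: segments -> SV evidence -> cycles -> report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .graph import (
    BoundaryGraph,
    CandidateCycle,
    build_boundary_graph,
    deduplicate_reverse_cycles,
    enumerate_simple_cycles,
    filter_valid_cycles,
    report_structures,
)
from .io import Reference
from .model import GenomicSegment, Params
from .segments import compute_segment_log2r, find_adjacent_pairs, select_amplified_segments
from .sv import AlignmentIndex, SVEvidence, collect_sv_evidence

__all__ = ["ReconstructionResult", "reconstruct"]


@dataclass
class ReconstructionResult:
    segments: list[GenomicSegment]  # full table with log2r filled
    amplified: list[GenomicSegment]
    adjacent_pairs: list[tuple[int, int]]
    evidence: list[SVEvidence]
    graph: BoundaryGraph
    n_raw_cycles: int
    candidates: list[CandidateCycle]
    valid_cycles: list[CandidateCycle]
    report: list[dict]

    @property
    def valid_tours(self) -> list[list[tuple[int, str]]]:
        return [c.segment_tour(self.graph) for c in self.valid_cycles]


def reconstruct(
    tumor_alignments,
    normal_alignments,
    candidate_segments: Sequence[GenomicSegment],
    reference,
    params: Optional[Params] = None,
    gene_bed=None,
    recompute_log2r: bool = True,
) -> ReconstructionResult:
    """Run the full reconstruction on one tumor/normal pair.

    ``candidate_segments`` is the segmentation table; when
    ``recompute_log2r`` is set the log2R column is (re)derived from the two
    alignment sets, otherwise the table's values are trusted.
    """
    params = params or Params()
    ref = reference if isinstance(reference, Reference) else Reference(reference)
    tumor = (
        tumor_alignments
        if isinstance(tumor_alignments, AlignmentIndex)
        else AlignmentIndex(tumor_alignments)
    )
    segments = list(candidate_segments)
    if recompute_log2r:
        normal = (
            normal_alignments
            if isinstance(normal_alignments, AlignmentIndex)
            else AlignmentIndex(normal_alignments)
        )
        segments = compute_segment_log2r(tumor, normal, segments)
    amplified = select_amplified_segments(segments, params)
    adjacent = find_adjacent_pairs(amplified, params)
    evidence = collect_sv_evidence(tumor, amplified, ref, params)
    graph = build_boundary_graph(amplified, evidence, adjacent)
    raw = enumerate_simple_cycles(graph, max_candidates=params.max_candidates)
    candidates = deduplicate_reverse_cycles(raw)
    valid = filter_valid_cycles(candidates, graph)
    report = report_structures(valid, graph, gene_bed=gene_bed)
    return ReconstructionResult(
        segments=segments,
        amplified=amplified,
        adjacent_pairs=adjacent,
        evidence=evidence,
        graph=graph,
        n_raw_cycles=len(raw),
        candidates=candidates,
        valid_cycles=valid,
        report=report,
    )
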