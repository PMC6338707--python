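"""Simulator contracts: determinism, truth-table consistency, evidence
classes forced by construction."""

import numpy as np
import pytest

from dmrecon.sim import (
    AmpliconPlan,
    SegmentDef,
    StructureDef,
    build_reference,
    make_fixture,
    plan_junctions,
    simulate_alignments,
    simulate_linked_reads,
    simulate_snvs,
)


def _basic_plan(seed=0, copies=10.0, **kw):
    return AmpliconPlan(
        chrom_lengths={"chr1": 60_000},
        segments=[SegmentDef("chr1", 10_001, 22_000), SegmentDef("chr1", 35_001, 47_000)],
        structures=[StructureDef("dm", ((1, "+"), (2, "+")), copies=copies)] if copies else [],
        seed=seed,
        **kw,
    )


def test_reference_determinism_and_truth():
    plan = _basic_plan(seed=9)
    ref1, truth1 = build_reference(plan)
    ref2, _ = build_reference(_basic_plan(seed=9))
    assert ref1 == ref2  # byte-identical
    ref3, _ = build_reference(_basic_plan(seed=10))
    assert ref1 != ref3
    assert truth1["expected_log2r"][1] == pytest.approx(np.log2(12 / 2))


def test_plan_validation():
    with pytest.raises(ValueError, match="overlap"):
        AmpliconPlan(
            chrom_lengths={"chr1": 50_000},
            segments=[SegmentDef("chr1", 1000, 5000), SegmentDef("chr1", 4000, 9000)],
            structures=[],
        )
    with pytest.raises(ValueError, match="bad segment index"):
        AmpliconPlan(
            chrom_lengths={"chr1": 50_000},
            segments=[SegmentDef("chr1", 1000, 5000)],
            structures=[StructureDef("x", ((2, "+"),), copies=1.0)],
        )


def test_junction_truth_kinds():
    plan = AmpliconPlan(
        chrom_lengths={"chr1": 100_000},
        segments=[
            SegmentDef("chr1", 10_001, 20_000),
            SegmentDef("chr1", 20_001, 30_000),  # reference-adjacent to s1
            SegmentDef("chr1", 50_001, 60_000),
        ],
        structures=[
            StructureDef(
                "dm",
                ((1, "+"), (2, "+"), (3, "-")),
                copies=8.0,
                bridged={2: ("chr1", 80_001, 82_000)},  # junction s3 -> s1
            )
        ],
    )
    truth = {(j["a"], j["b"]): (j["kind"], j["orientation"]) for j in plan_junctions(plan)}
    assert truth[((1, "R"), (2, "L"))] == ("adjacent", "head_to_tail")
    assert truth[((2, "R"), (3, "R"))] == ("sv_clean", "head_to_head")
    assert truth[((1, "L"), (3, "L"))] == ("sv_bridged", "tail_to_tail")


def test_alignment_determinism_and_no_amplicon_case():
    plan = _basic_plan(seed=4)
    ref, _ = build_reference(plan)
    sim1 = simulate_alignments(plan, ref)
    sim2 = simulate_alignments(_basic_plan(seed=4), ref)
    assert sim1.tumor == sim2.tumor and sim1.normal == sim2.normal

    flat = _basic_plan(seed=4, copies=0)
    ref0, _ = build_reference(flat)
    sim0 = simulate_alignments(flat, ref0)
    assert sim0.junction_reads == {}
    # tumor and normal have the same background read budget
    assert abs(len(sim0.tumor) - len(sim0.normal)) / len(sim0.normal) < 0.05


def test_junction_truth_counts_match_evidence_classes(bridging):
    """Bridged junctions produce zero traceable soft-clips but bridging
    pairs; clean junctions produce both soft-clip and discordant reads."""
    fx, res = bridging
    s = fx.samples["tumor"]
    kinds = {(tuple(j["a"]), tuple(j["b"])): j["kind"] for j in s.junction_truth}
    recovered = {(ev.boundary_a.key, ev.boundary_b.key): ev for ev in res.evidence}
    for pair, kind in kinds.items():
        ev = recovered[pair]
        if kind == "sv_bridged":
            assert ev.softclip_count == 0
            assert ev.bridging_count > 0
            assert ev.breakpoint_a is None  # unresolved
        elif kind == "sv_clean":
            assert ev.softclip_count > 0
            assert ev.discordant_count > 0


def test_snv_branch_means_reflect_copy_number():
    plan = _basic_plan(seed=2, copies=43.0, snvs_per_segment=200, normal_depth=40.0)
    ref, _ = build_reference(plan)
    snvs, loci = simulate_snvs(plan, ref)
    by_branch = {"upper": [], "lower": []}
    for snv, locus in zip(snvs, loci):
        by_branch[locus.branch].append(snv.vaf)
    assert np.mean(by_branch["upper"]) == pytest.approx(43 / 44, abs=0.01)
    assert np.mean(by_branch["lower"]) == pytest.approx(1 / 44, abs=0.01)


def test_snv_loci_shared_across_samples():
    plan_a = _basic_plan(seed=6, copies=10.0)
    ref, _ = build_reference(plan_a)
    _, loci = simulate_snvs(plan_a, ref)
    plan_b = _basic_plan(seed=6, copies=30.0)
    snvs_b, loci_b = simulate_snvs(plan_b, ref, loci=loci)
    assert loci_b is loci
    assert {(s.chrom, s.pos) for s in snvs_b} <= {(l.chrom, l.pos) for l in loci}


def test_linked_reads_share_barcode_within_molecule():
    plan = _basic_plan(seed=8)
    ref, _ = build_reference(plan)
    records, crossing = simulate_linked_reads(plan, ref)
    assert all(r.barcode for r in records)
    # every planted junction is crossed by some molecules
    keys = {((a), (b)) for (a, b, _o) in crossing}
    assert len(crossing) == 2
    assert all(n > 0 for n in crossing.values())


def test_fixture_names_and_unknown_rejected():
    with pytest.raises(ValueError, match="unknown fixture"):
        make_fixture("nope", seed=0)


def test_fixture_directory_round_trip(tmp_path, tiny):
    """A written fixture can be read back and reproduces the in-memory one."""
    from dmrecon.io import read_alignments, read_segment_table, read_snv_table

    fx, _res = tiny
    out = tmp_path / "fx"
    fx2 = make_fixture("tiny", seed=fx.seed, out_dir=out)
    assert (out / "truth.json").exists()
    segs = read_segment_table(out / "candidate_segments.tsv")
    assert segs == fx2.candidate_segments
    back = list(read_alignments(out / "tumor.tumor.sam"))
    assert len(back) == len(fx2.samples["tumor"].tumor)
    first = fx2.samples["tumor"].tumor[0]
    assert (back[0].name, back[0].pos, back[0].cigar) == (first.name, first.pos, first.cigar)
    snvs = read_snv_table(out / "tumor.snvs.tsv")
    assert len(snvs) == len(fx2.samples["tumor"].snvs)
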