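"""Synthetic cohort generator: determinism, conservation, replay, validation."""

import numpy as np
import pytest
from scipy import stats

import acrodj as aj
from acrodj.simulate import (ArchitectureSpec, CohortSpec, ExchangeEvent,
                             SharedIndel, build_ancestor, evolve_cohort)


SMALL_ARCH = ArchitectureSpec(rdna_stub_len=1000, unique1_len=10000,
                              ir_arm_len=2000, ir_spacer_len=500,
                              unique2_len=2000, satellite_len=2400,
                              tail_len=3000)


def test_ancestor_layout_and_inverted_arm():
    anc, ann = build_ancestor(ArchitectureSpec(ir_arm_len=5000), seed=1)
    arms = [a for a in ann if a.feature_class == "inverted_repeat_arm"]
    assert len(arms) == 2
    a1, a2 = arms
    assert a1.length == 5000 and a2.length == 5000
    arm1 = aj.Contig("a", anc.sequence[a1.start:a1.end])
    assert anc.sequence[a2.start:a2.end] == arm1.reverse_complement().sequence


def test_satellite_exact_monomer_count():
    spec = ArchitectureSpec(satellite_period=48, satellite_len=4800)
    anc, ann = build_ancestor(spec, seed=2)
    sat = next(a for a in ann if a.feature_class == "satellite_block")
    assert sat.length == 4800
    monomer = anc.sequence[sat.start : sat.start + 48]
    assert anc.sequence[sat.start : sat.end] == monomer * 100


def test_ancestor_determinism():
    a1, _ = build_ancestor(SMALL_ARCH, seed=3)
    a2, _ = build_ancestor(SMALL_ARCH, seed=3)
    assert a1.sequence == a2.sequence
    a3, _ = build_ancestor(SMALL_ARCH, seed=4)
    assert a3.sequence != a1.sequence


def test_ancestor_max_length_guard():
    with pytest.raises(ValueError, match="exceeds"):
        build_ancestor(ArchitectureSpec(tail_len=10_000_000), seed=0)


def test_cohort_determinism_and_conservation(fig2d):
    _, _, cohort, manifest = fig2d
    anc2, ann2, cohort2, manifest2 = aj.simulate_preset("fig2d")
    assert [c.sequence for c in cohort] == [c.sequence for c in cohort2]
    assert manifest.group_substitutions == manifest2.group_substitutions
    # members without indels/inserts/exchanges conserve ancestor length
    anc, _, _, _ = fig2d
    for cid in ("A9-14", "A9-15"):
        member = next(c for c in cohort if c.id == cid)
        assert member.length == anc.length


def test_zero_rate_no_event_cohort_identical_to_ancestor():
    anc, ann = build_ancestor(SMALL_ARCH, seed=5)
    spec = CohortSpec(groups=[("g1", ["m1", "m2"])], proximal_sub_rate=0.0,
                      distal_sub_rate=0.0, seed=5)
    cohort, manifest = evolve_cohort(anc, spec, ann)
    assert all(c.sequence == anc.sequence for c in cohort)


def test_substitution_count_within_binomial_bounds():
    anc, ann = build_ancestor(SMALL_ARCH, seed=6)
    spec = CohortSpec(groups=[("g1", ["m1"])], proximal_sub_rate=0.01,
                      distal_sub_rate=0.0, seed=6)
    cohort, manifest = evolve_cohort(anc, spec, ann)
    n = 10000  # proximal unique1 region scale: count subs in first 10 kb
    subs_in_region = sum(1 for pos, _ in manifest.members["m1"].substitutions
                         if pos < n)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.01)
    assert lo <= subs_in_region <= hi


def test_replay_reproduces_every_member(fig2d):
    anc, _, cohort, manifest = fig2d
    replayed = aj.replay_manifest(anc, manifest)
    assert [c.sequence for c in replayed] == [c.sequence for c in cohort]


def test_manifest_json_round_trip(tmp_path, fig2d):
    anc, _, cohort, manifest = fig2d
    p = tmp_path / "manifest.json"
    manifest.to_json(p)
    back = aj.SimManifest.from_json(p)
    assert back.pieces == manifest.pieces
    assert back.marker_truth() == manifest.marker_truth()
    replayed = aj.replay_manifest(anc, back)
    assert [c.sequence for c in replayed] == [c.sequence for c in cohort]


def test_fig2d_marker_truth_matches_printed_pattern(fig2d):
    """One lineage (the recombinant) carries both the group-3 marker and the
    two group-1 markers, mirroring the published carrier pattern."""
    _, _, _, manifest = fig2d
    truth = manifest.marker_truth()
    assert truth[0] == {"A9-13", "A9-21", "GM10063"}
    assert truth[1] == truth[2] == {"A9-22", "WAV17", "GM10063"}
    assert manifest.group_truth()["GM10063"] == "g3"


def test_overlapping_shared_indels_rejected():
    anc, ann = build_ancestor(SMALL_ARCH, seed=7)
    spec = CohortSpec(
        groups=[("g1", ["m1"])],
        shared_indels=[SharedIndel(("g1",), 2000, 500, "deletion"),
                       SharedIndel(("g1",), 2300, 100, "deletion")],
        seed=7)
    with pytest.raises(ValueError, match="overlapping"):
        evolve_cohort(anc, spec, ann)


def test_exchange_breakpoint_outside_contig_rejected():
    anc, ann = build_ancestor(SMALL_ARCH, seed=8)
    spec = CohortSpec(
        groups=[("g1", ["m1", "m2"])],
        exchange_events=[ExchangeEvent("m1", "m2", anc.length + 10)],
        seed=8)
    with pytest.raises(ValueError, match="breakpoint"):
        evolve_cohort(anc, spec, ann)


def test_indel_outside_proximal_region_rejected():
    anc, ann = build_ancestor(SMALL_ARCH, seed=9)
    sat = next(a for a in ann if a.feature_class == "satellite_block")
    spec = CohortSpec(
        groups=[("g1", ["m1"])],
        shared_indels=[SharedIndel(("g1",), sat.start + 100, 200, "deletion")],
        seed=9)
    with pytest.raises(ValueError, match="proximal"):
        evolve_cohort(anc, spec, ann)


def test_rate_validation():
    with pytest.raises(ValueError):
        CohortSpec(groups=[("g1", ["m1"])], proximal_sub_rate=0.7)
    with pytest.raises(ValueError):
        CohortSpec(groups=[("g1", ["m1"]), ("g2", ["m1"])])


def test_paper_scale_preset_architecture():
    """The paper-scale preset lays out 100-kb IR arms and places the three
    shared deletions at the 110/161/172-kb reference positions."""
    from acrodj.simulate import preset

    arch, cohort_spec = preset("paper-scale")
    anc, ann = build_ancestor(arch, cohort_spec.seed)
    assert anc.length == pytest.approx(400_000, abs=100)
    arms = [a for a in ann if a.feature_class == "inverted_repeat_arm"]
    assert [a.length for a in arms] == [100_000, 100_000]
    positions = [i.position for i in cohort_spec.shared_indels]
    assert positions == [110_000, 161_000, 172_000]
    a1 = arms[0]
    assert all(a1.start <= p < a1.end for p in positions)


def test_insertion_type_shared_indel_round_trips():
    anc, ann = build_ancestor(SMALL_ARCH, seed=10)
    spec = CohortSpec(
        groups=[("g1", ["m1", "m2"]), ("g2", ["m3"])],
        proximal_sub_rate=0.0, distal_sub_rate=0.0,
        shared_indels=[SharedIndel(("g1",), 3000, 400, "insertion")],
        seed=10)
    cohort, manifest = evolve_cohort(anc, spec, ann)
    m1, m3 = cohort[0], cohort[2]
    assert m1.length == anc.length + 400
    assert m3.sequence == anc.sequence
    assert m1.sequence[:3000] == anc.sequence[:3000]
    assert m1.sequence[3400:] == anc.sequence[3000:]
    replayed = aj.replay_manifest(anc, manifest)
    assert replayed[0].sequence == m1.sequence
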