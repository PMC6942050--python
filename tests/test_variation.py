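"""Indel calling, breakpoint matching, four-gamete test, exchange intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import acrodj as aj
from acrodj.variation import (DELETION, INSERTION, Marker, candidate_matches,
                              left_normalize)

from conftest import mutate, random_dna


def test_simple_deletion_call_left_normalized():
    ref, qry = "AAAATTTTCCCC", "AAAACCCC"
    aln = aj.global_align(qry, ref)
    calls = aj.call_indels(aln, ref, qry, min_len=2, flank=4)
    assert len(calls) == 1
    c = calls[0]
    assert (c.type, c.length, c.ref_pos) == (DELETION, 4, 4)
    assert c.left_flank == "AAAA" and c.right_flank == "CCCC"


def test_identical_sequences_no_calls():
    aln = aj.global_align("ACGTACGT", "ACGTACGT")
    assert aj.call_indels(aln, "ACGTACGT", "ACGTACGT", min_len=1) == []


def test_left_normalization_in_repeat_run():
    # deletion of one "AT" from an (AT)n run must shift to the run start
    ref = "GGGG" + "AT" * 6 + "CCCC"
    qry = "GGGG" + "AT" * 4 + "CCCC"
    aln = aj.global_align(qry, ref)
    calls = aj.call_indels(aln, ref, qry, min_len=2, flank=4)
    assert len(calls) == 1
    assert calls[0].ref_pos == 4  # run start


@given(st.text(alphabet="ACGT", min_size=10, max_size=80),
       st.integers(min_value=0, max_value=1000),
       st.integers(min_value=1, max_value=8))
def test_left_normalize_idempotent(ref, pos_raw, length):
    if length >= len(ref):
        return
    pos = pos_raw % (len(ref) - length)
    p1, _ = left_normalize(ref, pos, length, DELETION)
    p2, _ = left_normalize(ref, p1, length, DELETION)
    assert p1 == p2
    ins = ref[pos : pos + length]  # an arbitrary inserted string
    q1, s1 = left_normalize(ref, pos, length, INSERTION, ins)
    q2, s2 = left_normalize(ref, q1, length, INSERTION, s1)
    assert (q1, s1) == (q2, s2)


def test_match_breakpoints_clusters_identical_events():
    rng = np.random.default_rng(22)
    ref = random_dna(4000, rng)
    qry = ref[:1000] + ref[1200:]
    calls = []
    for qid in ("q1", "q2", "q3"):
        aln = aj.global_align(qry, ref)
        cs = aj.call_indels(aln, aj.Contig("ref", ref), aj.Contig(qid, qry))
        calls.extend(cs)
    markers = aj.match_breakpoints(calls)
    assert len(markers) == 1
    assert markers[0].carriers == {"q1", "q2", "q3"}


def test_equal_length_different_flanks_stay_separate():
    rng = np.random.default_rng(23)
    ref = random_dna(6000, rng)
    q1 = ref[:1000] + ref[1200:]   # deletion at 1000
    q2 = ref[:3000] + ref[3200:]   # same length, different locus
    calls = []
    for qid, q in (("q1", q1), ("q2", q2)):
        aln = aj.global_align(q, ref)
        calls.extend(aj.call_indels(aln, aj.Contig("ref", ref),
                                    aj.Contig(qid, q)))
    markers = aj.match_breakpoints(calls)
    assert len(markers) == 2


def test_match_breakpoints_empty_and_duplicate_carrier():
    assert aj.match_breakpoints([]) == []
    call = aj.IndelCall("ref", "q1", 100, 60, DELETION, "A" * 30, "C" * 30)
    with pytest.raises(ValueError, match="duplicate carrier"):
        aj.match_breakpoints([call, call])


def test_candidate_matches_reports_near_identical_flanks():
    m1 = Marker("a", 100, 60, DELETION, "A" * 30, "C" * 30, {"q1"})
    m2 = Marker("b", 500, 60, DELETION, "A" * 29 + "G", "C" * 30, {"q2"})
    m3 = Marker("c", 900, 61, DELETION, "A" * 29 + "G", "C" * 30, {"q3"})
    assert candidate_matches([m1, m2, m3]) == [("a", "b")]


# ---------------------------------------------------------------------------
# four-gamete and exchange intervals

FIG2D_CHROMS = ["A9-13", "A9-14", "A9-15", "A9-21", "A9-22", "WAV17", "GM10063"]


def printed_markers():
    """The three deletion markers at their printed positions and carriers."""
    return [
        Marker("d1.5", 110_000, 1500, DELETION, "L1", "R1",
               {"A9-13", "A9-15", "GM10063"}),
        Marker("d0.3", 161_000, 300, DELETION, "L2", "R2",
               {"A9-22", "WAV17", "GM10063"}),
        Marker("d5.0", 172_000, 5000, DELETION, "L3", "R3",
               {"A9-22", "WAV17", "GM10063"}),
    ]


def test_four_gamete_on_printed_carrier_sets():
    markers = printed_markers()
    M = aj.marker_matrix_from_carriers(markers, FIG2D_CHROMS)
    assert aj.four_gamete("d1.5", "d0.3", M) is True
    assert aj.four_gamete("d0.3", "d5.0", M) is False
    assert aj.four_gamete("d1.5", "d1.5", M) is False


def test_four_gamete_untestable_pair():
    M = pd.DataFrame({"c1": [1.0, np.nan], "c2": [0.0, np.nan]},
                     index=["m1", "m2"])
    with pytest.raises(ValueError, match="untestable"):
        aj.four_gamete("m1", "m2", M)


def test_four_gamete_symmetry_exhaustive_small():
    chroms = [f"c{i}" for i in range(5)]
    pats = list(itertools.product([0.0, 1.0], repeat=5))
    M = pd.DataFrame({c: [p[i] for p in pats] for i, c in enumerate(chroms)},
                     index=[f"m{j}" for j in range(len(pats))])
    rng = np.random.default_rng(24)
    for _ in range(200):
        i, j = rng.integers(0, len(pats), 2)
        assert aj.four_gamete(f"m{i}", f"m{j}", M) == \
            aj.four_gamete(f"m{j}", f"m{i}", M)


def test_exchange_intervals_printed_pattern():
    markers = printed_markers()
    M = aj.marker_matrix_from_carriers(markers, FIG2D_CHROMS)
    ivs = aj.exchange_intervals(markers, M)
    assert [iv.status for iv in ivs] == ["exchange_required", "linked"]
    assert ivs[0].width == 51_000
    assert ivs[1].width == 11_000
    # the adjoining 11-kb homogeneous block exceeds the NCO tract limit
    assert ivs[0].mechanism_class == "CO"
    assert aj.minimum_exchanges(ivs) == 1


def test_zero_matrix_all_linked():
    markers = [Marker(f"m{i}", i * 1000, 100, DELETION, f"L{i}", f"R{i}", set())
               for i in range(4)]
    M = aj.marker_matrix_from_carriers(markers, FIG2D_CHROMS)
    ivs = aj.exchange_intervals(markers, M)
    assert all(iv.status == "linked" for iv in ivs)
    assert aj.minimum_exchanges(ivs) == 0


def test_classify_mechanism_boundary():
    assert aj.classify_mechanism(112_000) == "CO"
    assert aj.classify_mechanism(1000) == "NCO_possible"
    assert aj.classify_mechanism(999) == "NCO_possible"


def test_minimum_exchanges_lower_bound_over_many_random_cohorts():
    """The greedy minimum never exceeds the number of planted crossovers
    (ground-truth marker matrices from 60 random cohort specs)."""
    from acrodj.simulate import (ArchitectureSpec, CohortSpec, ExchangeEvent,
                                 SharedIndel, build_ancestor, evolve_cohort)

    arch = ArchitectureSpec(rdna_stub_len=500, unique1_len=8000,
                            ir_arm_len=0, ir_spacer_len=0, unique2_len=500,
                            satellite_len=0, tail_len=1000)
    anc, ann = build_ancestor(arch, seed=0)
    rng = np.random.default_rng(25)
    members = [f"m{i}" for i in range(7)]
    for trial in range(60):
        groups = [("g1", members[:2]), ("g2", members[2:4]), ("g3", members[4:])]
        positions = np.sort(rng.choice(np.arange(1000, 8000, 150), size=4,
                                       replace=False))
        indels = [SharedIndel((rng.choice(["g1", "g2", "g3"]),), int(p), 60,
                              "deletion") for p in positions]
        n_x = int(rng.integers(0, 3))
        events = []
        for _ in range(n_x):
            recipient, donor = rng.choice(members, 2, replace=False)
            bp = int(rng.choice(positions[:-1]) + 80)  # between markers
            events.append(ExchangeEvent(recipient, donor, bp))
        spec = CohortSpec(groups=groups, proximal_sub_rate=0.0,
                          distal_sub_rate=0.0, shared_indels=indels,
                          exchange_events=events, seed=trial)
        _, manifest = evolve_cohort(anc, spec, ann)
        truth = manifest.marker_truth()
        markers = [Marker(f"m{i}", r["position"], r["length"], DELETION,
                          f"L{i}", f"R{i}", truth[i])
                   for i, r in enumerate(manifest.shared_indels)]
        M = aj.marker_matrix_from_carriers(markers, members)
        ivs = aj.exchange_intervals(markers, M)
        assert aj.minimum_exchanges(ivs) <= n_x


def test_marker_matrix_on_identical_cohort_is_zero():
    rng = np.random.default_rng(26)
    ref = aj.Contig("ref", random_dna(3000, rng))
    markers = [Marker("m1", 500, 100, DELETION, "L", "R", set())]
    alignments, calls = {}, {}
    for qid in ("q1", "q2"):
        alignments[qid] = aj.global_align(ref.sequence, ref.sequence)
        calls[qid] = []
    M = aj.build_marker_matrix(markers, alignments, calls)
    assert (M.values == 0.0).all()


def test_marker_matrix_matches_simulation_truth(fig2d, fig2d_analysis):
    _, _, _, manifest = fig2d
    markers = fig2d_analysis["markers"]
    matrix = fig2d_analysis["matrix"]
    truth = manifest.marker_truth()
    # markers sorted by position correspond to planted indels in order
    assert len(markers) == len(manifest.shared_indels)
    for i, m in enumerate(markers):
        carriers = set(matrix.columns[matrix.loc[m.marker_id] == 1.0])
        assert carriers == truth[i]
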