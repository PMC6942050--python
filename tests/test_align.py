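"""Pairwise alignment: exactness, identity modes, windows, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import acrodj as aj
from acrodj.align import (DEL, INS, MATCH, MISMATCH, PairwiseAlignment,
                          UnalignableError, _merge_ops)

from conftest import dp_edit_distance, mutate, random_dna

DNA = st.text(alphabet="ACGT", min_size=1, max_size=300)


def _mk(ops, q, t):
    from acrodj.align import _finish
    return _finish("q", "t", q, t, ops, (0, len(q)), (0, len(t)))


def test_identical_sequences_single_match_op():
    aln = aj.global_align("ACGT", "ACGT")
    assert aln.ops == [(MATCH, 4)]
    assert aln.substitutions == 0
    assert aj.identity(aln) == 100.0


def test_single_substitution_identity():
    aln = aj.global_align("ACGTACGT", "ACGAACGT")
    assert aln.substitutions == 1
    assert aj.identity(aln, "substitution_only") == pytest.approx(87.5)


def test_identity_mode_arithmetic():
    # 9 matches, 1 mismatch, 10 indel bases
    q = "A" * 9 + "C" + "G" * 10
    t = "A" * 9 + "T"
    aln = aj.global_align(q, t)
    assert (aln.matches, aln.mismatches, aln.indel_bases) == (9, 1, 10)
    assert aj.identity(aln, "substitution_only") == pytest.approx(90.0)
    assert aj.identity(aln, "blast_like") == pytest.approx(45.0)


def test_identity_error_on_zero_columns():
    aln = PairwiseAlignment("q", "t", [(INS, 5)], (0, 5), (0, 0), 0, 0, 0, 0)
    with pytest.raises(ValueError):
        aj.identity(aln)


def test_n_columns_excluded_from_identity():
    aln = aj.global_align("ACGTNNNN", "ACGTACGT")
    assert aln.n_columns == 4
    assert aln.aligned_columns == 4
    assert aj.identity(aln) == 100.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        aj.global_align("", "ACGT")


@given(DNA, DNA)
def test_edit_distance_matches_dp_oracle(a, b):
    assert aj.global_align(a, b).edit_distance == dp_edit_distance(a, b)


@given(DNA, DNA)
def test_symmetry_of_substitution_and_indel_counts(a, b):
    f = aj.global_align(a, b)
    r = aj.global_align(b, a)
    assert f.substitutions == r.substitutions
    assert f.edit_distance == r.edit_distance
    assert sum(n for k, n in f.ops if k == INS) == \
        sum(n for k, n in r.ops if k == DEL)


def test_ops_merged_and_span_consistent():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a, b = random_dna(500, rng), random_dna(500, rng)
        aln = aj.global_align(a, b)
        for (k1, n1), (k2, n2) in zip(aln.ops, aln.ops[1:]):
            assert k1 != k2 and n1 > 0 and n2 > 0
        q_len = sum(n for k, n in aln.ops if k in (MATCH, MISMATCH, INS))
        t_len = sum(n for k, n in aln.ops if k in (MATCH, MISMATCH, DEL))
        assert q_len == len(a) and t_len == len(b)


def test_merge_ops_collapses_adjacent_runs():
    assert _merge_ops([(MATCH, 2), (MATCH, 3), (INS, 1), (INS, 0), (DEL, 2)]) \
        == [(MATCH, 5), (INS, 1), (DEL, 2)]


def test_anchored_path_recovers_planted_deletion():
    rng = np.random.default_rng(7)
    t = random_dna(40000, rng)
    q = t[:15000] + t[16500:]
    q = mutate(q, 0.005, rng)
    aln = aj.global_align(q, t, direct_area=1_000_000)
    dels = [(k, n) for k, n in aln.ops if k == DEL and n > 100]
    assert dels == [(DEL, 1500)]


def test_unalignable_large_divergent_input():
    rng = np.random.default_rng(11)
    a, b = random_dna(30000, rng), random_dna(30000, rng)
    with pytest.raises(UnalignableError):
        aj.global_align(a, b, direct_area=1_000_000)


def test_window_identity_identical_sequences():
    rng = np.random.default_rng(2)
    ref = aj.Contig("r", random_dna(30000, rng))
    q = aj.Contig("q", ref.sequence)
    prof = aj.window_identity(ref, [q], window_bp=10000)
    assert prof.windows == [(0, 10000), (10000, 20000), (20000, 30000)]
    assert (prof.identities["q"] == 100.0).all()


def test_window_identity_final_window_deficit():
    rng = np.random.default_rng(3)
    ref = aj.Contig("r", random_dna(30000, rng))
    qseq = ref.sequence[:20000] + mutate(ref.sequence[20000:], 0.01, rng)
    planted = sum(a != b for a, b in zip(ref.sequence[20000:], qseq[20000:]))
    prof = aj.window_identity(ref, [aj.Contig("q", qseq)], window_bp=10000)
    vals = prof.identities["q"].tolist()
    assert vals[0] == 100.0 and vals[1] == 100.0
    assert vals[2] == pytest.approx(100.0 * (10000 - planted) / 10000)


def test_window_partial_final_window_rule():
    rng = np.random.default_rng(4)
    ref = aj.Contig("r", random_dna(26000, rng))
    q = aj.Contig("q", ref.sequence)
    prof = aj.window_identity(ref, [q], window_bp=10000)
    # 6-kb remainder >= half a window: kept
    assert prof.windows[-1] == (20000, 26000)
    ref2 = aj.Contig("r2", random_dna(24000, rng))
    prof2 = aj.window_identity(ref2, [aj.Contig("q2", ref2.sequence)],
                               window_bp=10000)
    assert prof2.windows[-1] == (10000, 20000)  # 4-kb remainder dropped


def test_windowed_substitutions_additive_without_indels():
    rng = np.random.default_rng(5)
    ref = aj.Contig("r", random_dna(30000, rng))
    qseq = mutate(ref.sequence, 0.01, rng)
    aln = aj.global_align(qseq, ref.sequence)
    assert aln.indel_events == 0
    prof = aj.window_identity(ref, [aj.Contig("q", qseq)], window_bp=10000)
    per_window_subs = [(1 - v / 100.0) * 10000 for v in prof.identities["q"]]
    assert sum(per_window_subs) == pytest.approx(aln.substitutions, abs=1e-6)


def test_windowed_identity_monotone_in_substitution_rate():
    rng = np.random.default_rng(6)
    lower, higher = [], []
    for _ in range(20):
        ref = random_dna(3000, rng)
        seed = rng.integers(2**31)
        a = mutate(ref, 0.005, np.random.default_rng(seed))
        b = mutate(ref, 0.02, np.random.default_rng(seed))
        lower.append(aj.identity(aj.global_align(a, ref)))
        higher.append(aj.identity(aj.global_align(b, ref)))
    assert np.mean(higher) < np.mean(lower)
    # with shared seeds, every replicate has at least as many substitutions
    assert all(h <= l for h, l in zip(higher, lower))


def test_align_range_full_interval_matches_global():
    rng = np.random.default_rng(8)
    a, b = random_dna(2000, rng), None
    b = mutate(a, 0.01, rng)
    full = aj.global_align(a, b)
    ranged = aj.align_range(a, b, (0, len(a)))
    assert ranged.substitutions == full.substitutions
    assert ranged.query_span == (0, len(a))


def test_align_range_recovers_planted_deletion_in_interval():
    rng = np.random.default_rng(9)
    a = random_dna(30000, rng)
    b = a[:10000] + a[11500:]  # 1.5-kb deletion in b
    aln = aj.align_range(a, b, (5000, 15000))
    dels = [(k, n) for k, n in aln.ops if k == INS]  # extra in query a
    assert (INS, 1500) in aln.ops or dels == [(INS, 1500)]
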