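"""Shared fixtures: the default synthetic cohort and its analysis products.

Session-scoped so the cohort is simulated and aligned once for the whole run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import acrodj as aj

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

BASES = "ACGT"


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def fig2d():
    """Default desk-scale cohort: (ancestor, annotations, cohort, manifest)."""
    return aj.simulate_preset("fig2d")


@pytest.fixture(scope="session")
def fig2d_analysis(fig2d):
    """Reference-based alignments, indel calls and markers for the cohort.

    Indel scanning is a proximal-region analysis (shared indels live in the
    conserved proximal region; the satellite array aligns ambiguously between
    groups), so calls are restricted to reference positions before the
    satellite array.
    """
    ancestor, ann, cohort, manifest = fig2d
    ref = next(c for c in cohort if c.id == manifest.suggested_reference)
    queries = [c for c in cohort if c.id != ref.id]
    alignments = {}
    calls_by_query = {}
    all_calls = []
    for q in queries:
        aln = aj.global_align(q, ref)
        alignments[q.id] = aln
        calls = [c for c in aj.call_indels(aln, ref, q)
                 if c.ref_pos < manifest.distal_start]
        calls_by_query[q.id] = calls
        all_calls.extend(calls)
    markers = aj.match_breakpoints(all_calls)
    matrix = aj.build_marker_matrix(markers, alignments, calls_by_query)
    return {
        "reference": ref,
        "queries": queries,
        "alignments": alignments,
        "calls_by_query": calls_by_query,
        "markers": markers,
        "matrix": matrix,
    }


def dp_edit_distance(a: str, b: str) -> int:
    """Independent full-DP Levenshtein oracle (row-vectorised numpy NW)."""
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    n = len(b)
    idx = np.arange(n + 1, dtype=np.int64)
    prev = idx.copy()
    for i in range(1, len(a) + 1):
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (bb != aa[i - 1]), prev[1:] + 1)
        # left-to-right horizontal relaxation in closed form
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])
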