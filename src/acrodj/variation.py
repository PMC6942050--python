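"""Indel calling, breakpoint matching across chromosomes, and inference of
exchanges between heterologous chromosomes.

Indel calls are left-normalized (shifted leftward while the alignment is
preserved) and carry exact reference flank strings; two calls from different
chromosomes are the *same* marker only when type, length and both flanks agree
exactly — mirroring base-level breakpoint identity.  Near-identical flanks are
reported as candidate matches, never merged silently.

Exchange inference formalizes the shared-marker argument as the classic
four-gamete condition: under an infinite-sites-style assumption (each indel
arose once, no recurrence), a marker pair exhibiting all four joint
presence/absence patterns across the cohort requires at least one exchange in
the intervening interval.  Adjacent markers with identical carrier sets are in
linkage.  Because noncrossover (gene-conversion) tracts are limited to about
1 kb, an exchange flanked by a longer homogeneous shared block is classified
as a crossover (CO); otherwise a noncrossover cannot be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import DEL, INS, MATCH, MISMATCH, PairwiseAlignment
from .io import Contig

DELETION = "deletion_in_query"
INSERTION = "insertion_in_query"

NCO_TRACT_LIMIT_BP = 1000


@dataclass
class IndelCall:
    reference_id: str
    query_id: str
    ref_pos: int  # left-normalized, 0-based on the reference
    length: int
    type: str  # deletion_in_query | insertion_in_query
    left_flank: str
    right_flank: str
    inserted_seq: str = ""  # insertions only


@dataclass
class Marker:
    """An indel shared-breakpoint marker with its carrier chromosomes."""

    marker_id: str
    ref_pos: int
    length: int
    type: str
    left_flank: str
    right_flank: str
    carriers: set = field(default_factory=set)

    @property
    def signature(self) -> tuple:
        return (self.type, self.length, self.left_flank, self.right_flank)


@dataclass
class ExchangeInterval:
    left_marker: str
    right_marker: str
    start: int
    end: int
    status: str  # exchange_required | linked
    mechanism_class: str | None = None  # CO | NCO_possible (exchange only)

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# calling and normalization


def left_normalize(ref: str, pos: int, length: int, kind: str,
                   inserted: str = "") -> tuple[int, str]:
    """Shift an indel leftward while the alignment it came from is preserved.

    For a deletion of ref[pos:pos+length], a left shift by one is valid iff
    ref[pos-1] == ref[pos+length-1]; for an insertion the inserted string is
    rotated.  Idempotent.  Returns (new_pos, inserted_seq).
    """
    if kind == DELETION:
        while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
            pos -= 1
        return pos, ""
    seq = inserted
    while pos > 0 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def call_indels(aln: PairwiseAlignment, reference: "Contig | str",
                query: "Contig | str", min_len: int = 50,
                flank: int = 30) -> list[IndelCall]:
    """Indel calls >= min_len from an alignment, left-normalized, with
    reference flank strings extracted after normalization.

    ``reference`` is the alignment's target, ``query`` its query.
    """
    ref = reference.sequence if isinstance(reference, Contig) else reference
    qry = query.sequence if isinstance(query, Contig) else query
    ref_id = reference.id if isinstance(reference, Contig) else aln.target_id
    qry_id = query.id if isinstance(query, Contig) else aln.query_id
    calls = []
    qi, ti = aln.query_span[0], aln.target_span[0]
    for kind, n in aln.ops:
        if kind in (MATCH, MISMATCH):
            qi += n
            ti += n
        elif kind == INS:
            if n >= min_len:
                pos, seq = left_normalize(ref, ti, n, INSERTION, qry[qi : qi + n])
                calls.append(IndelCall(
                    ref_id, qry_id, pos, n, INSERTION,
                    ref[max(0, pos - flank) : pos], ref[pos : pos + flank], seq,
                ))
            qi += n
        else:  # DEL: bases present on the reference, absent from the query
            if n >= min_len:
                pos, _ = left_normalize(ref, ti, n, DELETION)
                calls.append(IndelCall(
                    ref_id, qry_id, pos, n, DELETION,
                    ref[max(0, pos - flank) : pos],
                    ref[pos + n : pos + n + flank],
                ))
            ti += n
    return sorted(calls, key=lambda c: c.ref_pos)


def match_breakpoints(calls: Sequence[IndelCall]) -> list[Marker]:
    """Cluster calls into markers: same type, exact length and exact flanks.

    Raises if two calls from one query land in the same marker (duplicate
    carrier: the same chromosome cannot carry one mutation twice).
    """
    refs = {c.reference_id for c in calls}
    if len(refs) > 1:
        raise ValueError(f"calls span multiple references: {sorted(refs)}")
    markers: dict[tuple, Marker] = {}
    for c in sorted(calls, key=lambda c: (c.ref_pos, c.query_id)):
        key = (c.type, c.length, c.left_flank, c.right_flank)
        if key not in markers:
            short = "del" if c.type == DELETION else "ins"
            markers[key] = Marker(f"{short}{c.length}@{c.ref_pos}", c.ref_pos,
                                  c.length, c.type, c.left_flank, c.right_flank)
        m = markers[key]
        if c.query_id in m.carriers:
            raise ValueError(
                f"duplicate carrier {c.query_id} for marker {m.marker_id}"
            )
        m.carriers.add(c.query_id)
    return sorted(markers.values(), key=lambda m: (m.ref_pos, m.marker_id))


def candidate_matches(markers: Sequence[Marker],
                      max_flank_mismatch: int = 2) -> list[tuple[str, str]]:
    """Pairs of distinct markers whose flanks nearly agree (same type and
    length, combined flank Hamming distance <= max_flank_mismatch)."""
    out = []
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            if a.type != b.type or a.length != b.length:
                continue
            if len(a.left_flank) != len(b.left_flank) or \
               len(a.right_flank) != len(b.right_flank):
                continue
            d = sum(x != y for x, y in zip(a.left_flank, b.left_flank))
            d += sum(x != y for x, y in zip(a.right_flank, b.right_flank))
            if 0 < d <= max_flank_mismatch:
                out.append((a.marker_id, b.marker_id))
    return out


# ---------------------------------------------------------------------------
# marker matrix


def _covers(aln: PairwiseAlignment, start: int, end: int) -> bool:
    """Whether the alignment's target span covers [start, end)."""
    return aln.target_span[0] <= start and end <= aln.target_span[1]


def build_marker_matrix(markers: Sequence[Marker],
                        alignments: Mapping[str, PairwiseAlignment],
                        calls_by_query: Mapping[str, Sequence[IndelCall]],
                        ) -> pd.DataFrame:
    """Binary presence matrix (markers x chromosomes).

    1.0 = the query carries the marker; 0.0 = absence verified (the query
    aligns across the marker locus); NaN = locus unalignable in that query.
    The reference itself is not a column; add it explicitly if it is part of
    the cohort being scanned.
    """
    sigs = {m.signature: m.marker_id for m in markers}
    rows = [m.marker_id for m in markers]
    data = {}
    for qid, aln in alignments.items():
        col = {}
        called = {
            sigs[(c.type, c.length, c.left_flank, c.right_flank)]
            for c in calls_by_query.get(qid, [])
            if (c.type, c.length, c.left_flank, c.right_flank) in sigs
        }
        for m in markers:
            if m.marker_id in called:
                col[m.marker_id] = 1.0
            elif _covers(aln, m.ref_pos, m.ref_pos + (m.length if m.type == DELETION else 0)):
                col[m.marker_id] = 0.0
            else:
                col[m.marker_id] = np.nan
        data[qid] = col
    return pd.DataFrame(data, index=rows)


def marker_matrix_from_carriers(markers: Sequence[Marker],
                                chromosomes: Sequence[str]) -> pd.DataFrame:
    """Presence matrix directly from each marker's carrier set (no missing
    data) — e.g. when carriers are taken from a published figure."""
    data = {
        chrom: {m.marker_id: 1.0 if chrom in m.carriers else 0.0 for m in markers}
        for chrom in chromosomes
    }
    return pd.DataFrame(data, index=[m.marker_id for m in markers])


# ---------------------------------------------------------------------------
# four-gamete test and exchange intervals


def four_gamete(mi: str, mj: str, matrix: pd.DataFrame) -> bool:
    """True iff all four joint patterns (0,0),(0,1),(1,0),(1,1) occur among
    chromosomes non-missing at both markers — requiring at least one exchange
    between the two marker loci under a single-origin assumption."""
    a = matrix.loc[mi]
    b = matrix.loc[mj]
    ok = a.notna() & b.notna()
    if not ok.any():
        raise ValueError(f"untestable pair ({mi}, {mj}): no shared non-missing data")
    pairs = set(zip(a[ok].astype(int), b[ok].astype(int)))
    return len(pairs) == 4


def classify_mechanism(shared_block_len: int) -> str:
    """CO iff the homogeneous shared block adjoining an exchange exceeds the
    ~1-kb noncrossover tract-length limit."""
    if shared_block_len < 0:
        raise ValueError("block length must be >= 0")
    return "CO" if shared_block_len > NCO_TRACT_LIMIT_BP else "NCO_possible"


def exchange_intervals(markers: Sequence[Marker], matrix: pd.DataFrame,
                       default_shared_block: int = 0) -> list[ExchangeInterval]:
    """Classify every adjacent marker interval as exchange_required or linked.

    For exchange intervals, the adjoining homogeneous shared block is taken as
    the longest run of linked intervals immediately to either side (or
    ``default_shared_block`` when the exchange has no linked neighbour), and
    the mechanism class follows :func:`classify_mechanism`.
    """
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    ms = sorted(markers, key=lambda m: m.ref_pos)
    required = [four_gamete(a.marker_id, b.marker_id, matrix)
                for a, b in zip(ms, ms[1:])]
    intervals = []
    for i, (a, b) in enumerate(zip(ms, ms[1:])):
        status = "exchange_required" if required[i] else "linked"
        mech = None
        if required[i]:
            left = 0
            j = i - 1
            while j >= 0 and not required[j]:
                left += ms[j + 1].ref_pos - ms[j].ref_pos
                j -= 1
            right = 0
            j = i + 1
            while j < len(required) and not required[j]:
                right += ms[j + 1].ref_pos - ms[j].ref_pos
                j += 1
            shared = max(left, right, default_shared_block)
            mech = classify_mechanism(shared)
        intervals.append(ExchangeInterval(a.marker_id, b.marker_id,
                                          a.ref_pos, b.ref_pos, status, mech))
    return intervals


def minimum_exchanges(intervals: Sequence[ExchangeInterval]) -> int:
    """Lower bound on the number of exchanges: the size of a minimal disjoint
    subset of exchange-required intervals (greedy left-to-right scan)."""
    req = sorted((iv for iv in intervals if iv.status == "exchange_required"),
                 key=lambda iv: iv.end)
    count = 0
    last_end = -1
    for iv in req:
        if iv.start >= last_end:
            count += 1
            last_end = iv.end
    return count
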