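"""Pairwise long-sequence alignment and percent-identity statistics.

Alignments are unit-cost (Levenshtein) edit-distance alignments.  Small inputs
are aligned directly with exact bit-parallel DP (edlib); large inputs use
maximal unique shared k-mer anchors, collinear chaining, and exact DP between
consecutive anchors.  Identity has two modes:

* ``substitution_only`` (default): 100 * match / (match + mismatch).  This is
  the convention under which "53 nucleotide differences" over a 112-kb terminus
  corresponds to 99.95% identity — indel columns are not counted.
* ``blast_like``: indel bases enter the denominator.

Columns opposite an N are excluded from both numerator and denominator in both
modes (N marks gap-filled reference bases, not observed variation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import Contig

MATCH = "match"
MISMATCH = "mismatch"
INS = "insertion_in_query"
DEL = "deletion_in_query"

DEFAULT_ANCHOR_K = 21
# direct exact unit-cost DP below this query*target product (2 kb x 2 kb);
# larger inputs are anchored and gap-filled with affine-gap DP so that long
# indels stay contiguous (see _gap_ops)
DEFAULT_DIRECT_AREA = 4_000_000
# inter-anchor gaps up to this cell area use affine-gap DP (see _affine_ops)
AFFINE_GAP_AREA = 64_000_000
# anchorless pairs up to this area fall back to exact DP instead of failing
UNANCHORED_FALLBACK_AREA = 256_000_000


class UnalignableError(ValueError):
    """No anchor chain could be found between two large, divergent sequences.

    Raised instead of returning a (meaningless) low-identity alignment, so a
    failed localisation is distinguishable from a low-identity success.
    """


def _seq_of(x: "Contig | str") -> str:
    return x.sequence if isinstance(x, Contig) else x.upper()


def _id_of(x: "Contig | str", default: str) -> str:
    return x.id if isinstance(x, Contig) else default


@dataclass
class PairwiseAlignment:
    """An operation-list alignment between a query and a target sequence.

    ``ops`` is a run-length list of (kind, length) with kinds match / mismatch /
    insertion_in_query / deletion_in_query; adjacent ops of the same kind are
    merged and all lengths are positive.  ``matches`` and ``mismatches`` count
    only columns where neither base is N; ``n_columns`` counts the excluded
    columns (which still appear structurally inside match/mismatch ops).
    """

    query_id: str
    target_id: str
    ops: list[tuple[str, int]]
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    matches: int
    mismatches: int
    n_columns: int
    struct_mismatches: int  # mismatch columns including those opposite N

    @property
    def substitutions(self) -> int:
        return self.mismatches

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def indel_events(self) -> int:
        return sum(1 for kind, _ in self.ops if kind in (INS, DEL))

    @property
    def indel_bases(self) -> int:
        return sum(n for kind, n in self.ops if kind in (INS, DEL))

    @property
    def edit_distance(self) -> int:
        return self.struct_mismatches + self.indel_bases

    def transposed(self) -> "PairwiseAlignment":
        """The same alignment viewed with query and target swapped."""
        swap = {MATCH: MATCH, MISMATCH: MISMATCH, INS: DEL, DEL: INS}
        return PairwiseAlignment(
            query_id=self.target_id,
            target_id=self.query_id,
            ops=[(swap[k], n) for k, n in self.ops],
            query_span=self.target_span,
            target_span=self.query_span,
            matches=self.matches,
            mismatches=self.mismatches,
            n_columns=self.n_columns,
            struct_mismatches=self.struct_mismatches,
        )


def _merge_ops(ops: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for kind, n in ops:
        if n <= 0:
            continue
        if merged and merged[-1][0] == kind:
            merged[-1] = (kind, merged[-1][1] + n)
        else:
            merged.append((kind, n))
    return merged


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _edlib_ops(q: str, t: str) -> list[tuple[str, int]]:
    """Exact global (NW) alignment ops of q vs t via edlib."""
    if not q and not t:
        return []
    if not q:
        return [(DEL, len(t))]
    if not t:
        return [(INS, len(q))]
    res = edlib.align(q, t, task="path", mode="NW")
    kinds = {"=": MATCH, "X": MISMATCH, "I": INS, "D": DEL}
    return [(kinds[c], n) for c, n in _cigar_ops(res["cigar"])]


def _count_columns(q: str, t: str, ops: Sequence[tuple[str, int]],
                   q0: int = 0, t0: int = 0) -> tuple[int, int, int, int]:
    """Walk ops over the sequences and classify aligned columns.

    Returns (matches, mismatches, n_columns, struct_mismatches) with N-columns
    excluded from matches/mismatches.
    """
    qi, ti = q0, t0
    matches = mismatches = n_cols = struct_mm = 0
    for kind, n in ops:
        if kind == MATCH:
            seg = q[qi : qi + n]
            n_in_seg = seg.count("N")
            matches += n - n_in_seg
            n_cols += n_in_seg
            qi += n
            ti += n
        elif kind == MISMATCH:
            qs = q[qi : qi + n]
            ts = t[ti : ti + n]
            n_in_seg = sum(1 for a, b in zip(qs, ts) if a == "N" or b == "N")
            mismatches += n - n_in_seg
            n_cols += n_in_seg
            struct_mm += n
            qi += n
            ti += n
        elif kind == INS:
            qi += n
        else:
            ti += n
    return matches, mismatches, n_cols, struct_mm


def _finish(qid: str, tid: str, q: str, t: str, ops: list[tuple[str, int]],
            q_span: tuple[int, int], t_span: tuple[int, int]) -> PairwiseAlignment:
    ops = _merge_ops(ops)
    m, mm, ncol, smm = _count_columns(q, t, ops, q_span[0], t_span[0])
    return PairwiseAlignment(qid, tid, ops, q_span, t_span, m, mm, ncol, smm)


# affine-gap (Gotoh) alignment for inter-anchor gap fill.
#
# A strictly parsimonious unit-cost path scatters a long indel through
# coincidental matches whenever a substitution falls near its breakpoint, which
# destroys breakpoint identity between carriers of the same event.  Gap fill
# between anchors therefore uses a light affine penalty (open 3, extend 2,
# mismatch 2 in doubled units) that keeps near-unit-cost behaviour while
# preferring one contiguous gap over several fragments.

_MISMATCH_COST = 2
_GAP_OPEN = 3
_GAP_EXTEND = 2


def _affine_ops(q: str, t: str) -> list[tuple[str, int]]:
    """Global affine-gap alignment ops (Gotoh, minimising cost)."""
    m, n = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    INF = np.iinfo(np.int32).max // 4
    # M: match/mismatch state; X: gap in query (deletion, consumes target);
    # Y: gap in target (insertion, consumes query)
    M = np.full(n + 1, INF, dtype=np.int32)
    X = np.full(n + 1, INF, dtype=np.int32)
    Y = np.full(n + 1, INF, dtype=np.int32)
    M[0] = 0
    X[1:] = _GAP_OPEN + _GAP_EXTEND * np.arange(1, n + 1)
    tb_m = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0=M,1=X,2=Y predecessor
    tb_x = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0=extend,1=open from M
    tb_y = np.zeros((m + 1, n + 1), dtype=np.uint8)
    if n >= 1:
        tb_x[0, 1] = 1
    for i in range(1, m + 1):
        subst = np.where(ta != qa[i - 1], _MISMATCH_COST, 0).astype(np.int32)
        prevM, prevX, prevY = M.copy(), X.copy(), Y.copy()
        # Y: gap in target, moves down a row
        openY = prevM + _GAP_OPEN + _GAP_EXTEND
        extY = prevY + _GAP_EXTEND
        Y = np.where(extY <= openY, extY, openY)
        tb_y[i] = (extY > openY).astype(np.uint8)
        Y[0] = _GAP_OPEN + _GAP_EXTEND * i
        tb_y[i, 0] = 0 if i > 1 else 1
        # M: diagonal from any state
        diagM = prevM[:-1] + subst
        diagX = prevX[:-1] + subst
        diagY = prevY[:-1] + subst
        Mnew = np.full(n + 1, INF, dtype=np.int32)
        best = diagM
        src = np.zeros(n, dtype=np.uint8)
        better = diagX < best
        best = np.where(better, diagX, best)
        src = np.where(better, 1, src)
        better = diagY < best
        best = np.where(better, diagY, best)
        src = np.where(better, 2, src)
        Mnew[1:] = best
        tb_m[i, 1:] = src
        M = Mnew
        # X: gap in query, moves right along the row.  X[j] = min over j' < j
        # of M[j'] + open + extend*(j-j'); vectorised via a running minimum of
        # M[j'] - extend*j'.
        X = np.full(n + 1, INF, dtype=np.int32)
        if n >= 1:
            idx = np.arange(n, dtype=np.int32)
            run_min = np.minimum.accumulate(M[:-1] - _GAP_EXTEND * idx)
            X[1:] = run_min + _GAP_OPEN + _GAP_EXTEND * (idx + 1)
            # extend whenever continuing the previous X cell ties or wins
            tb_x[i, 1:] = np.where(X[1:] == X[:-1] + _GAP_EXTEND, 0, 1)
            tb_x[i, 1] = 1
    # traceback from the cheapest terminal state
    i, j = m, n
    state = int(np.argmin([M[n], X[n], Y[n]]))
    ops_rev: list[tuple[str, int]] = []

    def push(kind: str) -> None:
        if ops_rev and ops_rev[-1][0] == kind:
            ops_rev[-1] = (kind, ops_rev[-1][1] + 1)
        else:
            ops_rev.append((kind, 1))

    while i > 0 or j > 0:
        if state == 0:  # M at (i, j): diagonal step
            push(MATCH if q[i - 1] == t[j - 1] else MISMATCH)
            state = int(tb_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:  # X at (i, j): gap in query, consumed t[j-1]
            push(DEL)
            state = 0 if tb_x[i, j] == 1 else 1
            j -= 1
        else:  # Y at (i, j): gap in target, consumed q[i-1]
            push(INS)
            state = 0 if tb_y[i, j] == 1 else 2
            i -= 1
    return ops_rev[::-1]


def _gap_ops(q: str, t: str) -> list[tuple[str, int]]:
    """Inter-anchor gap fill: affine DP for moderate areas, exact unit-cost
    DP for very large (typically satellite) gaps."""
    if len(q) * len(t) <= AFFINE_GAP_AREA:
        return _affine_ops(q, t)
    return _edlib_ops(q, t)


# ---------------------------------------------------------------------------
# anchoring and chaining


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """k-mer -> position for k-mers occurring exactly once (N-free)."""
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in pos:
            del pos[kmer]
            dup.add(kmer)
        else:
            pos[kmer] = i
    return {km: p for km, p in pos.items() if "N" not in km}


def _anchor_segments(q: str, t: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact-match segments (q_start, t_start, length) from k-mers
    unique in both sequences, merged along diagonals."""
    qk = _unique_kmers(q, k)
    tk = _unique_kmers(t, k)
    matches = sorted(
        ((qp, tk[km]) for km, qp in qk.items() if km in tk),
        key=lambda m: (m[0] - m[1], m[0]),
    )
    segments: list[tuple[int, int, int]] = []
    for qp, tp in matches:
        if segments:
            sq, st, sl = segments[-1]
            if qp - tp == sq - st and qp <= sq + sl:
                # overlapping/abutting k-mers on one diagonal: exact extension
                segments[-1] = (sq, st, qp + k - sq)
                continue
        segments.append((qp, tp, k))
    return segments


def _chain(segments: list[tuple[int, int, int]],
           max_segments: int = 5000) -> list[tuple[int, int, int]]:
    """Collinear chain maximising total anchored length; leftmost tie-break.

    Chance extension of anchors can make neighbouring segments overlap by a
    few bases; such segments are still chainable, scored net of the overlap,
    and the overlap is trimmed off the later segment on emission.
    """
    if not segments:
        return []
    if len(segments) > max_segments:
        segments = sorted(segments, key=lambda s: -s[2])[:max_segments]
    segments = sorted(segments, key=lambda s: (s[0], s[1]))
    n = len(segments)
    score = [0] * n
    back = [-1] * n
    for i, (qi, ti, li) in enumerate(segments):
        score[i] = li
        for j in range(i):
            qj, tj, lj = segments[j]
            ov = max(qj + lj - qi, tj + lj - ti, 0)
            if ov < li and qj <= qi and tj <= ti and \
                    score[j] + li - ov > score[i]:
                score[i] = score[j] + li - ov
                back[i] = j
    best = max(range(n), key=lambda i: (score[i], -i))
    raw = []
    while best != -1:
        raw.append(segments[best])
        best = back[best]
    raw.reverse()
    chain: list[tuple[int, int, int]] = []
    for qs, ts, length in raw:
        if chain:
            pq, pt, pl = chain[-1]
            ov = max(pq + pl - qs, pt + pl - ts, 0)
            qs, ts, length = qs + ov, ts + ov, length - ov
        chain.append((qs, ts, length))
    return chain


def _align_core(q: str, t: str, k: int, direct_area: int) -> list[tuple[str, int]]:
    if len(q) == 0 or len(t) == 0:
        return _edlib_ops(q, t)
    if len(q) * len(t) <= direct_area:
        return _edlib_ops(q, t)
    chain = _chain(_anchor_segments(q, t, k))
    if not chain:
        # no shared unique k-mers: fall back to exact DP while the problem
        # still fits in memory, otherwise the pair is unalignable
        if len(q) * len(t) <= UNANCHORED_FALLBACK_AREA:
            return _edlib_ops(q, t)
        raise UnalignableError(
            f"no unique {k}-mer anchors shared by sequences of length "
            f"{len(q)} and {len(t)}"
        )
    ops: list[tuple[str, int]] = []
    qprev = tprev = 0
    for qs, ts, length in chain:
        ops.extend(_gap_ops(q[qprev:qs], t[tprev:ts]))
        ops.append((MATCH, length))
        qprev, tprev = qs + length, ts + length
    ops.extend(_gap_ops(q[qprev:], t[tprev:]))
    return ops


def global_align(a: "Contig | str", b: "Contig | str", *, k: int = DEFAULT_ANCHOR_K,
                 direct_area: int = DEFAULT_DIRECT_AREA) -> PairwiseAlignment:
    """Globally align a (query) against b (target), minimising edit distance.

    The alignment is computed in a canonical orientation and transposed if
    needed, so substitution/indel counts are symmetric in the two inputs.
    """
    q, t = _seq_of(a), _seq_of(b)
    qid, tid = _id_of(a, "query"), _id_of(b, "target")
    if not q or not t:
        raise ValueError("cannot align empty sequence")
    if (len(q), q) <= (len(t), t):
        ops = _align_core(q, t, k, direct_area)
        return _finish(qid, tid, q, t, ops, (0, len(q)), (0, len(t)))
    ops = _align_core(t, q, k, direct_area)
    aln = _finish(tid, qid, t, q, ops, (0, len(t)), (0, len(q)))
    return aln.transposed()


def identity(aln: PairwiseAlignment, mode: str = "substitution_only") -> float:
    """Percent identity of an alignment under the given mode."""
    if aln.aligned_columns == 0:
        raise ValueError("alignment has zero aligned columns")
    if mode == "substitution_only":
        return 100.0 * aln.matches / aln.aligned_columns
    if mode == "blast_like":
        return 100.0 * aln.matches / (aln.aligned_columns + aln.indel_bases)
    raise ValueError(f"unknown identity mode {mode!r}")


# ---------------------------------------------------------------------------
# coordinate projection and ranges


def _project(aln: PairwiseAlignment, query_pos: int) -> int:
    """Target position aligned at (or immediately after) a query position."""
    qi, ti = aln.query_span[0], aln.target_span[0]
    for kind, n in aln.ops:
        if kind in (MATCH, MISMATCH):
            if qi + n > query_pos:
                return ti + (query_pos - qi)
            qi += n
            ti += n
        elif kind == INS:
            if qi + n > query_pos:
                return ti
            qi += n
        else:
            ti += n
    return ti


def align_range(a: "Contig | str", b: "Contig | str",
                a_interval: tuple[int, int], *, k: int = DEFAULT_ANCHOR_K,
                direct_area: int = DEFAULT_DIRECT_AREA) -> PairwiseAlignment:
    """Alignment restricted to a query interval and its located partner on b.

    The partner interval is located by projecting the interval ends through a
    full anchored alignment, then the two subsequences are re-aligned.
    """
    q, t = _seq_of(a), _seq_of(b)
    qid, tid = _id_of(a, "query"), _id_of(b, "target")
    s, e = a_interval
    if not (0 <= s < e <= len(q)):
        raise ValueError(f"interval [{s}, {e}) outside query of length {len(q)}")
    full = global_align(q, t, k=k, direct_area=direct_area)
    ts = _project(full, s)
    te = _project(full, e - 1) + 1
    if te <= ts:
        raise UnalignableError(
            f"query interval [{s}, {e}) of {qid} has no alignable partner on {tid}"
        )
    ops = _align_core(q[s:e], t[ts:te], k, direct_area)
    return _finish(qid, tid, q, t, ops, (s, e), (ts, te))


# ---------------------------------------------------------------------------
# windowed identity profiles


@dataclass
class IdentityProfile:
    """Per-window percent identity of queries against a reference contig."""

    reference_id: str
    windows: list[tuple[int, int]]
    identities: pd.DataFrame  # rows: windows, columns: query ids, NaN = missing

    @property
    def mean_identity(self) -> pd.Series:
        return self.identities.mean(axis=1, skipna=True)

    def to_frame(self) -> pd.DataFrame:
        df = self.identities.copy()
        df.insert(0, "start", [w[0] for w in self.windows])
        df.insert(1, "end", [w[1] for w in self.windows])
        df["mean"] = self.mean_identity.values
        return df


def _window_bounds(length: int, window: int, step: int) -> list[tuple[int, int]]:
    bounds = []
    for s in range(0, length, step):
        e = min(s + window, length)
        if e - s >= window / 2:
            bounds.append((s, e))
        if e == length:
            break
    return bounds


def window_identity(reference: Contig, queries: Sequence[Contig],
                    window_bp: int = 100_000, step_bp: int | None = None,
                    mode: str = "substitution_only") -> IdentityProfile:
    """Tile the reference with windows and report per-query identity in each.

    Each query is aligned to the reference once; window identities are read
    off the alignment columns falling inside each reference window.  A final
    partial window is kept when it is at least half a window wide.  Windows in
    which a query has no aligned columns are recorded as missing (NaN).
    """
    step = step_bp or window_bp
    L = reference.length
    if L < window_bp:
        raise ValueError("reference shorter than one window")
    windows = _window_bounds(L, window_bp, step)
    cols = {}
    for query in queries:
        aln = global_align(query, reference)
        is_aln = np.zeros(L, dtype=bool)   # non-N aligned columns
        is_match = np.zeros(L, dtype=bool)
        is_indel = np.zeros(L, dtype=bool)
        q, t = _seq_of(query), reference.sequence
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        tarr = np.frombuffer(t.encode(), dtype=np.uint8)
        n_code = ord("N")
        qi, ti = 0, 0
        for kind, n in aln.ops:
            if kind in (MATCH, MISMATCH):
                qs = qarr[qi : qi + n]
                ts = tarr[ti : ti + n]
                non_n = (qs != n_code) & (ts != n_code)
                is_aln[ti : ti + n] = non_n
                is_match[ti : ti + n] = non_n & (qs == ts)
                qi += n
                ti += n
            elif kind == INS:
                qi += n
            else:
                is_indel[ti : ti + n] = True
                ti += n
        vals = []
        for s, e in windows:
            m = int(is_match[s:e].sum())
            al = int(is_aln[s:e].sum())
            if al == 0:
                vals.append(np.nan)
            elif mode == "substitution_only":
                vals.append(100.0 * m / al)
            else:
                vals.append(100.0 * m / (al + int(is_indel[s:e].sum())))
        cols[query.id] = vals
    df = pd.DataFrame(cols, index=[f"{s}-{e}" for s, e in windows])
    return IdentityProfile(reference.id, windows, df)
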