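"""rDNA/DJ junction location and far-distal homology-block mapping.

The junction is defined operationally as the end of the maximal >=99%-identity
terminal match between a contig end and an rDNA reference segment; its
position on the reference (``rdna_offset``) is reported relative to the
supplied reference rather than hard-coded, since rDNA coordinate systems
differ between references.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .align import UnalignableError, global_align, identity
from .io import Contig
from .repeats import _revcomp


@dataclass
class JunctionCall:
    contig_id: str
    junction_pos: int       # first contig position beyond the rDNA match
    rdna_prefix_len: int
    flank: str              # 2j bp centred on the junction
    rdna_offset: int        # junction position on the rDNA reference
    orientation: str = "forward"  # forward: rDNA stub at the contig start


@dataclass
class HomologyBlock:
    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]  # forward target coordinates on both strands
    identity: float
    strand: str  # forward | reverse


# ---------------------------------------------------------------------------
# junction


def _prefix_identity(prefix: str, rdna: str) -> tuple[float, int]:
    """Best infix identity of a contig prefix inside the rDNA reference, and
    the end position of that match on the reference."""
    res = edlib.align(prefix, rdna, mode="HW", task="locations")
    dist = res["editDistance"]
    end = res["locations"][0][1] + 1 if res["locations"] else 0
    return 100.0 * (len(prefix) - dist) / len(prefix), end


_WALK_MATCH = 1
_WALK_PENALTY = 3  # per mismatch base
_JUNCTION_K = 21


def _find_prefix_junction(seq: str, rdna: str, min_seed: int,
                          min_identity: float) -> tuple[int, int] | None:
    """Locate the end of the maximal near-exact terminal rDNA match.

    Edit-optimal infix alignment cannot pin the junction: with trailing
    non-rDNA sequence in the window, co-optimal paths smear stub-tail matches
    into the junk.  Instead, unique shared k-mers anchor the rDNA match; the
    rightmost anchor fixes the local diagonal (a chance k-mer match beyond
    the junction is vanishingly unlikely), and a direct base-comparison score
    walk along that diagonal (+1 match, -3 mismatch) peaks at the junction.
    The call is accepted when the matched prefix is at least ``min_seed`` bp
    with overall identity >= ``min_identity``.  Returns (junction position on
    the contig, match end on the reference).
    """
    from .align import _unique_kmers

    cap = min(len(seq), len(rdna))
    if cap < min_seed:
        return None
    qk = _unique_kmers(seq[:cap], _JUNCTION_K)
    tk = _unique_kmers(rdna, _JUNCTION_K)
    matches = [(qp, tk[km]) for km, qp in qk.items() if km in tk]
    if not matches:
        return None
    q_anchor, t_anchor = max(matches)
    # walk the anchor's diagonal forward; the score peak is the junction
    score = best = 0
    best_off = 0
    span = min(len(seq) - q_anchor, len(rdna) - t_anchor)
    for off in range(span):
        if seq[q_anchor + off] == rdna[t_anchor + off]:
            score += _WALK_MATCH
            if score > best:
                best = score
                best_off = off + 1
        else:
            score -= _WALK_PENALTY
    if best_off == 0:
        return None
    q_end, t_end = q_anchor + best_off, t_anchor + best_off
    if q_end < min_seed:
        return None
    ident, _ = _prefix_identity(seq[:q_end], rdna)
    if ident < min_identity:
        return None
    return q_end, t_end


def find_junction(contig: Contig, rdna_ref: Contig, min_seed: int = 200,
                  min_identity: float = 99.0, flank_half: int = 100,
                  try_both_orientations: bool = True) -> JunctionCall | None:
    """Locate the rDNA/DJ junction at a contig end, or None if no terminal
    rDNA match of at least ``min_seed`` bp is found (a "no junction" result,
    distinct from an error — expected for purely far-distal sequence)."""
    seq = contig.sequence
    hit = _find_prefix_junction(seq, rdna_ref.sequence, min_seed, min_identity)
    if hit is not None:
        pos, rdna_end = hit
        return JunctionCall(
            contig.id, pos, pos,
            seq[max(0, pos - flank_half) : pos + flank_half],
            rdna_end, "forward",
        )
    if try_both_orientations:
        rc = _revcomp(seq)
        hit = _find_prefix_junction(rc, rdna_ref.sequence, min_seed, min_identity)
        if hit is not None:
            pos, rdna_end = hit
            mirrored = len(seq) - pos
            return JunctionCall(
                contig.id, mirrored, pos,
                rc[max(0, pos - flank_half) : pos + flank_half],
                rdna_end, "reverse",
            )
    return None


def compare_junction_flanks(calls: list[JunctionCall]
                            ) -> tuple[bool, list[tuple[int, dict[str, str]]]]:
    """Whether all junction flank strings are identical; if not, a report of
    differing flank positions with the per-contig base at each."""
    if not calls:
        raise ValueError("no junction calls to compare")
    flanks = [c.flank for c in calls]
    if len(set(flanks)) <= 1:
        return True, []
    width = min(len(f) for f in flanks)
    report = []
    for i in range(width):
        bases = {c.contig_id: c.flank[i] for c in calls}
        if len(set(bases.values())) > 1:
            report.append((i, bases))
    if not report and len(set(len(f) for f in flanks)) > 1:
        report.append((width, {c.contig_id: c.flank[width:] or "-" for c in calls}))
    return False, report


# ---------------------------------------------------------------------------
# homology blocks


def _unique_kmer_index(seq: str, k: int) -> dict[str, int]:
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


def _stranded_blocks(q: str, t: str, k: int, min_block: int, max_gap: int,
                     diag_tol: int) -> list[tuple[int, int, int, int]]:
    """Collinear anchor clusters (q_start, q_end, t_start, t_end)."""
    qk = _unique_kmer_index(q, k)
    tk = _unique_kmer_index(t, k)
    matches = sorted(
        ((qp, tk[km]) for km, qp in qk.items() if km in tk),
        key=lambda m: (m[1] - m[0], m[0]),
    )
    clusters: list[list[int]] = []
    for qp, tp in matches:
        diag = tp - qp
        if clusters:
            q0, q1, t0, t1, d = clusters[-1]
            if abs(diag - d) <= diag_tol and 0 <= qp - (q1 - k) <= max_gap:
                clusters[-1] = [q0, qp + k, t0, tp + k, d]
                continue
        clusters.append([qp, qp + k, tp, tp + k, diag])
    return [(q0, q1, t0, t1) for q0, q1, t0, t1, _ in clusters
            if q1 - q0 >= min_block]


def homology_blocks(query: Contig, target: Contig, min_block: int = 2000,
                    min_identity: float = 85.0, k: int = 21,
                    max_gap: int = 5000, diag_tol: int = 200,
                    ) -> list[HomologyBlock]:
    """High-identity homology blocks between two contigs on both strands.

    Anchors (unique shared k-mers) are clustered by diagonal; each cluster's
    spans are re-aligned for an identity estimate.  Reverse-strand blocks are
    reported with target spans in forward coordinates.  Gaps between
    consecutive collinear blocks on the target are candidate internal
    deletions (see :func:`collinear_target_gaps`).
    """
    out: list[HomologyBlock] = []
    qs, ts = query.sequence, target.sequence
    for strand, t_seq in (("forward", ts), ("reverse", _revcomp(ts))):
        for q0, q1, t0, t1 in _stranded_blocks(qs, t_seq, k, min_block,
                                               max_gap, diag_tol):
            try:
                aln = global_align(qs[q0:q1], t_seq[t0:t1])
                ident = identity(aln)
            except (UnalignableError, ValueError):
                continue
            if ident < min_identity:
                continue
            span = (t0, t1) if strand == "forward" else (len(ts) - t1, len(ts) - t0)
            out.append(HomologyBlock(query.id, target.id, (q0, q1), span,
                                     ident, strand))
    return sorted(out, key=lambda b: b.query_span)


def collinear_target_gaps(blocks: list[HomologyBlock]
                          ) -> list[tuple[HomologyBlock, HomologyBlock, int]]:
    """Candidate internal deletions on the target: for consecutive collinear
    forward blocks, the extra target-side gap beyond the query-side gap."""
    fwd = sorted((b for b in blocks if b.strand == "forward"),
                 key=lambda b: b.query_span)
    gaps = []
    for a, b in zip(fwd, fwd[1:]):
        if b.target_span[0] >= a.target_span[1]:
            gap_t = b.target_span[0] - a.target_span[1]
            gap_q = b.query_span[0] - a.query_span[1]
            if gap_t - gap_q > 0:
                gaps.append((a, b, gap_t - gap_q))
    return gaps
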