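"""Repeat-architecture annotation: tandem satellite arrays, inverted repeats,
and foreign inserts embedded in satellite blocks.

Satellite period estimation uses nearest-downstream identical k-mer distances
(the mode of the distance distribution), which tolerates 1-2% monomer
divergence and yields an integer period directly.  Inverted repeats are found
by anchoring a contig against its own reverse complement after masking
satellite blocks (palindromic monomer content otherwise produces spurious
anti-diagonal anchors); arm identity is computed on the unmasked sequence.
Foreign inserts (e.g. HERV-K-like integrations) are defined structurally, as
non-periodic intervals inside a satellite block's outer span, not by homology
to any retroviral reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import global_align, identity
from .io import Contig

DEFAULT_PERIOD_K = 12
DEFAULT_MAX_PERIOD = 2000


@dataclass
class SatelliteBlock:
    contig_id: str
    start: int
    end: int
    period: int
    monomer_consensus: str
    mean_monomer_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InvertedRepeat:
    contig_id: str
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    arm_identity: float

    @property
    def spacer_len(self) -> int:
        return self.arm2[0] - self.arm1[1]


@dataclass
class ForeignInsert:
    contig_id: str
    start: int
    end: int
    host_block: SatelliteBlock

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# period estimation


def _downstream_distances(seq: str, k: int, max_period: int) -> np.ndarray:
    """Distance from each position to the nearest downstream identical k-mer
    (only distances <= max_period are recorded)."""
    nxt: dict[str, int] = {}
    dists = []
    for i in range(len(seq) - k, -1, -1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        j = nxt.get(kmer)
        if j is not None and j - i <= max_period:
            dists.append(j - i)
        nxt[kmer] = i
    return np.asarray(dists, dtype=np.int64)


def estimate_period(segment: str, k: int = DEFAULT_PERIOD_K,
                    max_period: int = DEFAULT_MAX_PERIOD,
                    min_fraction: float = 0.3, min_count: int = 10,
                    allow_short: bool = False) -> int | None:
    """Monomer period of a tandem array, or None for aperiodic input.

    The period is the mode of nearest-downstream identical k-mer distances,
    accepted when the mode covers at least ``min_fraction`` of all recorded
    distances and at least ``min_count`` of them (a handful of chance k-mer
    recurrences in aperiodic sequence must not look like a period).
    Invariant to circular rotation of a perfect array.
    """
    if isinstance(segment, Contig):
        segment = segment.sequence
    if len(segment) < 3 * max_period and not allow_short:
        raise ValueError(
            f"segment of {len(segment)} bp is shorter than 3 x max_period; "
            "pass allow_short=True to override"
        )
    dists = _downstream_distances(segment, k, max_period)
    if dists.size == 0:
        return None
    counts = np.bincount(dists)
    mode = int(counts.argmax())
    if counts[mode] >= max(min_fraction * dists.size, min_count) and mode >= 2:
        return mode
    return None


def _periodic_mask(seq: str, k: int, max_period: int) -> np.ndarray:
    """True at positions whose k-mer recurs downstream within max_period."""
    mask = np.zeros(len(seq), dtype=bool)
    nxt: dict[str, int] = {}
    for i in range(len(seq) - k, -1, -1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        j = nxt.get(kmer)
        if j is not None and j - i <= max_period:
            mask[i] = True
        nxt[kmer] = i
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _consensus(seq: str, period: int) -> tuple[str, float]:
    """Majority-vote monomer consensus and mean monomer identity."""
    n = len(seq) // period
    if n == 0:
        return seq, 100.0
    arr = np.frombuffer(seq[: n * period].encode(), dtype=np.uint8)
    arr = arr.reshape(n, period)
    cons = np.empty(period, dtype=np.uint8)
    for j in range(period):
        vals, counts = np.unique(arr[:, j], return_counts=True)
        cons[j] = vals[counts.argmax()]
    ident = float((arr == cons).mean() * 100.0)
    return cons.tobytes().decode(), ident


def find_satellite_blocks(contig: Contig, k: int = DEFAULT_PERIOD_K,
                          max_period: int = DEFAULT_MAX_PERIOD,
                          min_block: int = 1000,
                          merge_gap: int = 500) -> list[SatelliteBlock]:
    """Maximal tandemly repetitive blocks with estimated monomer period."""
    seq = contig.sequence
    mask = _periodic_mask(seq, k, max_period)
    runs = _runs(mask)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    blocks = []
    for s, e in merged:
        e = min(e + k, len(seq))  # cover the final k-mer's width
        if e - s < min_block:
            continue
        period = estimate_period(seq[s:e], k=k, max_period=max_period,
                                 allow_short=True)
        if period is None:
            continue
        cons, ident = _consensus(seq[s:e], period)
        blocks.append(SatelliteBlock(contig.id, s, e, period, cons, ident))
    return blocks


# ---------------------------------------------------------------------------
# inverted repeats


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _ir_segments(seq: str, k: int) -> list[tuple[int, int, int, int]]:
    """Anti-diagonal exact segments (a_start, a_end, b_start, b_end) with
    seq[a_start:a_end] == revcomp(seq[b_start:b_end]) and a < b, built from
    k-mers unique in the contig."""
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
    pairs = []
    for kmer, a in pos.items():
        if "N" in kmer:
            continue
        b = pos.get(_revcomp(kmer))
        if b is not None and a < b:
            pairs.append((a, b))
    # merge consecutive pairs on one anti-diagonal (a+1 pairs with b-1)
    pairs.sort(key=lambda p: (p[0] + p[1], p[0]))
    segments: list[list[int]] = []
    for a, b in pairs:
        if segments:
            a0, a1, b0, b1 = segments[-1]
            if a + b + k == a0 + b1 and a <= a1:
                segments[-1] = [a0, a + k, b, b1]
                continue
        segments.append([a, a + k, b, b + k])
    return [tuple(s) for s in segments]  # type: ignore[misc]


def _chain_ir(segments: list[tuple[int, int, int, int]]
              ) -> list[tuple[int, int, int, int]]:
    """Best chain: arm1 coordinates increase, arm2 coordinates decrease."""
    if not segments:
        return []
    segments = sorted(segments)
    n = len(segments)
    score = [0] * n
    back = [-1] * n
    for i, (a0, a1, b0, b1) in enumerate(segments):
        score[i] = a1 - a0
        for j in range(i):
            ja0, ja1, jb0, jb1 = segments[j]
            if ja1 <= a0 and jb0 >= b1 and score[j] + (a1 - a0) > score[i]:
                score[i] = score[j] + (a1 - a0)
                back[i] = j
    best = max(range(n), key=lambda i: (score[i], -i))
    chain = []
    while best != -1:
        chain.append(segments[best])
        best = back[best]
    return chain[::-1]


def find_inverted_repeats(contig: Contig, min_arm: int = 5000, k: int = 21,
                          mask_satellites: bool = True,
                          min_identity: float = 80.0) -> list[InvertedRepeat]:
    """Long inverted repeats via anchors between a contig and its own
    reverse complement, with satellite blocks masked before anchoring."""
    seq = contig.sequence
    if len(seq) < 2 * min_arm:
        return []
    work = seq
    if mask_satellites:
        for b in find_satellite_blocks(contig):
            work = work[: b.start] + "N" * (b.end - b.start) + work[b.end :]
    segments = _ir_segments(work, k)
    repeats: list[InvertedRepeat] = []
    while segments:
        chain = _chain_ir(segments)
        if not chain:
            break
        arm1 = (chain[0][0], chain[-1][1])
        arm2 = (chain[-1][2], chain[0][3])
        if (arm1[1] - arm1[0] < min_arm or arm2[1] - arm2[0] < min_arm
                or arm1[1] > arm2[0]):
            break
        aln = global_align(seq[arm1[0] : arm1[1]],
                           _revcomp(seq[arm2[0] : arm2[1]]))
        ident = identity(aln)
        if ident >= min_identity:
            repeats.append(InvertedRepeat(contig.id, arm1, arm2, ident))
        segments = [s for s in segments
                    if not (arm1[0] <= s[0] < arm1[1] or arm2[0] <= s[2] < arm2[1])]
    return sorted(repeats, key=lambda r: r.arm1)


# ---------------------------------------------------------------------------
# foreign inserts


def find_foreign_inserts(contig: Contig, blocks: list[SatelliteBlock],
                         min_insert: int = 500, max_insert: int = 50000,
                         k: int = DEFAULT_PERIOD_K,
                         max_period: int = DEFAULT_MAX_PERIOD,
                         low_identity: float = 60.0) -> list[ForeignInsert]:
    """Non-periodic intervals embedded in satellite blocks.

    Two signals are used: (a) a gap between two same-period blocks (an insert
    long enough to have split the array during block finding), with the host
    reported as the merged outer block; (b) an aperiodic or low-identity run
    of at least ``min_insert`` bp strictly inside one block.  An insert that is
    itself tandemly repetitive with period <= max_period is not detected.
    """
    seq = contig.sequence
    blocks = sorted(blocks, key=lambda b: b.start)
    inserts: list[ForeignInsert] = []
    for prev, nxt in zip(blocks, blocks[1:]):
        gap = nxt.start - prev.end
        if prev.period == nxt.period and min_insert <= gap <= max_insert:
            host = SatelliteBlock(
                contig.id, prev.start, nxt.end, prev.period,
                prev.monomer_consensus,
                (prev.mean_monomer_identity + nxt.mean_monomer_identity) / 2,
            )
            inserts.append(ForeignInsert(contig.id, prev.end, nxt.start, host))
    for b in blocks:
        sub = seq[b.start : b.end]
        mask = _periodic_mask(sub, k, max_period)
        # low-identity monomers count as foreign even if k-mer-periodic
        n_mono = len(sub) // b.period if b.period else 0
        if n_mono and b.monomer_consensus:
            arr = np.frombuffer(sub[: n_mono * b.period].encode(), dtype=np.uint8)
            cons = np.frombuffer(b.monomer_consensus[: b.period].encode(),
                                 dtype=np.uint8)
            ident = (arr.reshape(n_mono, b.period) == cons).mean(axis=1) * 100
            for m in np.nonzero(ident < low_identity)[0]:
                mask[m * b.period : (m + 1) * b.period] = False
        for s, e in _runs(~mask):
            e = min(e, len(sub))
            if e - s >= min_insert and s > 0 and e < len(sub) - k:
                inserts.append(ForeignInsert(contig.id, b.start + s, b.start + e, b))
    return sorted(inserts, key=lambda i: i.start)
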