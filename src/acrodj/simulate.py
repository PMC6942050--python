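"""Synthetic DJ-cohort generator with full ground truth.

Generates an ancestral DJ-like contig (rDNA stub, unique spacers, a long
inverted repeat, a 48-bp-period satellite array, a distal tail) and evolves a
cohort of related contigs from it: group-shared indels with identical
breakpoints, group-shared foreign inserts inside the satellite array,
substitutions, and optional exchange (crossover) lineages modelled as
single-crossover suffix transfers.

The substitution model mirrors the empirical identity gradient of real DJ
cohorts: a low-divergence proximal region shared by all chromosomes and a
distal tail whose divergence separates the cohort into groups.  Distal
substitutions are therefore drawn once per *group lineage* over the distal
region, while proximal-rate substitutions are drawn independently per member
over the whole contig.  Per-member independent distal noise would erase the
group structure that the grouping stage is meant to recover.

Every realized event is recorded in a :class:`SimManifest`; replaying the
manifest on the ancestor reproduces each member byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AnnotationRecord, Contig
from .rdna import random_dna, rdna_reference

_CODE = {c: i for i, c in enumerate("ACGT")}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MAX_ANCESTOR_LEN = 5_000_000


@dataclass
class ArchitectureSpec:
    """Layout of the ancestral contig, proximal to distal.

    Order: rDNA stub, unique1, IR arm 1, spacer, reverse complement of arm 1,
    unique2, satellite array (tandem copies of one random period-length
    monomer), tail.  The desk-scale defaults give a ~62-kb ancestor so the full
    pipeline runs in seconds; see :func:`preset` for the paper-scale layout.
    """

    rdna_stub_len: int = 4000
    unique1_len: int = 15000
    ir_arm_len: int = 5000
    ir_spacer_len: int = 2000
    unique2_len: int = 14000
    satellite_period: int = 48
    satellite_len: int = 5040
    tail_len: int = 12000

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.satellite_period < 2:
            raise ValueError("satellite_period must be >= 2")

    @property
    def total_len(self) -> int:
        return (self.rdna_stub_len + self.unique1_len + 2 * self.ir_arm_len
                + self.ir_spacer_len + self.unique2_len + self.satellite_len
                + self.tail_len)

    @property
    def satellite_start(self) -> int:
        return self.total_len - self.satellite_len - self.tail_len


@dataclass
class SharedIndel:
    """A deletion/insertion shared (with identical breakpoints) by groups."""

    groups: tuple[str, ...]
    position: int
    length: int
    kind: str  # "deletion" | "insertion"

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"indel kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("indel length must be positive")

    @property
    def interval(self) -> tuple[int, int]:
        if self.kind == "deletion":
            return (self.position, self.position + self.length)
        return (self.position, self.position)


@dataclass
class ForeignInsertSpec:
    """A group-shared foreign insertion inside the satellite array."""

    groups: tuple[str, ...]
    satellite_offset: int
    length: int


@dataclass
class ExchangeEvent:
    """Single-crossover suffix transfer: the recipient's sequence from the
    breakpoint (ancestor coordinates) onward is replaced by the donor's."""

    recipient: str
    donor: str
    breakpoint: int


@dataclass
class CohortSpec:
    groups: list[tuple[str, list[str]]]
    proximal_sub_rate: float = 0.005
    distal_sub_rate: float = 0.05
    shared_indels: list[SharedIndel] = field(default_factory=list)
    foreign_inserts: list[ForeignInsertSpec] = field(default_factory=list)
    exchange_events: list[ExchangeEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.proximal_sub_rate, self.distal_sub_rate):
            if not (0.0 <= rate <= 0.5):
                raise ValueError("substitution rates must lie in [0, 0.5]")
        members = [m for _, ms in self.groups for m in ms]
        if len(set(members)) != len(members):
            raise ValueError("every member must appear in exactly one group")

    @property
    def members(self) -> list[str]:
        return [m for _, ms in self.groups for m in ms]

    def group_of(self, member: str) -> str:
        for gid, ms in self.groups:
            if member in ms:
                return gid
        raise KeyError(member)


# ---------------------------------------------------------------------------
# ancestor


def build_ancestor(spec: ArchitectureSpec, seed: int,
                   max_length: int = MAX_ANCESTOR_LEN,
                   ) -> tuple[Contig, list[AnnotationRecord]]:
    """Lay out the ancestral contig and annotate each architectural part."""
    if spec.total_len > max_length:
        raise ValueError(
            f"ancestor length {spec.total_len} exceeds maximum {max_length}"
        )
    rng = np.random.default_rng(seed)
    ref = rdna_reference()
    if spec.rdna_stub_len > ref.length:
        raise ValueError("rdna_stub_len exceeds bundled rDNA reference length")
    stub = ref.sequence[ref.length - spec.rdna_stub_len :] if spec.rdna_stub_len else ""
    unique1 = random_dna(spec.unique1_len, rng)
    arm = random_dna(spec.ir_arm_len, rng)
    spacer = random_dna(spec.ir_spacer_len, rng)
    arm_rc = Contig("_", arm).reverse_complement().sequence if arm else ""
    unique2 = random_dna(spec.unique2_len, rng)
    monomer = random_dna(spec.satellite_period, rng)
    reps, rem = divmod(spec.satellite_len, spec.satellite_period)
    satellite = monomer * reps + monomer[:rem]
    tail = random_dna(spec.tail_len, rng)
    seq = stub + unique1 + arm + spacer + arm_rc + unique2 + satellite + tail
    contig = Contig("ancestor", seq, source="synthetic")

    ann: list[AnnotationRecord] = []
    pos = 0

    def advance(n: int) -> tuple[int, int]:
        nonlocal pos
        start, pos = pos, pos + n
        return start, pos

    s, e = advance(spec.rdna_stub_len)
    if e > s:
        ann.append(AnnotationRecord(contig.id, s, e, "rdna_stub"))
    advance(spec.unique1_len)
    s, e = advance(spec.ir_arm_len)
    if e > s:
        ann.append(AnnotationRecord(contig.id, s, e, "inverted_repeat_arm",
                                    {"role": "arm1"}))
    advance(spec.ir_spacer_len)
    s, e = advance(spec.ir_arm_len)
    if e > s:
        ann.append(AnnotationRecord(contig.id, s, e, "inverted_repeat_arm",
                                    {"role": "arm2", "strand": "-"}))
    advance(spec.unique2_len)
    s, e = advance(spec.satellite_len)
    if e > s:
        ann.append(AnnotationRecord(contig.id, s, e, "satellite_block",
                                    {"period": spec.satellite_period,
                                     "monomer": monomer}))
    return contig, ann


# ---------------------------------------------------------------------------
# cohort evolution


@dataclass
class MemberEvents:
    """Realized per-member events, all in ancestor coordinates."""

    group: str
    substitutions: list[tuple[int, str]]
    indels: list[int]   # indices into manifest.shared_indels
    inserts: list[int]  # indices into manifest.foreign_inserts


@dataclass
class SimManifest:
    """Ground truth for a synthetic cohort.

    ``pieces`` gives, per member, the post-exchange mosaic as
    (source_member, ancestor_start, ancestor_end) runs; a member that took part
    in no exchange is a single run of itself.  Replaying the manifest on the
    ancestor (see :func:`replay_manifest`) reproduces every member exactly.
    """

    seed: int
    ancestor_sha256: str
    architecture: dict
    groups: list[tuple[str, list[str]]]
    distal_start: int
    shared_indels: list[dict]      # position, length, kind, groups, sequence
    foreign_inserts: list[dict]    # position (ancestor bp), length, groups, sequence
    group_substitutions: dict[str, list[tuple[int, str]]]
    members: dict[str, MemberEvents]
    pieces: dict[str, list[tuple[str, int, int]]]
    exchange_events: list[dict]
    suggested_reference: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimManifest":
        raw = json.loads(Path(path).read_text())
        raw["members"] = {
            m: MemberEvents(
                group=ev["group"],
                substitutions=[(int(p), b) for p, b in ev["substitutions"]],
                indels=list(ev["indels"]),
                inserts=list(ev["inserts"]),
            )
            for m, ev in raw["members"].items()
        }
        raw["groups"] = [(g, list(ms)) for g, ms in raw["groups"]]
        raw["group_substitutions"] = {
            g: [(int(p), b) for p, b in subs]
            for g, subs in raw["group_substitutions"].items()
        }
        raw["pieces"] = {
            m: [(src, int(a), int(b)) for src, a, b in runs]
            for m, runs in raw["pieces"].items()
        }
        return cls(**raw)

    def marker_truth(self) -> dict[int, set[str]]:
        """Post-exchange carrier set of every shared indel, by indel index."""
        carriers: dict[int, set[str]] = {i: set() for i in range(len(self.shared_indels))}
        for member, runs in self.pieces.items():
            for i, indel in enumerate(self.shared_indels):
                pos = indel["position"]
                for src, a, b in runs:
                    if a <= pos < b:
                        if self.members[src].group in indel["groups"]:
                            carriers[i].add(member)
                        break
        return carriers

    def group_truth(self) -> dict[str, str]:
        """Post-exchange group of every member, defined by its distal tail."""
        out = {}
        for member, runs in self.pieces.items():
            tail_src = runs[-1][0]
            out[member] = self.members[tail_src].group
        return out


def _draw_substitutions(codes: np.ndarray, start: int, end: int, rate: float,
                        rng: np.random.Generator) -> list[tuple[int, str]]:
    if rate <= 0 or end <= start:
        return []
    hits = np.nonzero(rng.random(end - start) < rate)[0] + start
    shifts = rng.integers(1, 4, size=hits.size)
    subs = []
    for pos, shift in zip(hits, shifts):
        new = _BASES[(codes[pos] + shift) % 4]
        subs.append((int(pos), chr(new)))
    return subs


def _apply_events(seq: str, deletions: list[tuple[int, int]],
                  insertions: list[tuple[int, str]]) -> tuple[str, np.ndarray]:
    """Apply indel events (ancestor coordinates) to a substituted sequence.

    Returns the new sequence and an ancestor->member coordinate map of length
    len(seq)+1.  An insertion at position p sits between bases p-1 and p and
    belongs to the suffix starting at p.
    """
    L = len(seq)
    events = sorted(
        [(p, l, None) for p, l in deletions] + [(p, 0, s) for p, s in insertions]
    )
    anc2mem = np.empty(L + 1, dtype=np.int64)
    parts: list[str] = []
    prev = 0
    mem = 0
    for pos, dlen, ins in events:
        parts.append(seq[prev:pos])
        span = pos - prev
        anc2mem[prev:pos] = np.arange(mem, mem + span)
        mem += span
        if ins is None:  # deletion of [pos, pos+dlen)
            anc2mem[pos : pos + dlen] = mem
            prev = pos + dlen
        else:  # insertion before ancestor base pos
            anc2mem[pos] = mem
            parts.append(ins)
            parts.append(seq[pos : pos + 1])
            mem += len(ins) + (1 if pos < L else 0)
            prev = pos + 1
    parts.append(seq[prev:])
    anc2mem[prev:L] = np.arange(mem, mem + (L - prev))
    anc2mem[L] = mem + (L - prev)
    return "".join(parts), anc2mem


def _validate_cohort(spec: CohortSpec, L: int, distal_start: int,
                     sat_span: tuple[int, int]) -> None:
    group_ids = {g for g, _ in spec.groups}
    intervals = []
    for indel in spec.shared_indels:
        unknown = set(indel.groups) - group_ids
        if unknown:
            raise ValueError(f"indel references unknown groups {sorted(unknown)}")
        a, b = indel.interval
        if not (0 <= indel.position and max(b, a + 1) <= distal_start):
            raise ValueError(
                f"shared indel at {indel.position} outside proximal region "
                f"[0, {distal_start})"
            )
        intervals.append((a, max(b, a + 1)))
    intervals.sort()
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 < b1:
            raise ValueError("overlapping shared indels")
    for ins in spec.foreign_inserts:
        if not (0 <= ins.satellite_offset <= sat_span[1] - sat_span[0]):
            raise ValueError("foreign insert offset outside satellite array")
    members = set(spec.members)
    for ev in spec.exchange_events:
        if ev.recipient not in members or ev.donor not in members:
            raise ValueError(f"exchange references unknown member")
        if not (0 < ev.breakpoint < L):
            raise ValueError(f"exchange breakpoint {ev.breakpoint} outside contig")
        for a, b in intervals:
            if a < ev.breakpoint < b:
                raise ValueError("exchange breakpoint inside a shared indel")


def evolve_cohort(ancestor: Contig, spec: CohortSpec,
                  annotations: Sequence[AnnotationRecord],
                  ) -> tuple[list[Contig], SimManifest]:
    """Evolve a cohort from the ancestor according to the cohort spec."""
    L = ancestor.length
    sat = next((a for a in annotations if a.feature_class == "satellite_block"), None)
    sat_span = (sat.start, sat.end) if sat else (L, L)
    distal_start = sat_span[0]
    _validate_cohort(spec, L, distal_start, sat_span)

    ss = np.random.SeedSequence(spec.seed)
    n_groups = len(spec.groups)
    n_members = len(spec.members)
    n_events = len(spec.shared_indels) + len(spec.foreign_inserts)
    children = ss.spawn(n_groups + n_members + max(n_events, 1))
    group_rngs = {g: np.random.default_rng(c)
                  for (g, _), c in zip(spec.groups, children[:n_groups])}
    member_rngs = {m: np.random.default_rng(c)
                   for m, c in zip(spec.members, children[n_groups:n_groups + n_members])}
    event_rngs = [np.random.default_rng(c) for c in children[n_groups + n_members:]]

    anc_codes = np.frombuffer(ancestor.sequence.encode(), dtype=np.uint8).copy()
    code_of = np.zeros(256, dtype=np.uint8)
    for base, i in _CODE.items():
        code_of[ord(base)] = i
    anc_codes = code_of[anc_codes]

    # group-lineage distal substitutions
    group_subs = {
        g: _draw_substitutions(anc_codes, distal_start, L, spec.distal_sub_rate,
                               group_rngs[g])
        for g, _ in spec.groups
    }

    # realized event sequences (shared across carriers by construction)
    indel_records: list[dict] = []
    rng_i = 0
    for indel in spec.shared_indels:
        seq = (random_dna(indel.length, event_rngs[rng_i])
               if indel.kind == "insertion" else "")
        indel_records.append({
            "position": indel.position, "length": indel.length,
            "kind": indel.kind, "groups": list(indel.groups), "sequence": seq,
        })
        rng_i += 1
    insert_records: list[dict] = []
    for ins in spec.foreign_inserts:
        insert_records.append({
            "position": sat_span[0] + ins.satellite_offset, "length": ins.length,
            "groups": list(ins.groups),
            "sequence": random_dna(ins.length, event_rngs[rng_i]),
        })
        rng_i += 1

    members: dict[str, MemberEvents] = {}
    realized: dict[str, str] = {}
    maps: dict[str, np.ndarray] = {}
    for gid, ms in spec.groups:
        for m in ms:
            codes = anc_codes.copy()
            gsubs = group_subs[gid]
            for pos, base in gsubs:
                codes[pos] = _CODE[base]
            msubs = _draw_substitutions(codes, 0, L, spec.proximal_sub_rate,
                                        member_rngs[m])
            for pos, base in msubs:
                codes[pos] = _CODE[base]
            seq = _BASES[codes].tobytes().decode()
            my_indels = [i for i, r in enumerate(indel_records) if gid in r["groups"]]
            my_inserts = [i for i, r in enumerate(insert_records) if gid in r["groups"]]
            deletions = [(indel_records[i]["position"], indel_records[i]["length"])
                         for i in my_indels if indel_records[i]["kind"] == "deletion"]
            insertions = [(indel_records[i]["position"], indel_records[i]["sequence"])
                          for i in my_indels if indel_records[i]["kind"] == "insertion"]
            insertions += [(insert_records[i]["position"], insert_records[i]["sequence"])
                           for i in my_inserts]
            seq, anc2mem = _apply_events(seq, deletions, insertions)
            members[m] = MemberEvents(gid, msubs, my_indels, my_inserts)
            realized[m] = seq
            maps[m] = anc2mem

    # exchanges: single-crossover suffix transfers on the realized lineages
    pieces: dict[str, list[tuple[str, int, int]]] = {
        m: [(m, 0, L)] for m in spec.members
    }
    for ev in spec.exchange_events:
        bp = ev.breakpoint
        new_runs: list[tuple[str, int, int]] = []
        for src, a, b in pieces[ev.recipient]:
            if b <= bp:
                new_runs.append((src, a, b))
            elif a < bp:
                new_runs.append((src, a, bp))
        for src, a, b in pieces[ev.donor]:
            if a >= bp:
                new_runs.append((src, a, b))
            elif b > bp:
                new_runs.append((src, bp, b))
        pieces[ev.recipient] = new_runs

    cohort: list[Contig] = []
    for gid, ms in spec.groups:
        for m in ms:
            parts = [realized[src][maps[src][a]: maps[src][b]]
                     for src, a, b in pieces[m]]
            cohort.append(Contig(m, "".join(parts), source="synthetic",
                                 chromosome_label=gid))

    manifest = SimManifest(
        seed=spec.seed,
        ancestor_sha256=hashlib.sha256(ancestor.sequence.encode()).hexdigest(),
        architecture={"total_len": L, "distal_start": distal_start,
                      "satellite_span": list(sat_span)},
        groups=[(g, list(ms)) for g, ms in spec.groups],
        distal_start=distal_start,
        shared_indels=indel_records,
        foreign_inserts=insert_records,
        group_substitutions=group_subs,
        members=members,
        pieces=pieces,
        exchange_events=[asdict(ev) for ev in spec.exchange_events],
    )
    return cohort, manifest


def replay_manifest(ancestor: Contig, manifest: SimManifest) -> list[Contig]:
    """Rebuild every member from the recorded events alone."""
    L = ancestor.length
    anc_codes = np.frombuffer(ancestor.sequence.encode(), dtype=np.uint8).copy()
    code_of = np.zeros(256, dtype=np.uint8)
    for base, i in _CODE.items():
        code_of[ord(base)] = i
    anc_codes = code_of[anc_codes]

    realized: dict[str, str] = {}
    maps: dict[str, np.ndarray] = {}
    order: list[str] = [m for _, ms in manifest.groups for m in ms]
    for m in order:
        ev = manifest.members[m]
        codes = anc_codes.copy()
        for pos, base in manifest.group_substitutions[ev.group]:
            codes[pos] = _CODE[base]
        for pos, base in ev.substitutions:
            codes[pos] = _CODE[base]
        seq = _BASES[codes].tobytes().decode()
        deletions = [(manifest.shared_indels[i]["position"],
                      manifest.shared_indels[i]["length"])
                     for i in ev.indels
                     if manifest.shared_indels[i]["kind"] == "deletion"]
        insertions = [(manifest.shared_indels[i]["position"],
                       manifest.shared_indels[i]["sequence"])
                      for i in ev.indels
                      if manifest.shared_indels[i]["kind"] == "insertion"]
        insertions += [(manifest.foreign_inserts[i]["position"],
                        manifest.foreign_inserts[i]["sequence"])
                       for i in ev.inserts]
        realized[m], maps[m] = _apply_events(seq, deletions, insertions)

    out = []
    for m in order:
        parts = [realized[src][maps[src][a]: maps[src][b]]
                 for src, a, b in manifest.pieces[m]]
        out.append(Contig(m, "".join(parts), source="synthetic",
                          chromosome_label=manifest.members[m].group))
    return out


# ---------------------------------------------------------------------------
# presets


PRESET_SEEDS = {"minimal": 7, "fig2d": 42, "paper-scale": 42}


def preset(name: str, seed: int | None = None) -> tuple[ArchitectureSpec, CohortSpec]:
    """Named study presets.

    ``fig2d`` is the desk-scale default: a ~62-kb ancestor, three groups of
    2/2/3 members named after the hybrid lines, three shared deletions in the
    proximal region (A carried by group 3; B and C by group 1), and a
    recombinant lineage (GM10063) that enters the group-1 lineage between
    markers A and B and returns to a group-3 lineage after marker C — so it
    carries all three markers while grouping with group 3 by its distal tail.
    ``paper-scale`` uses 100-kb IR arms and places the three deletions at the
    110/161/172-kb positions of the real WAV17 contig.
    """
    if seed is None:
        seed = PRESET_SEEDS[name]
    if name == "minimal":
        arch = ArchitectureSpec(rdna_stub_len=2000, unique1_len=4000,
                                ir_arm_len=3000, ir_spacer_len=1000,
                                unique2_len=3000, satellite_len=2400,
                                tail_len=4000)
        cohort = CohortSpec(groups=[("g1", ["m1", "m2"]), ("g2", ["m3", "m4"])],
                            seed=seed)
        return arch, cohort
    if name == "fig2d":
        arch = ArchitectureSpec()
        cohort = CohortSpec(
            groups=[("g1", ["A9-22", "WAV17"]),
                    ("g2", ["A9-14", "A9-15"]),
                    ("g3", ["A9-13", "A9-21", "GM10063"])],
            shared_indels=[
                SharedIndel(("g3",), 10000, 1500, "deletion"),   # marker A
                SharedIndel(("g1",), 20500, 300, "deletion"),    # marker B
                SharedIndel(("g1",), 21300, 1000, "deletion"),   # marker C
            ],
            foreign_inserts=[
                ForeignInsertSpec(("g1",), 1200, 1500),
                ForeignInsertSpec(("g3",), 2500, 1200),
            ],
            exchange_events=[
                ExchangeEvent("GM10063", "WAV17", 15000),
                ExchangeEvent("GM10063", "A9-21", 40000),
            ],
            seed=seed,
        )
        return arch, cohort
    if name == "paper-scale":
        arch = ArchitectureSpec(rdna_stub_len=4000, unique1_len=80000,
                                ir_arm_len=100000, ir_spacer_len=6000,
                                unique2_len=10000, satellite_len=39984,
                                tail_len=60000)
        cohort = CohortSpec(
            groups=[("g1", ["A9-22", "WAV17"]),
                    ("g2", ["A9-14", "A9-15"]),
                    ("g3", ["A9-13", "A9-21", "GM10063"])],
            shared_indels=[
                SharedIndel(("g3",), 110000, 1500, "deletion"),
                SharedIndel(("g1",), 161000, 300, "deletion"),
                SharedIndel(("g1",), 172000, 5000, "deletion"),
            ],
            foreign_inserts=[
                ForeignInsertSpec(("g1",), 5000, 9000),
                ForeignInsertSpec(("g3",), 20000, 9000),
            ],
            exchange_events=[
                ExchangeEvent("GM10063", "WAV17", 135000),
                ExchangeEvent("GM10063", "A9-21", 250000),
            ],
            seed=seed,
        )
        return arch, cohort
    raise ValueError(f"unknown preset {name!r}")


def simulate_preset(name: str, seed: int | None = None,
                    ) -> tuple[Contig, list[AnnotationRecord], list[Contig], SimManifest]:
    """Build ancestor + cohort for a named preset in one call."""
    arch, cohort_spec = preset(name, seed)
    ancestor, ann = build_ancestor(arch, cohort_spec.seed)
    cohort, manifest = evolve_cohort(ancestor, cohort_spec, ann)
    manifest.suggested_reference = "A9-14" if name != "minimal" else "m1"
    return ancestor, ann, cohort, manifest
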