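"""Reading/writing the standard formats the pipeline touches, plus run configuration.

Coordinates are 0-based half-open everywhere in this package; BED is therefore
written natively.  N bases are accepted on input (accession sequences contain
gap-filled Ns) but are excluded from identity denominators downstream.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

FEATURE_CLASSES = (
    "satellite_block",
    "inverted_repeat_arm",
    "foreign_insert",
    "rdna_stub",
    "homology_block",
    "indel_marker",
)


@dataclass
class Contig:
    """A named DNA sequence with chromosome/source labels.

    ``sequence`` is an uppercase string over {A,C,G,T,N}; ``chromosome_label``
    is e.g. ``"HSA21"`` and ``source`` the hybrid line of origin (``"WAV17"``).
    """

    id: str
    sequence: str
    source: str = ""
    chromosome_label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Contig id must be non-empty")
        self.sequence = self.sequence.upper()
        _validate_sequence(self.sequence, self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self, new_id: str | None = None) -> "Contig":
        rc = str(Seq(self.sequence).reverse_complement())
        return Contig(new_id or f"{self.id}_rc", rc, self.source, self.chromosome_label)


def _validate_sequence(seq: str, name: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"illegal character {seq[offset]!r} at offset {offset} in record {name!r}"
        )


@dataclass
class AnnotationRecord:
    """A feature interval on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    feature_class: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_sequences(path: str | Path) -> list[Contig]:
    """Read a (multi-)FASTA file into Contigs.

    Header tokens may encode source and chromosome as ``id|source|chromosome``.
    Lowercase is normalised to uppercase; characters outside {A,C,G,T,N} are
    rejected with their offset.
    """
    path = Path(path)
    contigs: list[Contig] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.id.split("|")
        cid = tokens[0]
        source = tokens[1] if len(tokens) > 1 else ""
        chrom = tokens[2] if len(tokens) > 2 else ""
        contigs.append(Contig(cid, str(rec.seq), source=source, chromosome_label=chrom))
    if not contigs:
        raise ValueError(f"no records in {path}")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate contig ids in {path}")
    return contigs


def write_sequences(contigs: Iterable[Contig], path: str | Path) -> None:
    """Write contigs to FASTA, encoding labels as ``id|source|chromosome``."""
    records = []
    for c in contigs:
        name = c.id
        if c.source or c.chromosome_label:
            name = f"{c.id}|{c.source}|{c.chromosome_label}"
        records.append(SeqRecord(Seq(c.sequence), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write annotations as BED6+1 (extra column holds serialized attributes).

    Records are written sorted by (contig_id, start); strand comes from the
    ``strand`` attribute when present, else ``+``.
    """
    lines = []
    for rec in sorted(records, key=lambda r: (r.contig_id, r.start, r.end)):
        attrs = {k: v for k, v in rec.attributes.items() if k != "strand"}
        extra = ";".join(f"{k}={v}" for k, v in sorted(attrs.items())) or "."
        strand = rec.attributes.get("strand", "+")
        lines.append(
            "\t".join(
                [rec.contig_id, str(rec.start), str(rec.end), rec.feature_class,
                 "0", str(strand), extra]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read back a BED6+1 file written by :func:`write_annotations`."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        chrom, start, end, name, _score, strand = fields[:6]
        attrs: dict = {}
        if len(fields) > 6 and fields[6] != ".":
            for kv in fields[6].split(";"):
                k, _, v = kv.partition("=")
                attrs[k] = v
        if strand != "+":
            attrs["strand"] = strand
        records.append(AnnotationRecord(chrom, int(start), int(end), name, attrs))
    return records


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a marker-presence or distance matrix as TSV (header row of labels)."""
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a sectioned key=value config file; CLI flags override these values."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    return {section: dict(parser[section]) for section in parser.sections()}


def run_manifest(parameters: Mapping, inputs: Iterable[str | Path], seed: int | None,
                 path: str | Path) -> None:
    """Write a JSON run manifest with parameters, seed and input checksums."""
    checksums = {}
    for p in inputs:
        p = Path(p)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    payload = {"parameters": dict(parameters), "seed": seed, "inputs": checksums}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
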