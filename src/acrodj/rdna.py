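"""Synthetic rDNA reference segment.

The simulator and the junction finder need an intergenic-spacer-like rDNA
segment whose end abuts the distal junction.  No real rDNA sequence is bundled;
this module generates a deterministic *synthetic* stand-in segment instead.
For analysis of real accession contigs, supply a genuine IGS-containing
reference (e.g. extracted from the U13369 rDNA repeat) to ``find_junction``.
"""

from __future__ import annotations

import numpy as np

from .io import Contig

_RDNA_SEED = 190413  # fixed; the segment is part of the package's definition
RDNA_REF_LEN = 6000

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def rdna_reference(length: int = RDNA_REF_LEN) -> Contig:
    """Deterministic synthetic IGS-like rDNA segment.

    The segment's last base is defined to abut the rDNA/DJ junction, i.e. the
    simulator copies a suffix of this segment as each ancestor's rDNA stub.
    """
    rng = np.random.default_rng(_RDNA_SEED)
    return Contig("rdna_ref_synthetic", random_dna(length, rng), source="synthetic")
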