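"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (substitutions only)."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length n."""
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_positions(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position with a uniformly chosen *different* base."""
    out = list(seq)
    for p in positions:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def phred_from_string(qual: str) -> list[int]:
    """Decode a FASTQ quality string (Sanger, offset 33) to integer phred scores."""
    return [ord(c) - 33 for c in qual]
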