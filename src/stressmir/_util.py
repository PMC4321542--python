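"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def hamming(a: str, b: str) -> int:
    """Hamming distance over the common prefix; lengths must match."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def is_wc_pair(x: str, y: str) -> bool:
    """Watson-Crick pair (DNA letters)."""
    return (x, y) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def is_gu_pair(x: str, y: str) -> bool:
    """G:U wobble (written G:T in DNA space)."""
    return (x, y) in {("G", "T"), ("T", "G")}


def can_pair(x: str, y: str) -> bool:
    """Watson-Crick or G:U wobble."""
    return is_wc_pair(x, y) or is_gu_pair(x, y)
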