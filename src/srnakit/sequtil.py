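"""Small sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    idx = rng.integers(0, 4, size=length, dtype=np.uint8)
    return bytes(_BASES_U8[idx]).decode("ascii")


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)
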