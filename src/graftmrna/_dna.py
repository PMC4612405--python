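"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 ASCII code -> 0..3 index (A,C,G,T); 255 for anything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return bytes(_BASE_BYTES[codes]).decode("ascii")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def base_indices(seq: str) -> np.ndarray:
    """Encode a DNA string as 0..3 base indices (255 for non-ACGT)."""
    return _CODE[encode(seq)]


def mutate_base(rng: np.random.Generator, base: str) -> str:
    """Substitute `base` with one of the three other bases, uniformly."""
    i = BASE_TO_INDEX[base]
    return BASES[(i + 1 + rng.integers(0, 3)) % 4]
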