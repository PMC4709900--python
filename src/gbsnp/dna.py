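"""Small DNA helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: stable base order used everywhere depth 4-tuples appear
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte value -> 0..3 (A,C,G,T), 255 for anything else (N etc.)
_CODE = np.full(256, 255, dtype=np.uint8)
for _b in "ACGT":
    _CODE[ord(_b)] = BASE_INDEX[_b]
    _CODE[ord(_b.lower())] = BASE_INDEX[_b]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of base codes (A=0,C=1,G=2,T=3, other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def phred(qual: str) -> np.ndarray:
    """Phred+33 quality string -> integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
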