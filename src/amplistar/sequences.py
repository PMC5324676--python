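"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte value -> base code (A=0 C=1 G=2 T=3), 255 for anything else
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3)."""
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    """uint8 codes -> DNA string."""
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def homopolymer_runs(seq: str, min_len: int = 8) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= ``min_len``.

    Returns ``(start, end, base)`` with 0-based half-open coordinates.
    """
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j, seq[i]))
        i = j
    return runs


def run_length_at(seq: str, pos0: int) -> int:
    """Length of the maximal homopolymer run covering 0-based ``pos0``."""
    base = seq[pos0]
    i = pos0
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos0
    n = len(seq)
    while j + 1 < n and seq[j + 1] == base:
        j += 1
    return j - i + 1
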