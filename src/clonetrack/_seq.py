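"""Low-level nucleotide-sequence helpers (2-bit encoding, vectorised Hamming)."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seqs: list[str] | np.ndarray) -> np.ndarray:
    """Encode equal-length ACGT strings into a (n, L) uint8 matrix."""
    if len(seqs) == 0:
        return np.empty((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    n, L = len(seqs), len(seqs[0])
    arr = arr.reshape(n, L)
    out = np.empty_like(arr)
    # ASCII -> 2-bit codes; anything outside ACGT raises
    lookup = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        lookup[ord(base)] = code
    out = lookup[arr]
    if (out == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return out


def decode(mat: np.ndarray) -> list[str]:
    lookup = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    return [bytes(lookup[row]).decode() for row in mat]


def hamming_to_all(query: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Hamming distance from one encoded sequence to every row of ``mat``."""
    return (mat != query[None, :]).sum(axis=1)
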