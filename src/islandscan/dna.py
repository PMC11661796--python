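"""Low-level DNA sequence helpers shared across the package.

Sequences are plain upper-case ACGT strings at the API surface; internally
they are encoded as small integer arrays (A=0, C=1, G=2, T=3) so that PWM
scanning and Hamming distances vectorize over whole libraries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i


def validate(seq: str) -> None:
    """Raise ValueError naming the first offending position if *seq* is not pure ACGT."""
    for i, c in enumerate(seq):
        if c not in BASE_INDEX:
            raise ValueError(f"non-ACGT character {c!r} at position {i}")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A=0, C=1, G=2, T=3)."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        validate(seq)  # raises with the offending position
    return arr


def encode_many(seqs) -> np.ndarray:
    """Encode an iterable of equal-length DNA strings as an (N, L) int8 array."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty sequence list")
    joined = "".join(seqs)
    arr = _LUT[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        for s in seqs:
            validate(s)
    length = len(seqs[0])
    if len(joined) != length * len(seqs):
        raise ValueError("sequences have unequal lengths")
    return arr.reshape(len(seqs), length)


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in np.asarray(arr))


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
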