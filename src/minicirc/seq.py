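"""Low-level DNA string helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric encoding used by the alignment kernels: A=0 C=1 G=2 T=3, N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def validate_alphabet(seq: str, *, name: str = "sequence") -> None:
    """Raise ``ValueError`` if *seq* contains characters outside ACGTN."""
    bad = set(seq.upper()) - VALID_CHARS
    if bad:
        raise ValueError(
            f"{name} contains non-ACGTN characters: {sorted(bad)[:5]}"
        )


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes excluded from the denominator.

    Returns ``nan`` for sequences with no unambiguous bases.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return float("nan")
    return gc / denom


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Draw an i.i.d. DNA string with expected GC fraction *gc*."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=p)
    return "".join(DNA_BASES[c] for c in codes)


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so position *offset* becomes position 0."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]
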