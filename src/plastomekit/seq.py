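"""Low-level nucleotide utilities for linear and circular DNA.

Coordinates are 0-based half-open throughout the package.  Circularity is
handled by explicit wrap-around arithmetic; sequence doubling is used only
inside search routines, never in stored objects.
"""
from __future__ import annotations

import numpy as np

#: IUPAC degenerate nucleotide codes mapped to the base sets they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMP = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: 4-bit encoding of IUPAC codes (bit per base) for vectorised matching.
IUPAC_BITS: dict[str, int] = {
    code: sum(1 << "ACGT".index(b) for b in bases) for code, bases in IUPAC_SETS.items()
}

_DNA = np.frombuffer(b"ACGT", dtype="S1")


def complement(s: str) -> str:
    """Complement of a (possibly degenerate) DNA string, same orientation."""
    return s.translate(_COMP)


def revcomp(s: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    return s.translate(_COMP)[::-1]


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect (symmetric)."""
    return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])


def at_fraction(s: str) -> float:
    """Exact A+T fraction of a sequence (denominator is the full length)."""
    if not s:
        raise ValueError("AT fraction of an empty sequence is undefined")
    u = s.upper()
    return (u.count("A") + u.count("T")) / len(s)


def at_count(s: str) -> int:
    u = s.upper()
    return u.count("A") + u.count("T")


def random_dna(n: int, at: float, rng: np.random.Generator) -> str:
    """Random DNA of length ``n`` with i.i.d. bases at the given AT fraction."""
    if not 0.0 <= at <= 1.0:
        raise ValueError(f"AT fraction must be in [0, 1], got {at}")
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    idx = rng.choice(4, size=n, p=p)
    return _DNA[idx].tobytes().decode("ascii")


def mutate(s: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-base rate."""
    if rate <= 0:
        return s
    n_mut = rng.binomial(len(s), rate)
    if n_mut == 0:
        return s
    pos = rng.choice(len(s), size=n_mut, replace=False)
    out = list(s)
    bases = "ACGT"
    for p in pos:
        alts = [b for b in bases if b != out[p].upper()]
        out[p] = alts[rng.integers(0, len(alts))]
    return "".join(out)


def rotate(s: str, k: int) -> str:
    """Rotate a circular sequence so that position ``k`` becomes position 0."""
    k %= len(s)
    return s[k:] + s[:k]


def circularly_equal(a: str, b: str, allow_revcomp: bool = False) -> bool:
    """Rotation-invariant equality of two circular sequences."""
    if len(a) != len(b):
        return False
    if a in b + b:
        return True
    return allow_revcomp and revcomp(a) in b + b


def circular_slice(s: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` of a circle, wrapping if ``end`` exceeds len."""
    n = len(s)
    length = end - start
    if length < 0 or length > n:
        raise ValueError("circular_slice requires start <= end <= start + len(s)")
    start %= n
    if start + length <= n:
        return s[start:start + length]
    return s[start:] + s[:(start + length) % n]


def count_mismatches(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance with optional early exit once ``limit`` is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


def iupac_match_count(primer: str, window: str) -> int:
    """Number of IUPAC-compatible positions between primer and window."""
    return sum(iupac_compatible(p, w) for p, w in zip(primer, window))


def encode_bits(s: str) -> np.ndarray:
    """Encode a DNA string as 4-bit IUPAC masks for vectorised matching."""
    lut = np.zeros(128, dtype=np.uint8)
    for code, bits in IUPAC_BITS.items():
        lut[ord(code)] = bits
        lut[ord(code.lower())] = bits
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return lut[arr]
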