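"""Small DNA-string utilities shared across modules."""

from __future__ import annotations

import itertools
import zlib

import numpy as np

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte lookup used by the vectorised simulator (codes 0..3 -> ASCII)
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: str = DNA_BASES) -> bool:
    return len(seq) > 0 and all(c in alphabet for c in seq)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (A=0, C=1, G=2, T=3)."""
    arr = _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-ACGT character in sequence {seq!r}")
    return arr


def decode_rows(codes: np.ndarray) -> list[str]:
    """uint8 code matrix -> list of DNA strings, one per row."""
    ascii_rows = BASE_BYTES[codes]
    return [row.tobytes().decode("ascii") for row in ascii_rows]


def stable_seed(key: str) -> int:
    """Deterministic 31-bit seed derived from a string key."""
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF


def deterministic_sequence(key: str, length: int) -> str:
    """Reproducible pseudo-random DNA string keyed on an identifier.

    Used for amplicon filler so the simulated reference depends only on
    the locus identity, never on the run seed.
    """
    rng = np.random.default_rng(stable_seed(key))
    return "".join(rng.choice(list(DNA_BASES), size=length))


def generate_barcodes(n: int, length: int = 6, min_dist: int = 3,
                      seed: int = 20240601) -> list[str]:
    """Greedy code set with pairwise Hamming distance >= ``min_dist``.

    Enumerates all ``4**length`` words in a seed-shuffled order and keeps
    each word far enough from everything already kept.  Distance >= 3
    makes single-mismatch rescue unambiguous.
    """
    rng = np.random.default_rng(seed)
    words = ["".join(p) for p in itertools.product(DNA_BASES, repeat=length)]
    rng.shuffle(words)
    kept: list[str] = []
    for w in words:
        if all(hamming(w, k) >= min_dist for k in kept):
            kept.append(w)
            if len(kept) == n:
                return kept
    raise ValueError(f"cannot build {n} codes of length {length} at distance {min_dist}")
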