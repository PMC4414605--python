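"""Bloom filters over canonical b-mers, with the classical false-positive model.

A filter is an m-bit array with k hash functions. After inserting n elements,
the false-positive rate is approximately F = (1 - e^(-k/r))^k with r = m/n
bits per element; minimizing over k gives k = r*ln(2) and F = (0.6185)^r.
Membership queries have no false negatives, which is what makes the filter
safe as a read-dispatch gate: a read that truly matches a partition can never
be routed away from it.

b-mers are canonicalized (lexicographic min of the b-mer and its reverse
complement) on both build and query, so reverse-strand matches are covered.
b-mers containing N are invalid and skipped on both sides.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import struct
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from dispatchmap.io_formats import TargetSeq

_RC = str.maketrans("ACGTN", "TGCAN")

_MAGIC = b"DMBF1\n"


def reverse_complement(s: str) -> str:
    return s.translate(_RC)[::-1]


def canonical(bmer: str, b: Optional[int] = None) -> Optional[str]:
    """Canonical form of a b-mer: min(bmer, reverse_complement(bmer)).

    Returns None for b-mers containing a base outside {A,C,G,T} (callers
    skip these). Raises if ``b`` is given and the length does not match.
    """
    if b is not None and len(bmer) != b:
        raise ValueError(f"expected a {b}-mer, got length {len(bmer)}")
    if "N" in bmer:
        return None
    rc = bmer.translate(_RC)[::-1]
    return bmer if bmer <= rc else rc


# alias matching the operation name used elsewhere in the package docs
canonical_bmer = canonical


def base_hashes(key: bytes, seed: int) -> tuple[int, int]:
    """Two independent seeded 64-bit hashes of ``key`` (one keyed blake2b
    digest split in half). Deterministic across runs and platforms."""
    digest = hashlib.blake2b(
        key, digest_size=16, key=seed.to_bytes(8, "little")
    ).digest()
    return struct.unpack("<QQ", digest)


def hash_positions(key: bytes, k: int, m: int, seed: int = 0) -> list[int]:
    """k bit positions in [0, m) by double hashing: (g1 + i*g2) mod m."""
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    g1, g2 = base_hashes(key, seed)
    return [(g1 + i * g2) % m for i in range(k)]


def fpr(r: float, k: int) -> float:
    """False-positive rate (1 - e^(-k/r))^k for r bits per element."""
    if r <= 0:
        raise ValueError(f"bits-per-element r must be positive, got {r}")
    if k < 1:
        raise ValueError(f"number of hash functions k must be >= 1, got {k}")
    return (1.0 - math.exp(-k / r)) ** k


def optimal_k(r: float) -> int:
    """Optimal integer number of hash functions, floor(r*ln 2), at least 1."""
    if r <= 0:
        raise ValueError(f"bits-per-element r must be positive, got {r}")
    return max(1, math.floor(r * math.log(2)))


@dataclass
class BloomFilter:
    """m-bit array + k seeded double-hashing functions over canonical b-mers."""

    m: int
    k: int
    b: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 1:
            raise ValueError("m and k must be >= 1")
        self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)
        self.n_inserted = 0

    # -- low-level bit ops ---------------------------------------------------
    def _set(self, pos: int) -> None:
        self.bits[pos >> 3] |= np.uint8(1 << (pos & 7))

    def _get(self, pos: int) -> bool:
        return bool(self.bits[pos >> 3] >> (pos & 7) & 1)

    # -- hashed-key interface (hash once, query many filters) ---------------
    def insert_hashed(self, g1: int, g2: int) -> None:
        for i in range(self.k):
            self._set((g1 + i * g2) % self.m)
        self.n_inserted += 1

    def contains_hashed(self, g1: int, g2: int) -> bool:
        for i in range(self.k):
            if not self._get((g1 + i * g2) % self.m):
                return False
        return True

    # -- string-key interface -----------------------------------------------
    def insert(self, key: str | bytes) -> None:
        if isinstance(key, str):
            key = key.encode("ascii")
        self.insert_hashed(*base_hashes(key, self.seed))

    def contains(self, key: str | bytes) -> bool:
        if isinstance(key, str):
            key = key.encode("ascii")
        return self.contains_hashed(*base_hashes(key, self.seed))

    def __contains__(self, key: str | bytes) -> bool:
        return self.contains(key)

    def popcount(self) -> int:
        return int(np.unpackbits(self.bits).sum())

    def occupancy(self) -> float:
        return self.popcount() / self.m

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        meta = {
            "m": self.m, "k": self.k, "b": self.b,
            "seed": self.seed, "n_inserted": self.n_inserted,
        }
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(json.dumps(meta).encode("ascii") + b"\n")
            fh.write(self.bits.tobytes())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "BloomFilter":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a filter file (bad magic)")
            meta = json.loads(fh.readline())
            f = cls(m=meta["m"], k=meta["k"], b=meta["b"], seed=meta["seed"])
            raw = fh.read()
        f.bits = np.frombuffer(raw, dtype=np.uint8).copy()
        if f.bits.size != (f.m + 7) // 8:
            raise ValueError(f"{path}: truncated bit array")
        f.n_inserted = meta["n_inserted"]
        return f


def iter_canonical_bmers(seq: str, b: int) -> Iterator[str]:
    """Canonical b-mers of ``seq`` with stride 1, skipping those with N."""
    for i in range(len(seq) - b + 1):
        c = canonical(seq[i : i + b])
        if c is not None:
            yield c


def count_bmer_positions(targets: Iterable[TargetSeq], b: int) -> int:
    """Number of valid (N-free) b-mer positions across all targets."""
    return sum(1 for t in targets for _ in iter_canonical_bmers(t.seq, b))


def build_filter(
    targets: list[TargetSeq], b: int, r: float = 8.0, seed: int = 0
) -> BloomFilter:
    """Build a partition filter holding every canonical b-mer of ``targets``.

    The bit-array size is m = r * (number of valid b-mer positions, counted
    before canonical deduplication), and k = optimal_k(r).
    """
    if b < 1:
        raise ValueError("b-mer length must be >= 1")
    bmers = [c for t in targets for c in iter_canonical_bmers(t.seq, b)]
    if not bmers:
        warnings.warn(f"no valid {b}-mers in targets; filter is empty")
    m = max(1, round(r * len(bmers)))
    f = BloomFilter(m=m, k=optimal_k(r), b=b, seed=seed)
    for c in bmers:
        f.insert(c)
    return f
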