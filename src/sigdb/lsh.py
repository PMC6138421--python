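"""K-mer extraction and locality-sensitive hashing of sequences.

A sequence is decomposed into overlapping k-mers (sliding window, step 1) and
each k-mer is hashed to one position of a fixed-length binary vector — the
locality-sensitive hash (LSH) of the sequence. Two similar sequences share
most of their k-mers and therefore most of their set positions, so the
popcount of the AND of two LSHs estimates the size of their shared k-mer set.

Two conventions matter and are fixed here:

* **Window count.** A sequence of length ``n`` yields ``n - k`` windows, at
  offsets ``0 .. n-k-1``; the final base never starts a window. (A step-1
  window could also be counted as ``n - k + 1``; the ``n - k`` convention is
  what the sizing arithmetic in this package assumes, e.g. 19,992 8-mers for
  a 20,000-base sequence.) Sequences of length ``<= k`` are rejected.
* **Hash function.** K-mers are hashed with a seeded, stable 64-bit keyed
  BLAKE2b digest reduced modulo the LSH length. The seed travels with the
  :class:`LSHConstructor` so that both protocol parties place identical
  k-mers at identical positions, on any platform and in any process.

The LSH length is sized at a fixed ratio (default 5:1) of positions to the
longest sequence being compared; at that ratio the chance that a given k-mer
shares its position with at least one of the other ``n - 1`` k-mers is
``1 - (1 - 1/L)^(n-1)``, about 18% for n = 20,000 and L = 100,000.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import DimensionMismatchError, SequenceError
from .sequences import Sequence

#: Default ratio of LSH positions to bases of the longest sequence.
DEFAULT_LSH_RATIO = 5

HASH_NAME = "blake2b-64"


def kmer_space_size(k: int) -> int:
    """Number of possible DNA k-mers over {A,C,G,T}: ``4**k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 4**k


def extract_kmers(seq: Sequence, k: int) -> list[str]:
    """All k-mers of ``seq`` by a step-1 sliding window, duplicates retained.

    Returns the ``n - k`` windows at offsets ``0 .. n-k-1``. Raises
    :class:`SequenceError` if ``len(seq) <= k`` (no window under the
    ``n - k`` convention).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(seq)
    if n <= k:
        raise SequenceError(
            f"sequence {seq.id!r} has length {n} <= k={k}: no k-mer windows "
            f"under the n-k window convention"
        )
    b = seq.bases
    return [b[i : i + k] for i in range(n - k)]


def lsh_size_for(max_seq_len: int, ratio: int = DEFAULT_LSH_RATIO) -> int:
    """LSH length for a given maximum sequence length (default 5:1 rule)."""
    if max_seq_len < 1:
        raise ValueError("max_seq_len must be >= 1")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    return ratio * max_seq_len


def collision_probability(n_items: int, L: int) -> float:
    """Chance a given item shares its hash position with another.

    Closed form ``1 - (1 - 1/L)**(n_items - 1)`` under uniform placement of
    ``n_items`` items into ``L`` positions.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if L < 1:
        raise ValueError("L must be >= 1")
    return 1.0 - (1.0 - 1.0 / L) ** (n_items - 1)


def expected_distinct(n_items: int, space: int) -> float:
    """Expected number of distinct values among ``n_items`` uniform draws
    from a space of ``space`` values: ``space * (1 - (1 - 1/space)**n)``."""
    return space * (1.0 - (1.0 - 1.0 / space) ** n_items)


@dataclass(frozen=True)
class LSHConstructor:
    """Shared parameters that define the k-mer -> position map.

    Both parties must use the same constructor: identical ``(k, L,
    hash_seed)`` guarantee identical k-mers land at identical positions.
    """

    k: int
    L: int
    hash_seed: int = 0
    hash_name: str = HASH_NAME

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.hash_name != HASH_NAME:
            raise ValueError(f"unsupported hash function {self.hash_name!r}")
        # keyed-BLAKE2b key derived once from the seed
        object.__setattr__(
            self, "_key", self.hash_seed.to_bytes(8, "little", signed=False)
        )

    def hash_kmer(self, kmer: str) -> int:
        """Deterministic position in ``[0, L)`` for a k-mer.

        Stable across runs and platforms for a fixed ``(kmer, hash_seed, L)``.
        """
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer {kmer!r} has length {len(kmer)}, constructor expects k={self.k}"
            )
        digest = hashlib.blake2b(
            kmer.encode("ascii"), digest_size=8, key=self._key
        ).digest()
        return int.from_bytes(digest, "little") % self.L


def hash_kmer(kmer: str, constructor: LSHConstructor) -> int:
    """Functional alias for :meth:`LSHConstructor.hash_kmer`."""
    return constructor.hash_kmer(kmer)


@dataclass
class LSHVector:
    """Binary vector of length L; bit j is set iff some k-mer hashes to j."""

    bits: np.ndarray  # bool array of length L

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ValueError("LSH bits must be a 1-D vector")

    @property
    def L(self) -> int:
        return self.bits.shape[0]

    @property
    def magnitude(self) -> int:
        """Popcount: number of filled positions."""
        return int(np.count_nonzero(self.bits))

    def positions(self) -> np.ndarray:
        """Sorted indices of the set bits."""
        return np.flatnonzero(self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LSHVector):
            return NotImplemented
        return self.L == other.L and bool(np.array_equal(self.bits, other.bits))


def build_lsh(seq: Sequence, constructor: LSHConstructor) -> LSHVector:
    """Hash every k-mer of ``seq`` into a fresh length-L bit vector.

    Repeated k-mers set their shared position once, so
    ``magnitude <= min(L, n - k)``.
    """
    bits = np.zeros(constructor.L, dtype=bool)
    hash_one = constructor.hash_kmer
    for kmer in extract_kmers(seq, constructor.k):
        bits[hash_one(kmer)] = True
    return LSHVector(bits)


def intersection(a: LSHVector, b: LSHVector) -> int:
    """Popcount of the AND of two equal-length LSH vectors."""
    if a.L != b.L:
        raise DimensionMismatchError(
            f"LSH lengths differ: {a.L} vs {b.L}; both parties must share one constructor"
        )
    return int(np.count_nonzero(a.bits & b.bits))
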