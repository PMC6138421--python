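"""Database-Owner-side protocol operations.

The owner hashes every database entry with the Querier-provided LSH
constructor, then scores the encrypted query against *every* entry — no
early termination, so the point at which computation stops reveals nothing
about which entry matched (execution time scales only with database size).

Scoring never decrypts anything: the encrypted intersection count is the
homomorphic sum of the query's ciphertexts at exactly the positions filled
in the entry's (plaintext) LSH. The owner returns, per entry, the pair
{encrypted intersection, plaintext entry magnitude}.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

from .errors import DimensionMismatchError
from .lsh import LSHConstructor, LSHVector, build_lsh
from .paillier import Ciphertext
from .querier import EncryptedQuery
from .sequences import Sequence, read_fasta


@dataclass
class ScorePair:
    """Owner's reply for one entry: encrypted count + plaintext magnitude."""

    entry_id: str
    encrypted_intersection: Ciphertext
    db_magnitude: int


@dataclass
class DatabaseIndex:
    """Ordered per-entry LSHs built with the shared constructor.

    ``max_seq_len`` is the longest entry length after truncation — the value
    the Querier's LSH sizing needs. ``max_seq_len_raw`` records the longest
    pre-truncation length for logging.
    """

    entries: list[tuple[str, LSHVector]]
    constructor: LSHConstructor
    max_seq_len: int
    max_seq_len_raw: int

    def __len__(self) -> int:
        return len(self.entries)


def build_index(
    source: Union[str, Path, list[Sequence]],
    constructor: LSHConstructor,
    truncate_len: Optional[int] = None,
) -> DatabaseIndex:
    """Hash each database record into an LSH, preserving record order.

    ``source`` is a FASTA path or an in-memory record list. Records longer
    than ``truncate_len`` contribute only their first ``truncate_len`` bases.
    """
    records = source if isinstance(source, list) else read_fasta(source)
    max_raw = max(len(r) for r in records)
    if truncate_len is not None:
        records = [r.truncated(truncate_len) for r in records]
    entries = [(r.id, build_lsh(r, constructor)) for r in records]
    return DatabaseIndex(
        entries=entries,
        constructor=constructor,
        max_seq_len=max(len(r) for r in records),
        max_seq_len_raw=max_raw,
    )


def score_entry(
    enc_query: EncryptedQuery,
    entry_id: str,
    entry_lsh: LSHVector,
    rng: Optional[random.Random] = None,
) -> ScorePair:
    """Encrypted intersection of the query with one entry.

    Multiplies (= homomorphically adds) the query ciphertexts at the entry's
    filled positions, seeded with a fresh encryption of zero so that every
    returned ciphertext carries fresh randomness — including the one for an
    empty entry. Work is proportional to the entry's popcount only.
    """
    if entry_lsh.L != enc_query.L:
        raise DimensionMismatchError(
            f"entry LSH length {entry_lsh.L} != encrypted query length {enc_query.L}"
        )
    pk = enc_query.public_key
    n2 = pk.nsquare
    acc = pk.encrypt(0, rng=rng).value
    cts = enc_query.ciphertexts
    for j in entry_lsh.positions():
        acc = acc * cts[j].value % n2
    return ScorePair(
        entry_id=entry_id,
        encrypted_intersection=Ciphertext(value=acc, public_key=pk),
        db_magnitude=entry_lsh.magnitude,
    )


def scan_database(
    enc_query: EncryptedQuery,
    index: DatabaseIndex,
    rng: Optional[random.Random] = None,
    on_entry: Optional[Callable[[str], None]] = None,
) -> list[ScorePair]:
    """Score the encrypted query against every entry, in index order.

    The scan-all contract is unconditional: all entries are scored on every
    query regardless of intermediate results. ``on_entry`` is an
    instrumentation hook invoked once per entry (used to audit the
    contract); it must not influence scoring.
    """
    if index.constructor != enc_query.constructor:
        raise DimensionMismatchError(
            "database index and encrypted query were built with different LSH constructors"
        )
    pairs = []
    for entry_id, entry_lsh in index.entries:
        if on_entry is not None:
            on_entry(entry_id)
        pairs.append(score_entry(enc_query, entry_id, entry_lsh, rng=rng))
    return pairs
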