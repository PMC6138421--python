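"""Querier-side protocol operations.

The Querier hashes the secret sequence into an LSH, encrypts every position
(zeros included — an unencrypted zero would leak the query's k-mer content),
sends the ciphertext vector to the Database Owner, and later decrypts the
returned per-entry intersection counts to form the three similarity metrics:

* ``IoU = I / (|Q| + |D| - I)`` — intersection over union,
* ``IoQ = I / |Q|``            — intersection over query magnitude,
* ``IoD = I / |D|``            — intersection over database-entry magnitude,

where ``I`` is the number of LSH positions filled in both vectors and
``|Q|``, ``|D|`` are the two magnitudes. IoQ (IoD) is insensitive to the
entry (query) being longer, which is why all three are reported. A metric
with a zero denominator is defined as 0.

The plaintext query magnitude ``|Q|`` stays on the Querier's side; it is
never part of any artifact handed to the owner.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence as TSequence

from .errors import IntegrityError
from .lsh import LSHConstructor, build_lsh
from .paillier import Ciphertext, PrivateKey, PublicKey
from .sequences import Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .db_owner import ScorePair


@dataclass
class EncryptedQuery:
    """Length-L vector of ciphertexts plus the shared LSH constructor.

    ``query_magnitude`` is Querier-local state and is excluded from the
    serialized artifact sent to the Database Owner.
    """

    ciphertexts: list[Ciphertext]
    constructor: LSHConstructor
    public_key: PublicKey
    query_magnitude: int

    def __post_init__(self) -> None:
        if len(self.ciphertexts) != self.constructor.L:
            raise ValueError(
                f"ciphertext vector length {len(self.ciphertexts)} != L={self.constructor.L}"
            )

    @property
    def L(self) -> int:
        return self.constructor.L


@dataclass(frozen=True)
class SimilarityScores:
    """Decrypted per-entry similarity result."""

    entry_id: str
    intersection: int
    db_magnitude: int
    iou: float
    ioq: float
    iod: float


def build_encrypted_query(
    seq: Sequence,
    constructor: LSHConstructor,
    pk: PublicKey,
    rng: Optional[random.Random] = None,
) -> EncryptedQuery:
    """Hash ``seq`` and encrypt all L positions of its LSH element-wise.

    Every position is encrypted, set or not, each with fresh randomness, so
    the ciphertext vector reveals nothing about which positions are filled.
    """
    lsh = build_lsh(seq, constructor)
    bits = lsh.bits
    ciphertexts = [pk.encrypt(int(b), rng=rng) for b in bits]
    return EncryptedQuery(
        ciphertexts=ciphertexts,
        constructor=constructor,
        public_key=pk,
        query_magnitude=lsh.magnitude,
    )


def compute_similarity(
    intersection: int, q_mag: int, d_mag: int, entry_id: str = ""
) -> SimilarityScores:
    """IoU/IoQ/IoD from an intersection count and the two magnitudes.

    Raises :class:`IntegrityError` if ``intersection > min(q_mag, d_mag)`` —
    impossible for honestly computed scores, so it is surfaced rather than
    clamped.
    """
    if intersection < 0 or q_mag < 0 or d_mag < 0:
        raise ValueError("intersection and magnitudes must be non-negative")
    if intersection > min(q_mag, d_mag):
        raise IntegrityError(
            f"decrypted intersection {intersection} exceeds min(|Q|={q_mag}, "
            f"|D|={d_mag}); the score pair is inconsistent"
        )
    union = q_mag + d_mag - intersection
    return SimilarityScores(
        entry_id=entry_id,
        intersection=intersection,
        db_magnitude=d_mag,
        iou=intersection / union if union else 0.0,
        ioq=intersection / q_mag if q_mag else 0.0,
        iod=intersection / d_mag if d_mag else 0.0,
    )


def decrypt_scores(
    sk: PrivateKey, pairs: "TSequence[ScorePair]", q_mag: int
) -> list[SimilarityScores]:
    """Decrypt returned score pairs into per-entry similarity metrics.

    One result per database entry, in the owner's entry order.
    """
    results = []
    for pair in pairs:
        inter = sk.decrypt(pair.encrypted_intersection)
        results.append(
            compute_similarity(inter, q_mag, pair.db_magnitude, entry_id=pair.entry_id)
        )
    return results
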