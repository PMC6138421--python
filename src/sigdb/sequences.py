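"""DNA sequence container and FASTA ingest.

Sequences are plain uppercase strings over the alphabet ``{A, C, G, T, X, N}``.
``X`` marks a corrupted base introduced by the mutation simulator and ``N`` the
usual ambiguity code; both are treated as ordinary symbols by the k-mer
hashing downstream, so a degraded base still perturbs exactly the k-mers that
cover it. A strict mode restricts the alphabet to ``{A, C, G, T}`` for callers
that want to reject ambiguous input outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO

from .errors import SequenceError

#: Permissive alphabet: four bases plus the error symbol and ambiguity code.
ALPHABET = frozenset("ACGTXN")
#: Strict alphabet: unambiguous bases only.
STRICT_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class Sequence:
    """An identified DNA sequence.

    Parameters
    ----------
    id:
        Record identifier (for FASTA input, the header token up to the first
        whitespace).
    bases:
        Uppercase string over :data:`ALPHABET`.
    """

    id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError(f"sequence {self.id!r} is empty")

    @classmethod
    def from_string(cls, id: str, bases: str, *, strict: bool = False) -> "Sequence":
        """Build a sequence, uppercasing and validating the alphabet.

        With ``strict=True`` any symbol outside ``{A,C,G,T}`` is rejected;
        otherwise ``X`` and ``N`` are also accepted.
        """
        bases = bases.upper()
        allowed = STRICT_ALPHABET if strict else ALPHABET
        bad = set(bases) - allowed
        if bad:
            raise SequenceError(
                f"sequence {id!r} contains symbols outside the "
                f"{'strict ' if strict else ''}alphabet: {sorted(bad)}"
            )
        return cls(id=id, bases=bases)

    def truncated(self, max_len: int) -> "Sequence":
        """First ``max_len`` bases (the whole sequence if already shorter)."""
        if max_len < 1:
            raise SequenceError("max_len must be >= 1")
        if len(self.bases) <= max_len:
            return self
        return Sequence(id=self.id, bases=self.bases[:max_len])


def read_fasta(path: Union[str, Path], *, strict: bool = False) -> list[Sequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Record order is preserved; the record id is the header token up to the
    first whitespace. Raises :class:`SequenceError` on an empty file.
    """
    records = [
        Sequence.from_string(rec.id, str(rec.seq), strict=strict)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: Union[str, Path], seqs: Iterable[Sequence], width: int = 80) -> None:
    """Write sequences as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i : i + width] + "\n")


def iter_fasta(path: Union[str, Path], *, strict: bool = False) -> Iterator[Sequence]:
    """Stream FASTA records without materialising the whole file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield Sequence.from_string(rec.id, str(rec.seq), strict=strict)
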