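"""Exception hierarchy for the sigdb package."""


class SigDBError(Exception):
    """Base class for all sigdb errors."""


class SequenceError(SigDBError):
    """Invalid sequence input (alphabet, length, empty FASTA, ...)."""


class KeyMismatchError(SigDBError):
    """Operation mixed ciphertexts or keys from different key pairs."""


class DimensionMismatchError(SigDBError):
    """LSH vectors or encrypted queries of incompatible length."""


class IntegrityError(SigDBError):
    """A decrypted value violates a protocol invariant (e.g. an
    intersection count exceeding either party's LSH magnitude)."""


class SchemaError(SigDBError):
    """A serialized artifact has the wrong schema version or is corrupt."""
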