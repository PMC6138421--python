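"""JSON serialization of protocol artifacts.

Every artifact is a JSON object with a ``schema`` tag (refused on mismatch)
and a ``kind`` discriminator. Big integers are lowercase hex strings. The
encrypted-query artifact deliberately omits the query magnitude — that value
stays on the Querier's side.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .db_owner import ScorePair
from .errors import SchemaError
from .lsh import LSHConstructor
from .paillier import Ciphertext, PrivateKey, PublicKey
from .querier import EncryptedQuery

SCHEMA = "sigdb/1"


def _hex(x: int) -> str:
    return format(x, "x")


def _unhex(s: object, what: str) -> int:
    if not isinstance(s, str):
        raise SchemaError(f"{what}: expected a hex string, got {type(s).__name__}")
    try:
        return int(s, 16)
    except ValueError as exc:
        raise SchemaError(f"{what}: corrupt hex string") from exc


def _check_header(obj: dict, kind: str) -> None:
    if not isinstance(obj, dict):
        raise SchemaError(f"expected a JSON object for {kind}")
    if obj.get("schema") != SCHEMA:
        raise SchemaError(
            f"schema tag {obj.get('schema')!r} does not match {SCHEMA!r}; refusing to parse"
        )
    if obj.get("kind") != kind:
        raise SchemaError(f"artifact kind {obj.get('kind')!r}, expected {kind!r}")


# ---------------------------------------------------------------- keys

def public_key_to_dict(pk: PublicKey) -> dict:
    return {"schema": SCHEMA, "kind": "public_key", "key_size": pk.key_size, "n": _hex(pk.n)}


def public_key_from_dict(obj: dict) -> PublicKey:
    _check_header(obj, "public_key")
    return PublicKey(n=_unhex(obj.get("n"), "public_key.n"), key_size=int(obj["key_size"]))


def private_key_to_dict(sk: PrivateKey) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "private_key",
        "key_size": sk.public_key.key_size,
        "n": _hex(sk.public_key.n),
        "p": _hex(sk.p),
        "q": _hex(sk.q),
    }


def private_key_from_dict(obj: dict) -> PrivateKey:
    _check_header(obj, "private_key")
    pk = PublicKey(n=_unhex(obj.get("n"), "private_key.n"), key_size=int(obj["key_size"]))
    return PrivateKey(
        p=_unhex(obj.get("p"), "private_key.p"),
        q=_unhex(obj.get("q"), "private_key.q"),
        public_key=pk,
    )


# ---------------------------------------------------------------- constructor

def constructor_to_dict(c: LSHConstructor) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "lsh_constructor",
        "k": c.k,
        "L": c.L,
        "hash_name": c.hash_name,
        "hash_seed": c.hash_seed,
    }


def constructor_from_dict(obj: dict) -> LSHConstructor:
    _check_header(obj, "lsh_constructor")
    return LSHConstructor(
        k=int(obj["k"]),
        L=int(obj["L"]),
        hash_seed=int(obj["hash_seed"]),
        hash_name=obj["hash_name"],
    )


# ---------------------------------------------------------------- query

def encrypted_query_to_dict(q: EncryptedQuery) -> dict:
    """Owner-facing artifact: ciphertexts + parameters, no plaintext state."""
    return {
        "schema": SCHEMA,
        "kind": "encrypted_query",
        "constructor": constructor_to_dict(q.constructor),
        "public_key": public_key_to_dict(q.public_key),
        "ciphertexts": [_hex(c.value) for c in q.ciphertexts],
    }


def encrypted_query_from_dict(obj: dict) -> EncryptedQuery:
    """Rebuild an encrypted query on the owner side.

    The query magnitude is not part of the artifact; the owner-side object
    carries a sentinel of ``-1`` (it is never used by owner operations).
    """
    _check_header(obj, "encrypted_query")
    pk = public_key_from_dict(obj["public_key"])
    cts = [
        Ciphertext(value=_unhex(s, f"ciphertexts[{i}]"), public_key=pk)
        for i, s in enumerate(obj["ciphertexts"])
    ]
    return EncryptedQuery(
        ciphertexts=cts,
        constructor=constructor_from_dict(obj["constructor"]),
        public_key=pk,
        query_magnitude=-1,
    )


def query_state_to_dict(query_magnitude: int) -> dict:
    """Querier-local state needed later to score decrypted counts."""
    return {"schema": SCHEMA, "kind": "query_state", "query_magnitude": query_magnitude}


def query_state_from_dict(obj: dict) -> int:
    _check_header(obj, "query_state")
    return int(obj["query_magnitude"])


# ---------------------------------------------------------------- score pairs

def score_pairs_to_dict(pairs: list[ScorePair], pk: PublicKey) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "score_pairs",
        "public_key": public_key_to_dict(pk),
        "pairs": [
            {
                "entry_id": p.entry_id,
                "ciphertext": _hex(p.encrypted_intersection.value),
                "db_magnitude": p.db_magnitude,
            }
            for p in pairs
        ],
    }


def score_pairs_from_dict(obj: dict) -> list[ScorePair]:
    _check_header(obj, "score_pairs")
    pk = public_key_from_dict(obj["public_key"])
    return [
        ScorePair(
            entry_id=item["entry_id"],
            encrypted_intersection=Ciphertext(
                value=_unhex(item.get("ciphertext"), f"pairs[{i}].ciphertext"),
                public_key=pk,
            ),
            db_magnitude=int(item["db_magnitude"]),
        )
        for i, item in enumerate(obj["pairs"])
    ]


# ---------------------------------------------------------------- file I/O

def dump_json(obj: dict, path: Union[str, Path]) -> None:
    """Write an artifact with a canonical layout (stable byte-wise)."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n")


def load_json(path: Union[str, Path]) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON") from exc
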