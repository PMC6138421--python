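"""End-to-end protocol orchestration.

Runs the full two-party exchange in order: size the LSH from the owner's
longest (truncated) entry, build and encrypt the query LSH, hash the
database, score every entry homomorphically, decrypt, and compute
IoU/IoQ/IoD per entry. :func:`run_protocol` does this in memory;
:func:`run_exchange` additionally writes each exchanged artifact and the
result TSV to disk, exactly as two real parties would exchange them.

:func:`run_protocol_plaintext` computes the identical result without
encryption (AND/popcount on the two plaintext LSHs). The encrypted and
plaintext paths are interchangeable by construction — the homomorphic sum of
encrypted bits over an entry's filled positions decrypts to the popcount of
the AND — and the test suite holds them to exact equality. Evaluation-scale
experiments use the plaintext path for speed.
"""

from __future__ import annotations

import csv
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import serialization as ser
from .db_owner import build_index, scan_database
from .lsh import DEFAULT_LSH_RATIO, LSHConstructor, build_lsh, intersection, lsh_size_for
from .paillier import DEFAULT_KEY_SIZE, keygen
from .querier import (
    SimilarityScores,
    build_encrypted_query,
    compute_similarity,
    decrypt_scores,
)
from .sequences import Sequence, read_fasta

logger = logging.getLogger("sigdb.protocol")


@dataclass
class ProtocolConfig:
    """Tuned defaults: k=8, 5:1 LSH sizing, 3072-bit keys, 20 kb truncation."""

    k: int = 8
    lsh_ratio: int = DEFAULT_LSH_RATIO
    key_size: int = DEFAULT_KEY_SIZE
    truncate_len: int = 20_000
    hash_seed: int = 0
    sort_results: bool = False  # sort TSV by IoU descending
    rng: Optional[random.Random] = field(default=None, repr=False)  # fixture mode only


def constructor_for(max_seq_len: int, config: ProtocolConfig) -> LSHConstructor:
    """LSH constructor sized by the ratio rule from the owner's longest
    (post-truncation) entry length."""
    eff = min(max_seq_len, config.truncate_len)
    return LSHConstructor(
        k=config.k, L=lsh_size_for(eff, config.lsh_ratio), hash_seed=config.hash_seed
    )


def run_protocol(
    query: Sequence,
    db_records: list[Sequence],
    config: Optional[ProtocolConfig] = None,
) -> list[SimilarityScores]:
    """Full encrypted exchange in memory; one result row per database entry,
    in database order."""
    config = config or ProtocolConfig()
    # Step 1 (owner -> querier): longest entry length, capped at truncation
    max_len = min(max(len(r) for r in db_records), config.truncate_len)
    constructor = constructor_for(max_len, config)
    logger.info("stage=size max_seq_len=%d L=%d", max_len, constructor.L)
    # Steps 2-4 (querier): key pair + encrypted query LSH
    pk, sk = keygen(config.key_size, rng=config.rng)
    enc_query = build_encrypted_query(
        query.truncated(config.truncate_len), constructor, pk, rng=config.rng
    )
    logger.info("stage=encrypt L=%d key_size=%d", enc_query.L, config.key_size)
    # Steps 5-8 (owner): hash database, score every entry
    index = build_index(db_records, constructor, truncate_len=config.truncate_len)
    pairs = scan_database(enc_query, index, rng=config.rng)
    logger.info("stage=scan entries=%d", len(pairs))
    # Steps 9-10 (querier): decrypt and score
    return decrypt_scores(sk, pairs, enc_query.query_magnitude)


def run_protocol_plaintext(
    query: Sequence,
    db_records: list[Sequence],
    config: Optional[ProtocolConfig] = None,
) -> list[SimilarityScores]:
    """Same result as :func:`run_protocol`, computed without encryption."""
    config = config or ProtocolConfig()
    max_len = min(max(len(r) for r in db_records), config.truncate_len)
    constructor = constructor_for(max_len, config)
    q_lsh = build_lsh(query.truncated(config.truncate_len), constructor)
    results = []
    for rec in db_records:
        d_lsh = build_lsh(rec.truncated(config.truncate_len), constructor)
        inter = intersection(q_lsh, d_lsh)
        results.append(
            compute_similarity(inter, q_lsh.magnitude, d_lsh.magnitude, entry_id=rec.id)
        )
    return results


def write_results_tsv(
    results: list[SimilarityScores], path: Union[str, Path], sort: bool = False
) -> None:
    """Result table: entry_id, db_magnitude, intersection, IoU, IoQ, IoD."""
    rows = sorted(results, key=lambda r: -r.iou) if sort else results
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["entry_id", "db_magnitude", "intersection", "iou", "ioq", "iod"])
        for r in rows:
            w.writerow(
                [r.entry_id, r.db_magnitude, r.intersection,
                 repr(r.iou), repr(r.ioq), repr(r.iod)]
            )


def run_exchange(
    query_fasta: Union[str, Path],
    db_fasta: Union[str, Path],
    config: Optional[ProtocolConfig] = None,
    outdir: Union[str, Path] = ".",
) -> Path:
    """File-based exchange: write every artifact a real two-party run would
    pass across the trust boundary, plus the final TSV. Returns the TSV path.

    Artifacts written under ``outdir``: ``public_key.json``,
    ``private_key.json`` (querier-local), ``constructor.json``,
    ``encrypted_query.json``, ``query_state.json`` (querier-local),
    ``score_pairs.json``, ``results.tsv``.
    """
    config = config or ProtocolConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    query = read_fasta(query_fasta)[0]
    db_records = read_fasta(db_fasta)
    max_len = min(max(len(r) for r in db_records), config.truncate_len)
    constructor = constructor_for(max_len, config)
    logger.info("stage=size max_seq_len=%d L=%d", max_len, constructor.L)
    ser.dump_json(ser.constructor_to_dict(constructor), outdir / "constructor.json")

    pk, sk = keygen(config.key_size, rng=config.rng)
    ser.dump_json(ser.public_key_to_dict(pk), outdir / "public_key.json")
    ser.dump_json(ser.private_key_to_dict(sk), outdir / "private_key.json")

    enc_query = build_encrypted_query(
        query.truncated(config.truncate_len), constructor, pk, rng=config.rng
    )
    logger.info("stage=encrypt L=%d key_size=%d", enc_query.L, config.key_size)
    ser.dump_json(ser.encrypted_query_to_dict(enc_query), outdir / "encrypted_query.json")
    ser.dump_json(
        ser.query_state_to_dict(enc_query.query_magnitude), outdir / "query_state.json"
    )

    # Owner side works purely from the exchanged artifacts.
    owner_query = ser.encrypted_query_from_dict(
        ser.load_json(outdir / "encrypted_query.json")
    )
    index = build_index(db_records, constructor, truncate_len=config.truncate_len)
    pairs = scan_database(owner_query, index, rng=config.rng)
    logger.info("stage=scan entries=%d", len(pairs))
    ser.dump_json(ser.score_pairs_to_dict(pairs, pk), outdir / "score_pairs.json")

    returned = ser.score_pairs_from_dict(ser.load_json(outdir / "score_pairs.json"))
    q_mag = ser.query_state_from_dict(ser.load_json(outdir / "query_state.json"))
    results = decrypt_scores(sk, returned, q_mag)
    logger.info("stage=decrypt entries=%d", len(results))

    tsv_path = outdir / "results.tsv"
    write_results_tsv(results, tsv_path, sort=config.sort_results)
    return tsv_path
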