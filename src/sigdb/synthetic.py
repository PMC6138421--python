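"""Synthetic sequence fixtures.

Generates everything the test surface needs without any download: i.i.d.
random genomes with a configurable GC fraction, prefix queries, and the
two-genome classifier-evaluation dataset (non-overlapping database entries
plus wild-type and Bernoulli-mutated queries).

Random genomes carry no repeat structure, codon bias or strand asymmetry, so
they emulate the combinatorial statistics of real bacterial sequence (k-mer
occupancy, hash collision rates) but not its repeat-driven quirks. All
fixtures are byte-for-byte reproducible from ``(seed, parameters)``, and the
FASTA writer embeds the generator parameters in headers for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence as TSeq, Union

import numpy as np

from .errors import SequenceError
from .mutation import mutate_bernoulli
from .sequences import Sequence, write_fasta


def random_genome(
    length: int,
    gc_content: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    id: str = "synthetic_genome",
) -> Sequence:
    """I.i.d. random DNA of the given length and expected GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError(f"gc_content {gc_content} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return Sequence(id=id, bases="".join(bases))


def prefix_query(seq: Sequence, prefix_len: int) -> Sequence:
    """First ``prefix_len`` bases of ``seq`` as a new query record."""
    if prefix_len < 1:
        raise ValueError("prefix_len must be >= 1")
    if prefix_len > len(seq):
        raise SequenceError(
            f"prefix_len {prefix_len} exceeds sequence length {len(seq)}"
        )
    return Sequence(id=f"{seq.id}_prefix{prefix_len}", bases=seq.bases[:prefix_len])


def sample_nonoverlapping(
    genome_len: int, n: int, entry_len: int, rng: np.random.Generator
) -> list[int]:
    """Start coordinates of ``n`` pairwise non-overlapping windows of
    ``entry_len`` bases, uniform over all valid configurations.

    Uses the spacing transform: draw ``n`` points in the slack space
    ``[0, genome_len - n * entry_len]``, sort them, and shift the i-th by
    ``i * entry_len``. Unlike naive rejection sampling this cannot jam at
    high occupancy (e.g. windows covering 75% of the genome). Returned
    starts are in random order.
    """
    slack = genome_len - n * entry_len
    if slack < 0:
        raise SequenceError(
            f"cannot place {n} non-overlapping windows of {entry_len} bases in a "
            f"{genome_len}-base genome"
        )
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    starts = gaps + np.arange(n) * entry_len
    return [int(s) for s in rng.permutation(starts)]


@dataclass
class LengthSet:
    """One classifier-evaluation length set: entries + 3x queries."""

    entry_len: int
    entries: list[Sequence]
    #: (query, source_entry_id, mutation probability; 0.0 = wild type)
    queries: list[tuple[Sequence, str, float]]


@dataclass
class CorrectnessDataset:
    genomes: list[Sequence]
    sets: dict[int, LengthSet]
    params: dict = field(default_factory=dict)


def correctness_dataset(
    genome_len: int = 100_000,
    n_genomes: int = 2,
    entry_lens: TSeq[int] = (1000, 2000, 3000),
    entries_per_set: int = 50,
    query_len: int = 1000,
    mutation_probs: TSeq[float] = (0.05, 0.10),
    gc_content: float = 0.5,
    seed: int = 0,
) -> CorrectnessDataset:
    """Build the two-genome classifier-evaluation dataset.

    Per entry length, ``entries_per_set`` non-overlapping entries are sampled
    in total, split evenly across the genomes. From each entry one
    ``query_len``-base wild-type query is cut at a random offset, then
    duplicated once per mutation probability with per-base Bernoulli
    mutation — so each length set has ``(1 + len(mutation_probs)) *
    entries_per_set`` queries, searched only against its own set.
    """
    if entries_per_set % n_genomes:
        raise ValueError("entries_per_set must divide evenly across the genomes")
    per_genome = entries_per_set // n_genomes
    if genome_len < per_genome * max(entry_lens):
        raise SequenceError(
            f"genome_len {genome_len} cannot host {per_genome} non-overlapping "
            f"entries of {max(entry_lens)} bases"
        )
    rng = np.random.default_rng(seed)
    genomes = [
        random_genome(genome_len, gc_content, rng=rng, id=f"genome{g}")
        for g in range(n_genomes)
    ]
    sets: dict[int, LengthSet] = {}
    for entry_len in entry_lens:
        entries: list[Sequence] = []
        queries: list[tuple[Sequence, str, float]] = []
        for genome in genomes:
            starts = sample_nonoverlapping(genome_len, per_genome, entry_len, rng)
            for s in starts:
                eid = f"{genome.id}_len{entry_len}_at{s}"
                entry = Sequence(id=eid, bases=genome.bases[s : s + entry_len])
                entries.append(entry)
                q_off = int(rng.integers(0, entry_len - query_len + 1))
                wt = Sequence(
                    id=f"{eid}_q{q_off}", bases=entry.bases[q_off : q_off + query_len]
                )
                queries.append((wt, eid, 0.0))
                for p in mutation_probs:
                    mut_seed = int(rng.integers(0, 2**31 - 1))
                    queries.append((mutate_bernoulli(wt, p, mut_seed), eid, p))
        sets[entry_len] = LengthSet(entry_len=entry_len, entries=entries, queries=queries)
    params = {
        "genome_len": genome_len,
        "n_genomes": n_genomes,
        "entry_lens": list(entry_lens),
        "entries_per_set": entries_per_set,
        "query_len": query_len,
        "mutation_probs": list(mutation_probs),
        "gc_content": gc_content,
        "seed": seed,
    }
    return CorrectnessDataset(genomes=genomes, sets=sets, params=params)


def write_correctness_fixtures(
    dataset: CorrectnessDataset, outdir: Union[str, Path]
) -> Path:
    """Write per-length-set entry/query FASTA files plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"params": dataset.params, "files": []}
    header = "|".join(f"{k}={v}" for k, v in dataset.params.items())
    for entry_len, ls in dataset.sets.items():
        db_path = outdir / f"db_len{entry_len}.fasta"
        q_path = outdir / f"queries_len{entry_len}.fasta"
        write_fasta(db_path, [Sequence(id=f"{e.id} {header}", bases=e.bases) for e in ls.entries])
        write_fasta(
            q_path,
            [Sequence(id=f"{q.id} source={src}|p={p:g}|{header}", bases=q.bases)
             for q, src, p in ls.queries],
        )
        manifest["files"].append(
            {"entry_len": entry_len, "db": db_path.name, "queries": q_path.name,
             "n_entries": len(ls.entries), "n_queries": len(ls.queries)}
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir / "manifest.json"
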