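# Methods

## Protocol model

`sigdb` implements a two-party secure similarity search. The Querier holds a
secret DNA sequence; the Database Owner holds an ordered collection of
sequences. The exchanged objects are: the LSH constructor (k-mer length *k*,
LSH length *L*, hash seed), the Paillier public key, the element-wise
encrypted query LSH, and per-entry score pairs {encrypted intersection
count, plaintext entry-LSH magnitude}. The trust boundary is the serialized
JSON artifacts; both roles are shipped in one package and
`run_exchange` replays the full file-level exchange locally.

What each side learns, by construction: the owner learns only the LSH
parameters and an IND-CPA-secure ciphertext vector; the querier learns the
number of entries, each entry's LSH magnitude, and the intersection counts —
nothing else about entry content. The scan-all contract (every entry scored
on every query, enforced in `scan_database` and audited by an
instrumentation hook) prevents the timing side channel in which an early
exit would reveal which entry matched.

## K-mer window convention

A length-*n* sequence yields **n − k** windows, at offsets 0 … n−k−1; the
final base never starts a window. A step-1 window can equally be counted as
n−k+1; the n−k convention is adopted because all of the package's sizing
arithmetic is stated in those terms (a 20,000-base sequence → 19,992
8-mers), and the difference of one window is far below every tolerance in
use. Sequences with length ≤ k are rejected explicitly rather than returning
an empty window list.

## Hash function

K-mers are hashed with keyed BLAKE2b (8-byte digest, key = the 64-bit
`hash_seed`), reduced mod *L*. Requirements driving this choice: stability
across processes, runs and platforms (both parties must build identical
maps — a language runtime's built-in string hash is salted per process and
unusable here), seedability, and near-uniform dispersion (verified by a
χ² occupancy test at α = 0.001). The seed travels inside the serialized
constructor.

## LSH sizing and collision analytics

*L* = ratio × (longest entry length after truncation), default ratio 5:1.
Sequences longer than `truncate_len` (default 20,000 bases) contribute only
their first `truncate_len` bases, on both sides. At 5:1 the probability that
a given k-mer shares its position with at least one of the other n−1 k-mers
is 1 − (1 − 1/L)^(n−1) ≈ 18.1% for n = 20,000, L = 100,000; the closed form
assumes uniform placement and is checked against simulated hashings (±1
percentage point). Larger *L* lowers the collision (false-match) floor at
linear cost in encryption and scoring work.

## Paillier implementation

Implemented from scratch on Python integers (`sigdb.paillier`): Miller-Rabin
prime generation (40 rounds), *g* = n+1 so that g^m = 1 + mn (mod n²),
encryption c = (1+mn)·r^n mod n², decryption via λ = lcm(p−1, q−1) and
μ = λ⁻¹ mod n. Supported modulus sizes: 512/1024 (tests only — factorable;
never for real data) and 2048/3072/4096, default 3072 (~128-bit security).
Encryption randomness r is drawn from the OS CSPRNG; a clearly-labelled
deterministic mode (a seeded `random.Random` passed as `rng`) exists only so
regression fixtures can be byte-reproducible. Homomorphic addition is
ciphertext multiplication mod n²; the owner seeds each per-entry sum with a
fresh encryption of zero so every returned ciphertext is re-randomized, and
an empty entry still returns a valid ciphertext.

All *L* positions of the query LSH are encrypted, zeros included: leaving
zeros in the clear would hand the owner the query's k-mer positions
directly.

## Similarity metrics and integrity

IoU = I/(|Q|+|D|−I), IoQ = I/|Q|, IoD = I/|D|. A metric whose denominator is
zero is defined as 0 (keeps IoU ≤ min(IoQ, IoD) everywhere and avoids
undefined division for pathological inputs). A decrypted intersection
exceeding min(|Q|, |D|) cannot arise from an honest exchange, so it raises
an `IntegrityError` instead of being clamped silently. Scores are kept at
full float precision; tabulated comparisons round half-up to 2 decimals.

## Mutation simulator

Two mechanisms, selected per experiment:

* **Fixed-count** (`mutate_uniform`, `mutate_localized`): exactly
  round(p·n) positions, chosen without replacement — uniformly over the
  whole sequence, or confined to the second half ("localized", p ≤ 0.5, so
  p = 0.5 rewrites the second half completely while the first half remains a
  perfect match; which half is mutated is a convention, fixed to the second).
  Replacement is uniform over the 3 alternative bases plus `'X'` (a
  data-error symbol); a mutated position never keeps its original symbol.
* **Per-base Bernoulli** (`mutate_bernoulli`): each base independently
  mutated with probability p to one of the 3 alternative bases (no `'X'`);
  this is the mechanism of the classifier experiment, where mutation is
  defined as switching to an alternate base.

Fixed counts use round-half-up; the choice between floor and round is
immaterial at the rates used but is pinned for reproducibility.

## ANI ground truth

ANI is computed as the identity of the pairwise alignment over the aligned
region: the shorter sequence is aligned end-to-end within the longer
(semi-global / infix alignment, edlib), identity = matched columns /
alignment length, and the two comparison directions are averaged (for this
alignment mode they coincide, which is what bidirectional ANI reduces to
for a single pair). Identity over the aligned region — not an end-to-end
global alignment of both sequences — is essential: a 1,000-base query cut
verbatim from a 3,000-base entry has nucleotide identity 1.0, while an
end-to-end global alignment would report ≈ 0.33 and destroy the ground
truth for every unequal-length pair. Which published ANI variant is "the"
reference is genuinely open; this definition is the package's stand-in and
is stated as such.

## ROC construction

Classification thresholds start at 0 (everything "relevant") and then take
each unique similarity score in ascending order; a pair is relevant when
score ≥ threshold. TPR/FPR are computed per threshold and AUC is the
trapezoidal area after closing the curve at (0, 0). The construction is
cross-checked against scikit-learn's `roc_auc_score` in the tests.

## Classifier experiment (scaled)

Two unrelated random 100-kb genomes stand in for two bacterial genomes. Per
entry length {1000, 2000, 3000}: 50 non-overlapping entries in total (25 per
genome), each contributing one 1,000-base wild-type query cut at a random
offset plus two Bernoulli-mutated copies (p = 0.05 and 0.10) — 150 queries
per set, compared only within their own set, with *L* sized 5:1 for that
set's entry length. Scores are max(IoU, IoQ, IoD), absorbing query/entry
length differences; labels are ANI ≥ τ for τ ∈ {0.95, 0.99}. The scaled
sizes (50/150 instead of 500/1,500) keep the experiment desk-scale at ~35 s;
full scale is reachable through the same function's parameters.
Non-overlapping entry placement uses the spacing transform (draw n points in
the slack space, sort, shift the i-th by i·entry_len), which samples
uniformly over valid configurations and — unlike naive rejection sampling —
cannot jam even at the 75% genome occupancy the 3,000-base set requires.

Experiment-scale scoring runs through the plaintext LSH path
(`run_protocol_plaintext`), which is exactly equal to the encrypted path —
the homomorphic sum over an entry's filled positions decrypts to the
popcount of the AND of the two bit vectors — and the test suite enforces
that equality pairwise against an independent set-intersection oracle. The
encrypted path itself is exercised end-to-end at production LSH size
(L = 100,000) with a 512-bit test key.

## Synthetic data: what it does and does not emulate

`random_genome` draws i.i.d. bases at a configurable GC fraction (default
0.5). This reproduces the combinatorial statistics that drive the protocol —
distinct-k-mer occupancy (≈ 65,536·(1 − (1 − 1/65,536)^(n−k)) distinct
8-mers), hash-collision rates, prefix-query containment — but not the
repeat structure, codon bias or strand asymmetry of real genomes. Real
bacterial sequence has more repeated 8-mers, so LSH magnitudes run a few
percent lower and prefix-query IoU values shift by up to ~0.03 relative to
the synthetic expectation; passing tests on synthetic data therefore
validate the protocol arithmetic, not organism-specific score tables.
Reverse complements are not canonicalized: a query only matches the strand
as stored.

## Numerical and degenerate-input choices

* Zero-denominator metrics → 0 (above); negative inputs rejected.
* `compute_similarity` validates I ≤ min(|Q|, |D|) (integrity, not clamp).
* FASTA records shorter than k+1 bases are an error at indexing time.
* Entry ids are the FASTA header token up to the first whitespace; entry
  order is FASTA order and is preserved end-to-end.
* Serialized artifacts carry a schema tag (`sigdb/1`) and big integers as
  lowercase hex; any tag mismatch or corrupt hex is a refusal, not a silent
  re-interpretation.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
one fully encrypted identity run at L = 100,000 (512-bit test key), 10
replicate genomes for each prefix-query average, 100 query–entry pairs for
the encrypted-vs-plaintext equality check (L = 500), 1,000 random pairs for
homomorphic-addition correctness, 20 seeds per mutation rate for the
degradation monotonicity checks, and the 50-entry/150-query classifier
experiment described above. These sizes were chosen so the whole surface
re-runs comfortably on a single CPU while keeping every statistical
tolerance far above its sampling noise.

## Known limitations

* Legitimate metadata leakage is inherent to the design: the querier learns
  the database size and per-entry LSH magnitudes (hence rough entry
  lengths). A fully homomorphic variant could hide magnitudes at much higher
  cost; it is out of scope here.
* No formal security analysis, side-channel hardening, network transport or
  authentication: parties exchange files and are assumed willing.
* Pure-Python Paillier is the performance floor: ~2 ms per encryption at
  test key sizes, ~100× slower at 3072 bits. Scoring is Θ(total set bits)
  per query; parallelization is out of scope.
* Indels and rearrangements are not modelled by the mutation simulator;
  k-mer hashing is naturally robust to large rearrangements but every
  substitution disrupts up to k windows.
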