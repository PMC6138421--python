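"""Ground-truth similarity, ROC construction and the classifier experiment.

Treats the similarity search as a binary classifier: a query–entry pair is
"truly similar" when its average nucleotide identity (ANI) clears a
threshold (0.95 or 0.99), and the predicted score is ``max(IoU, IoQ, IoD)``
(the maximum absorbs query/entry length differences). The ROC is built by
sweeping a score threshold from 0 upward through every unique score, calling
a pair "relevant" when ``score >= threshold``.

ANI here is the identity of the pairwise alignment computed over the aligned
region: the shorter sequence is aligned end-to-end inside the longer
(semi-global, via edlib) and identity = matches / alignment length. Both
directions of the pair are computed and averaged (they coincide for this
alignment mode, which is what "bidirectional" ANI reduces to for a
two-sequence comparison). Identity over the aligned region — rather than an
end-to-end global alignment of both sequences — is what makes a 1,000-base
query cut from a 3,000-base entry score ANI ~ 1.0, as a nucleotide-identity
ground truth must.

The classifier experiment scores pairs through the plaintext LSH path, which
is exactly equal to the encrypted protocol output (held to equality in the
test suite) at a fraction of the cost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence as TSeq

import edlib
import numpy as np

from .lsh import LSHConstructor, build_lsh, intersection, lsh_size_for
from .querier import compute_similarity
from .sequences import Sequence
from .synthetic import CorrectnessDataset, correctness_dataset

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _identity(a: str, b: str) -> float:
    """Alignment identity of the shorter string inside the longer."""
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    matches = aln_len = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        aln_len += int(count)
        if op == "=":
            matches += int(count)
    return matches / aln_len if aln_len else 0.0


def ani(seq_a: Sequence, seq_b: Sequence) -> float:
    """Average nucleotide identity of two sequences, in [0, 1].

    Mean of the two comparison directions; see the module docstring for the
    alignment convention.
    """
    if not len(seq_a) or not len(seq_b):
        raise ValueError("ANI requires two non-empty sequences")
    return 0.5 * (_identity(seq_a.bases, seq_b.bases) + _identity(seq_b.bases, seq_a.bases))


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    n_relevant: int
    tpr: float
    fpr: float


def roc_curve(scores: TSeq[float], labels: TSeq[bool]) -> list[RocPoint]:
    """ROC points for the threshold sweep 0, then each unique score ascending.

    At each threshold a pair is "relevant" when ``score >= threshold``;
    TPR/FPR are computed against the boolean labels. Requires at least one
    positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equally long")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    thresholds = [0.0] + sorted(set(scores.tolist()) - {0.0})
    points = []
    for t in thresholds:
        relevant = scores >= t
        tp = int((relevant & labels).sum())
        fp = int((relevant & ~labels).sum())
        points.append(
            RocPoint(
                threshold=t,
                n_relevant=int(relevant.sum()),
                tpr=tp / n_pos,
                fpr=fp / n_neg,
            )
        )
    return points


def auc(scores: TSeq[float], labels: TSeq[bool]) -> float:
    """Trapezoidal area under the ROC curve, in [0, 1].

    The sweep's lowest threshold (0) contributes the all-relevant point
    (FPR=1, TPR=1); the curve is closed at (0, 0) for the integration.
    """
    points = roc_curve(scores, labels)
    fpr = np.array([0.0] + [p.fpr for p in reversed(points)])
    tpr = np.array([0.0] + [p.tpr for p in reversed(points)])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def sigdb_score(query: Sequence, entry: Sequence, constructor: LSHConstructor) -> float:
    """``max(IoU, IoQ, IoD)`` for one pair via the plaintext LSH path."""
    q = build_lsh(query, constructor)
    d = build_lsh(entry, constructor)
    s = compute_similarity(intersection(q, d), q.magnitude, d.magnitude)
    return max(s.iou, s.ioq, s.iod)


@dataclass
class LengthSetResult:
    entry_len: int
    auc_by_tau: dict[float, float]
    n_pos_by_tau: dict[float, int]
    n_comparisons: int


def correctness_experiment(
    dataset: CorrectnessDataset | None = None,
    taus: TSeq[float] = (0.95, 0.99),
    k: int = 8,
    lsh_ratio: int = 5,
    hash_seed: int = 0,
    seed: int = 0,
    **dataset_kwargs,
) -> dict[int, LengthSetResult]:
    """Classifier replication: AUROC per entry-length set and ANI threshold.

    For every query–entry pair within a length set, computes alignment ANI
    (ground truth) and the LSH similarity ``max(IoU, IoQ, IoD)``; labels
    pairs by ``ANI >= tau`` and reports the threshold-sweep AUROC. Queries
    are compared only against entries of their own length set, each set's
    LSH being sized by the ratio rule for its entry length.

    Pass a prebuilt :class:`~sigdb.synthetic.CorrectnessDataset` or let one
    be generated from ``seed`` and ``dataset_kwargs``.
    """
    if dataset is None:
        dataset = correctness_dataset(seed=seed, **dataset_kwargs)
    results: dict[int, LengthSetResult] = {}
    for entry_len, ls in dataset.sets.items():
        constructor = LSHConstructor(
            k=k, L=lsh_size_for(entry_len, lsh_ratio), hash_seed=hash_seed
        )
        entry_lshs = [(e, build_lsh(e, constructor)) for e in ls.entries]
        scores: list[float] = []
        anis: list[float] = []
        for query, _src, _p in ls.queries:
            q_lsh = build_lsh(query, constructor)
            for entry, d_lsh in entry_lshs:
                s = compute_similarity(
                    intersection(q_lsh, d_lsh), q_lsh.magnitude, d_lsh.magnitude
                )
                scores.append(max(s.iou, s.ioq, s.iod))
                anis.append(ani(query, entry))
        anis_arr = np.asarray(anis)
        auc_by_tau = {}
        n_pos_by_tau = {}
        for tau in taus:
            labels = anis_arr >= tau
            auc_by_tau[tau] = auc(scores, labels)
            n_pos_by_tau[tau] = int(labels.sum())
        results[entry_len] = LengthSetResult(
            entry_len=entry_len,
            auc_by_tau=auc_by_tau,
            n_pos_by_tau=n_pos_by_tau,
            n_comparisons=len(scores),
        )
    return results
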