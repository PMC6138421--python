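"""In-silico point mutation of query sequences.

Models point mutations and sequencing errors: a mutated base becomes one of
the three alternative bases or ``'X'`` (a data-error symbol), so a mutated
position never retains its original symbol. Three sampling modes:

* :func:`mutate_uniform` — a fixed count ``round(p * n)`` of positions chosen
  uniformly across the whole sequence (used in the rate-sweep experiments);
* :func:`mutate_localized` — the same fixed count, confined to the second
  half of the sequence, so ``p = 0.5`` fully rewrites that half while the
  first half stays a perfect match;
* :func:`mutate_bernoulli` — each base mutated independently with
  probability ``p`` to one of the three alternative bases (the
  classifier-evaluation mechanism; no ``'X'``, matching mutation to an
  alternate base only).
"""

from __future__ import annotations

import numpy as np

from .errors import SequenceError
from .sequences import Sequence

_BASES = "ACGT"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _replacement(rng: np.random.Generator, original: str, include_x: bool) -> str:
    choices = [b for b in _BASES if b != original]
    if include_x:
        choices.append("X")
    return choices[rng.integers(len(choices))]


def _mutate_at(
    seq: Sequence, positions: np.ndarray, rng: np.random.Generator, include_x: bool, tag: str
) -> Sequence:
    bases = list(seq.bases)
    for pos in positions:
        bases[pos] = _replacement(rng, bases[pos], include_x)
    return Sequence(id=f"{seq.id}{tag}", bases="".join(bases))


def mutate_uniform(seq: Sequence, p: float, seed: int) -> Sequence:
    """Mutate exactly ``round(p * n)`` positions, drawn uniformly without
    replacement across the whole sequence; 0 <= p <= 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mutation rate {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(seq)
    count = _round_half_up(p * n)
    positions = rng.choice(n, size=count, replace=False)
    return _mutate_at(seq, positions, rng, include_x=True, tag=f"_mut{p:g}")


def mutate_localized(seq: Sequence, p: float, seed: int) -> Sequence:
    """Mutate ``round(p * n)`` positions, all within the second half.

    ``p`` is still a fraction of the *total* length, so it is capped at 0.5:
    at ``p = 0.5`` the second half is fully mutated and the first half is an
    exact match to the original.
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError(
            f"localized mutation rate {p} outside [0, 0.5]; all mutations must fit "
            f"in one half of the sequence"
        )
    rng = np.random.default_rng(seed)
    n = len(seq)
    half = n // 2
    count = _round_half_up(p * n)
    if count > n - half:
        raise SequenceError(f"{count} mutations do not fit in the second half ({n - half} bases)")
    positions = half + rng.choice(n - half, size=count, replace=False)
    return _mutate_at(seq, positions, rng, include_x=True, tag=f"_locmut{p:g}")


def mutate_bernoulli(seq: Sequence, p: float, seed: int) -> Sequence:
    """Mutate each base independently with probability ``p`` to one of the
    three alternative bases; 0 <= p <= 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mutation probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.flatnonzero(rng.random(len(seq)) < p)
    return _mutate_at(seq, positions, rng, include_x=False, tag=f"_bern{p:g}")
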