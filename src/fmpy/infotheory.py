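"""Information-theoretic measures of choice uncertainty.

A binary choice sequence that departs from randomness carries less than one
bit per choice. The Shannon uncertainty of an n-gram distribution,

    L = −Σ_i p_i log2 p_i   (bits),

is maximal, L_max = log2(#outcomes) = n bits, when every n-gram is equally
likely. The relative complement 1 − L/L_max measures departure from
randomness on [0, 1]: 0 for a fully random sequence, 1 for a fully
determined one. The tetragram-order information

    L4 = L(tetragram) − L(trigram)

is the conditional uncertainty of one turn given the previous three: 1 bit
for an iid fair chooser, 0 when the fourth turn is fully determined by the
preceding trigram (e.g. strict alternation).

Distributions are plug-in estimates from overlapping windows; no
small-sample bias correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import TurnSequence, ValidationError

__all__ = [
    "ChoiceDistribution",
    "UncertaintyResult",
    "ngram_distribution",
    "uncertainty",
    "relative_complement",
    "order_information",
    "uncertainty_summary",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ChoiceDistribution:
    """A probability distribution over n-grams of a fixed order."""

    probabilities: dict[str, float]
    order: int

    def __post_init__(self) -> None:
        probs = np.array(list(self.probabilities.values()), dtype=float)
        if probs.size == 0:
            raise ValidationError("empty distribution")
        if (probs < 0).any():
            raise ValidationError("negative probability")
        if abs(probs.sum() - 1.0) > _SUM_TOL:
            raise ValidationError(f"probabilities sum to {probs.sum():.12g}, not 1")

    @property
    def l_max(self) -> float:
        """Maximum uncertainty at this order: log2 of the outcome count (2^order)."""
        return float(self.order)


@dataclass(frozen=True)
class UncertaintyResult:
    """Tetragram-order uncertainty metrics for one subject."""

    L: float
    L_max: float
    relative_complement: float
    L4: float


def ngram_distribution(seq: TurnSequence | str, order: int) -> ChoiceDistribution:
    """Empirical n-gram distribution from overlapping windows of a sequence."""
    turns = seq.turns if isinstance(seq, TurnSequence) else seq
    if order < 1:
        raise ValidationError("order must be >= 1")
    n_windows = len(turns) - order + 1
    if n_windows < 1:
        raise ValidationError(f"need at least {order} turns to estimate order-{order} n-grams")
    counts: dict[str, int] = {}
    for i in range(n_windows):
        g = turns[i : i + order]
        counts[g] = counts.get(g, 0) + 1
    return ChoiceDistribution({g: c / n_windows for g, c in counts.items()}, order)


def uncertainty(dist: ChoiceDistribution) -> float:
    """Shannon uncertainty −Σ p log2 p in bits; zero-probability terms contribute 0."""
    probs = np.array([p for p in dist.probabilities.values() if p > 0], dtype=float)
    return float(-(probs * np.log2(probs)).sum())


def relative_complement(L: float, L_max: float) -> float:
    """Departure from randomness, 1 − L/L_max ∈ [0, 1]."""
    if L_max <= 0:
        raise ValidationError("L_max must be positive")
    if not (0.0 <= L <= L_max + _SUM_TOL):
        raise ValidationError(f"L={L:g} outside [0, L_max={L_max:g}]")
    return 1.0 - L / L_max

def order_information(seq: TurnSequence | str) -> float:
    """Tetragram-order information L4 = L(tetragram) − L(trigram), in bits.

    The conditional uncertainty of one turn given the three before it;
    bounded by [0, 1] for a binary alphabet. Requires >= 4 turns.

    The trigram distribution is estimated from the prefixes of the same
    windows that feed the tetragram distribution (i.e. trigrams of the
    sequence minus its last turn), so the difference is an exact empirical
    conditional entropy and the [0, 1] bounds hold for every finite
    sequence; with all trigram windows the plug-in difference can stray
    outside them on short inputs. The two estimates coincide as the
    sequence grows.
    """
    turns = seq.turns if isinstance(seq, TurnSequence) else seq
    if len(turns) < 4:
        raise ValidationError("order_information needs at least 4 turns")
    h4 = uncertainty(ngram_distribution(turns, 4))
    h3 = uncertainty(ngram_distribution(turns[:-1], 3))
    return h4 - h3


def uncertainty_summary(seq: TurnSequence | str) -> UncertaintyResult:
    """Tetragram-order uncertainty L, its maximum (4 bits), the relative
    complement 1 − L/4 and the order information L4 for one sequence."""
    h4 = uncertainty(ngram_distribution(seq, 4))
    return UncertaintyResult(
        L=h4,
        L_max=4.0,
        relative_complement=relative_complement(h4, 4.0),
        L4=order_information(seq),
    )
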