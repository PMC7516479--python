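"""The three earliness criteria evaluated at a split point.

For a split point n the structured model keeps only the (prefix, suffix)
and (prefix, class) dependencies.  Its effective dimension counts the free
parameters of the (prefix, class) table built from observed support sizes:

    dim(n) = ||A_n|| * ||C|| - 1

where ``||A_n||`` is the number of distinct observed prefix configurations
and ``||C||`` the number of classes.  The penalized-likelihood criteria are

    MDL(n) = (log2 N / 2) * dim(n) - LL(n)      (BIC-style, bits)
    AIC(n) = dim(n) - LL(n)                     (1 bit per parameter)

with LL the structured log-likelihood in bits.  The conditional-entropy
criterion (CH-70 at its default threshold) accepts the split when the gap
H(C|A_n) - H(C|A,B) has fallen to at most ``rho`` (default 0.3) of its
n = 1 baseline — i.e. at least a 70% reduction — and scores an accepted
split as n itself and a rejected one as +inf, so that minimizing the score
yields the earliest accepted split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dataset_io import DiscreteTimeSeriesDataset
from .empirical_model import (
    ConfigurationCounts,
    conditional_entropy,
    count_configurations,
    structured_log_likelihood,
)

__all__ = [
    "StructureScore",
    "ScoreCurve",
    "model_dimension",
    "mdl_score",
    "aic_score",
    "ch70_score",
]

CRITERIA = ("ch70", "mdl", "aic")


@dataclass(frozen=True)
class StructureScore:
    """One criterion evaluated at one split point.

    For the penalized-likelihood criteria ``value = penalty - ll`` exactly.
    For the conditional-entropy criterion ``value`` is n when accepted and
    +inf when rejected; ``gap`` holds the entropy gap at n.
    """

    n: int
    criterion: str
    value: float
    ll: float
    penalty: float
    dimension: int
    gap: float | None = None


@dataclass
class ScoreCurve:
    """Scores of one criterion at every split point n = 1..L."""

    criterion: str
    scores: list[StructureScore]

    def values(self) -> list[float]:
        return [s.value for s in self.scores]

    def argmin(self, tie: str = "earliest") -> int:
        """Split point minimizing the criterion; ties broken as requested."""
        if tie not in ("earliest", "latest"):
            raise ValueError("tie must be 'earliest' or 'latest'")
        best = None
        best_n = None
        for s in self.scores:
            if best is None or s.value < best or (
                tie == "latest" and s.value == best
            ):
                best, best_n = s.value, s.n
        return best_n


def model_dimension(counts: ConfigurationCounts) -> int:
    """Number of free parameters charged to the model: ||A_n||*||C|| - 1."""
    return counts.support_a * counts.n_classes - 1


def _gap(counts: ConfigurationCounts) -> float:
    return conditional_entropy(counts, "C", "A") - conditional_entropy(
        counts, "C", "AB"
    )


def mdl_score(data: DiscreteTimeSeriesDataset, n: int) -> StructureScore:
    """MDL/BIC score at split n: (log2 N / 2) * dim - LL, in bits."""
    counts = count_configurations(data, n)
    ll = structured_log_likelihood(counts)
    dim = model_dimension(counts)
    penalty = 0.5 * math.log2(counts.N) * dim
    return StructureScore(
        n=n, criterion="mdl", value=penalty - ll, ll=ll, penalty=penalty,
        dimension=dim,
    )


def aic_score(data: DiscreteTimeSeriesDataset, n: int) -> StructureScore:
    """AIC score at split n: dim - LL, charging 1 bit per parameter."""
    counts = count_configurations(data, n)
    ll = structured_log_likelihood(counts)
    dim = model_dimension(counts)
    return StructureScore(
        n=n, criterion="aic", value=float(dim) - ll, ll=ll,
        penalty=float(dim), dimension=dim,
    )


def ch70_score(
    data: DiscreteTimeSeriesDataset,
    n: int,
    rho: float = 0.3,
    baseline_gap: float | None = None,
) -> StructureScore:
    """Conditional-entropy criterion at split n.

    Accepts n when the entropy gap is at most ``rho`` times its n = 1
    baseline (``rho = 0.3`` demands a 70% reduction); the score is n when
    accepted, +inf otherwise.  A zero baseline accepts every n.
    ``baseline_gap`` lets a sweep pass the precomputed n = 1 gap.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly between 0 and 1")
    counts = count_configurations(data, n)
    ll = structured_log_likelihood(counts)
    dim = model_dimension(counts)
    gap = _gap(counts)
    if baseline_gap is None:
        baseline_gap = gap if n == 1 else _gap(count_configurations(data, 1))
    accepted = baseline_gap == 0.0 or gap <= rho * baseline_gap
    return StructureScore(
        n=n, criterion="ch70", value=float(n) if accepted else math.inf,
        ll=ll, penalty=0.0, dimension=dim, gap=gap,
    )
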