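"""Earliness sweep and reporting.

The sweep evaluates a criterion at every split point n = 1..L and returns
the earliest minimizer (ties broken toward smaller n by default, since the
whole point of the exercise is earliness).  The chosen n is a property of
the dataset — the method characterizes how early the collection as a whole
becomes classifiable, not when a single running series can be cut.

Also provided: prefix truncation, the earliness percentage n/L*100, the
BEA(p) earliness/accuracy trade-off statistic and a paired Wilcoxon
signed-rank comparison of criteria on BEA values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats as _sps

from .dataset_io import DiscreteTimeSeriesDataset
from .empirical_model import (
    conditional_entropy,
    count_configurations,
    structured_log_likelihood,
)
from .result import CriterionResult, MCECResult
from .scoring import CRITERIA, ScoreCurve, StructureScore, model_dimension

__all__ = [
    "mcec",
    "earliness_percent",
    "truncate",
    "bea",
    "TradeoffRecord",
    "ComparisonReport",
    "compare_criteria",
    "MCECResult",
]


def earliness_percent(n: int, length: int) -> float:
    """Percentage of the series consumed at split n: n/L*100."""
    if not 1 <= n <= length:
        raise ValueError(f"split point must be in 1..{length}, got {n}")
    return n / length * 100.0


def truncate(data: DiscreteTimeSeriesDataset, n: int) -> DiscreteTimeSeriesDataset:
    """Keep time points 1..n of every instance; labels unchanged."""
    if not 1 <= n <= data.length:
        raise ValueError(f"split point must be in 1..{data.length}, got {n}")
    return DiscreteTimeSeriesDataset(
        data.symbols[:, :n, :].copy(),
        list(data.alphabet_sizes),
        list(data.labels),
        list(data.class_values),
    )


def _sweep(data: DiscreteTimeSeriesDataset, rho: float):
    """Evaluate counts once per n and derive all three criteria from them."""
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly between 0 and 1")
    L = data.length
    logn_half = 0.5 * math.log2(data.n_instances)
    curves = {name: [] for name in CRITERIA}
    gaps: list[float] = []
    baseline = None
    for n in range(1, L + 1):
        counts = count_configurations(data, n)
        ll = structured_log_likelihood(counts)
        dim = model_dimension(counts)
        gap = conditional_entropy(counts, "C", "A") - conditional_entropy(
            counts, "C", "AB"
        )
        if baseline is None:
            baseline = gap
        gaps.append(gap)
        accepted = baseline == 0.0 or gap <= rho * baseline
        curves["ch70"].append(
            StructureScore(
                n=n, criterion="ch70",
                value=float(n) if accepted else math.inf,
                ll=ll, penalty=0.0, dimension=dim, gap=gap,
            )
        )
        curves["mdl"].append(
            StructureScore(
                n=n, criterion="mdl", value=logn_half * dim - ll,
                ll=ll, penalty=logn_half * dim, dimension=dim,
            )
        )
        curves["aic"].append(
            StructureScore(
                n=n, criterion="aic", value=float(dim) - ll,
                ll=ll, penalty=float(dim), dimension=dim,
            )
        )
    return {name: ScoreCurve(name, scores) for name, scores in curves.items()}, gaps


def mcec(
    data: DiscreteTimeSeriesDataset,
    criterion: str = "all",
    rho: float = 0.3,
    tie: str = "earliest",
) -> MCECResult:
    """Sweep every split point and pick the minimizer of each criterion.

    Parameters
    ----------
    data : DiscreteTimeSeriesDataset
        Symbol-coded fixed-length series with labels.
    criterion : {"ch70", "mdl", "aic", "all"}
        Which criterion (or all three) to evaluate.
    rho : float
        Residual fraction of the n = 1 entropy gap the conditional-entropy
        criterion tolerates (0.3 means a 70% reduction is required).
    tie : {"earliest", "latest"}
        Which minimizer to keep when several split points tie.

    The result carries, per criterion, the chosen n, the earliness
    percentage and the full score curve, plus the entropy-gap curve.
    Identical input always yields identical output.
    """
    criterion = criterion.lower()
    if criterion != "all" and criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    wanted = CRITERIA if criterion == "all" else (criterion,)
    curves, gaps = _sweep(data, rho)
    result = MCECResult(
        n_instances=data.n_instances,
        length=data.length,
        n_features=data.n_features,
        n_classes=data.n_classes,
        entropy_gap_curve=gaps,
    )
    for name in wanted:
        curve = curves[name]
        n = curve.argmin(tie=tie)
        result.criteria[name] = CriterionResult(
            criterion=name,
            n=n,
            earliness_percent=earliness_percent(n, data.length),
            curve=curve.values(),
        )
    return result


def bea(earliness: float, accuracy: float, p: float) -> float:
    """Balanced earliness/accuracy score: p*(100 - E) + (1 - p)*A.

    ``earliness`` and ``accuracy`` are percentages in [0, 100]; ``p`` in
    [0, 1] weights earliness against accuracy.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 0.0 <= earliness <= 100.0 or not 0.0 <= accuracy <= 100.0:
        raise ValueError("earliness and accuracy must lie in [0, 100]")
    return p * (100.0 - earliness) + (1.0 - p) * accuracy


@dataclass(frozen=True)
class TradeoffRecord:
    """Earliness/accuracy pair with its BEA(p) value."""

    earliness: float
    accuracy: float
    p: float
    bea: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bea", bea(self.earliness, self.accuracy, self.p)
        )


@dataclass
class ComparisonReport:
    """Paired Wilcoxon signed-rank comparison of two criteria on BEA values.

    ``direction`` names the side with the larger BEA sum ("first",
    "second", or None when every pairwise difference is zero, in which
    case the test is degenerate and carries no p-value).
    """

    n_pairs: int
    n_effective: int
    p_value: float | None
    direction: str | None
    significant: bool
    alpha: float


def compare_criteria(
    first: list[TradeoffRecord],
    second: list[TradeoffRecord],
    alpha: float = 0.05,
) -> ComparisonReport:
    """Two-sided Wilcoxon signed-rank test on paired BEA values.

    Zero differences are dropped (the classic treatment), and the reported
    effective sample size is the pair count after that removal.
    """
    if len(first) != len(second):
        raise ValueError("paired lists must have equal length")
    if not first:
        raise ValueError("need at least one pair")
    diffs = [a.bea - b.bea for a, b in zip(first, second)]
    nonzero = [d for d in diffs if d != 0.0]
    if not nonzero:
        return ComparisonReport(
            n_pairs=len(diffs), n_effective=0, p_value=None,
            direction=None, significant=False, alpha=alpha,
        )
    res = _sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided")
    direction = "first" if sum(nonzero) > 0 else "second"
    return ComparisonReport(
        n_pairs=len(diffs),
        n_effective=len(nonzero),
        p_value=float(res.pvalue),
        direction=direction,
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
    )
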