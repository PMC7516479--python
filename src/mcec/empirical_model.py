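"""Exact counting and entropy machinery over the prefix/suffix/class partition.

For a labelled collection of N discrete series of length L, a split point n
partitions each series into a prefix configuration ``a`` (time points 1..n,
all m features) and a suffix configuration ``b`` (time points n+1..L).  The
empirical joint distribution over (a, b, c) — with c the class label — is
estimated by plug-in frequencies with no smoothing, so the maximum-likelihood
identities used by the scoring criteria hold exactly.

The structured model at split n keeps only the dependencies
{prefix, suffix} and {prefix, class}: it is the Bayesian network with the
prefix as the sole parent of both the suffix and the class, whose joint
factors as ``P(a) P(b|a) P(c|a)``.  This factorization coincides with the
maximum-entropy distribution that matches the empirical marginals on
(prefix, suffix) and (prefix, class); :func:`maxent_structure_check`
verifies that numerically by iterative proportional fitting on small systems.

All entropies and log-likelihoods are in bits (base-2 logarithms).
Configuration keys are tuples in time-major, feature-minor order and all
iteration is in sorted key order, so every sum is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset_io import DiscreteTimeSeriesDataset

__all__ = [
    "ConfigurationCounts",
    "MaxEntReport",
    "count_configurations",
    "entropy",
    "conditional_entropy",
    "entropy_gap",
    "total_correlation",
    "structured_log_likelihood",
    "maxent_structure_check",
]

_SUM_TOL = 1e-9


def _check_split(n: int, length: int) -> int:
    n = int(n)
    if not 1 <= n <= length:
        raise ValueError(f"split point must be in 1..{length}, got {n}")
    return n


@dataclass
class ConfigurationCounts:
    """Exact joint counts of (prefix config, suffix config, class) at split n.

    ``joint`` maps ``(a, b, c)`` to its instance count, where ``a`` and
    ``b`` are flat symbol tuples of length ``n*m`` and ``(L-n)*m``.  The
    marginal tables are exact sums of the joint and every table sums to N.
    ``support_a`` is the number of distinct observed prefix configurations
    (non-decreasing in n on a fixed dataset).
    """

    n: int
    length: int
    n_features: int
    N: int
    joint: dict
    count_a: dict
    count_ab: dict
    count_ac: dict
    count_c: dict

    @property
    def support_a(self) -> int:
        return len(self.count_a)

    @property
    def n_classes(self) -> int:
        return len(self.count_c)


def count_configurations(
    data: DiscreteTimeSeriesDataset, n: int
) -> ConfigurationCounts:
    """Tally every (prefix, suffix, class) configuration at split point n.

    At ``n == L`` the suffix is the empty tuple for every instance.
    """
    n = _check_split(n, data.length)
    joint: dict = {}
    for j in range(data.n_instances):
        series = data.symbols[j]  # (L, m), time-major
        a = tuple(int(v) for v in series[:n].reshape(-1))
        b = tuple(int(v) for v in series[n:].reshape(-1))
        key = (a, b, data.labels[j])
        joint[key] = joint.get(key, 0) + 1

    count_a: dict = {}
    count_ab: dict = {}
    count_ac: dict = {}
    count_c: dict = {}
    for (a, b, c), cnt in sorted(joint.items()):
        count_a[a] = count_a.get(a, 0) + cnt
        count_ab[(a, b)] = count_ab.get((a, b), 0) + cnt
        count_ac[(a, c)] = count_ac.get((a, c), 0) + cnt
        count_c[c] = count_c.get(c, 0) + cnt
    return ConfigurationCounts(
        n=n,
        length=data.length,
        n_features=data.n_features,
        N=data.n_instances,
        joint=dict(sorted(joint.items())),
        count_a=count_a,
        count_ab=count_ab,
        count_ac=count_ac,
        count_c=count_c,
    )


def entropy(dist) -> float:
    """Shannon entropy of a probability vector, in bits.

    Uses the convention ``0 * log2(0) = 0``.  Raises on negative mass or a
    total differing from 1 by more than the tolerance.
    """
    p = np.asarray(dist, dtype=float)
    if np.any(p < -_SUM_TOL):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > max(_SUM_TOL, 1e-9 * p.size):
        raise ValueError(f"probabilities sum to {total}, not 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _entropy_of_counts(table: dict, N: int) -> float:
    """Entropy of the plug-in distribution count/N, in bits.

    Computed as ``log2 N - (1/N) * sum c*log2 c`` for numerical hygiene.
    """
    if N == 0:
        raise ValueError("empty count table")
    acc = 0.0
    for cnt in table.values():
        if cnt > 0:
            acc += cnt * math.log2(cnt)
    return math.log2(N) - acc / N


def conditional_entropy(
    counts: ConfigurationCounts, target: str, given: str
) -> float:
    """Empirical conditional entropy H(target | given), in bits.

    Supported pairs: ``("C", "A")``, ``("C", "AB")``, ``("B", "A")``.
    The empty suffix at ``n == L`` gives H(B|A) = 0.
    """
    pair = (target.upper(), given.upper())
    N = counts.N
    if pair == ("C", "A"):
        return _entropy_of_counts(counts.count_ac, N) - _entropy_of_counts(
            counts.count_a, N
        )
    if pair == ("C", "AB"):
        return _entropy_of_counts(counts.joint, N) - _entropy_of_counts(
            counts.count_ab, N
        )
    if pair == ("B", "A"):
        return _entropy_of_counts(counts.count_ab, N) - _entropy_of_counts(
            counts.count_a, N
        )
    raise ValueError(f"unsupported conditional entropy pair {pair}")


def entropy_gap(data: DiscreteTimeSeriesDataset, n: int) -> float:
    """H(C | prefix at n) - H(C | full series), in bits.

    This is the information about the class carried by the whole series but
    not by its first n points.  It is non-negative, non-increasing in n and
    exactly zero at n = L.
    """
    counts = count_configurations(data, n)
    return conditional_entropy(counts, "C", "A") - conditional_entropy(
        counts, "C", "AB"
    )


def total_correlation(columns) -> float:
    """Total correlation (multi-information) of jointly observed variables.

    ``columns`` is an (N, V) array: N joint observations of V discrete
    variables.  Returns the sum of marginal entropies minus the joint
    entropy of the empirical distribution; always >= 0.
    """
    arr = np.asarray(columns)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need an (N, V) array with N >= 1 observations")
    N = arr.shape[0]
    marg = 0.0
    for v in range(arr.shape[1]):
        _, cnts = np.unique(arr[:, v], return_counts=True)
        marg += _entropy_of_counts(dict(enumerate(cnts.tolist())), N)
    joint: dict = {}
    for row in arr:
        key = tuple(row.tolist())
        joint[key] = joint.get(key, 0) + 1
    return marg - _entropy_of_counts(joint, N)


def structured_log_likelihood(counts: ConfigurationCounts) -> float:
    """Log-likelihood of the data under the structured model, in bits.

    Sum over instances of ``log2[P(a) P(b|a) P(c|a)]`` with plug-in
    frequencies.  Equals ``-N * [H(A) + H(B|A) + H(C|A)]`` exactly (the
    maximum-likelihood plug-in duality), which is how it is computed.
    """
    N = counts.N
    h = (
        _entropy_of_counts(counts.count_a, N)
        + conditional_entropy(counts, "B", "A")
        + conditional_entropy(counts, "C", "A")
    )
    return -N * h


@dataclass
class MaxEntReport:
    """Outcome of the maximum-entropy cross-check at one split point."""

    distance: float
    iterations: int
    entropy_maxent: float
    entropy_empirical: float

    @property
    def passed(self) -> bool:
        return self.distance <= 1e-6


def maxent_structure_check(
    counts: ConfigurationCounts,
    max_cells: int = 2048,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> MaxEntReport:
    """Verify that the product form P(a)P(b|a)P(c|a) is the max-entropy
    distribution matching the empirical (prefix, suffix) and (prefix, class)
    marginals.

    Runs iterative proportional fitting from the uniform distribution over
    the observed-support grid and reports the max-norm distance between the
    IPF optimum and the product form.  Intended for small test systems only;
    refuses grids larger than ``max_cells``.
    """
    a_keys = sorted(counts.count_a)
    b_keys = sorted({b for (_, b) in counts.count_ab})
    c_keys = sorted(counts.count_c)
    shape = (len(a_keys), len(b_keys), len(c_keys))
    n_cells = shape[0] * shape[1] * shape[2]
    if n_cells > max_cells:
        raise ValueError(
            f"joint grid of {n_cells} cells exceeds the {max_cells}-cell "
            "test-scale guard"
        )
    a_idx = {k: i for i, k in enumerate(a_keys)}
    b_idx = {k: i for i, k in enumerate(b_keys)}
    c_idx = {k: i for i, k in enumerate(c_keys)}

    N = counts.N
    p_ab = np.zeros(shape[:2])
    for (a, b), cnt in counts.count_ab.items():
        p_ab[a_idx[a], b_idx[b]] = cnt / N
    p_ac = np.zeros((shape[0], shape[2]))
    for (a, c), cnt in counts.count_ac.items():
        p_ac[a_idx[a], c_idx[c]] = cnt / N

    p = np.full(shape, 1.0 / n_cells)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        m_ab = p.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(m_ab > 0, p_ab / np.where(m_ab > 0, m_ab, 1.0), 0.0)
        p = p * scale[:, :, None]
        m_ac = p.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(m_ac > 0, p_ac / np.where(m_ac > 0, m_ac, 1.0), 0.0)
        p = p * scale[:, None, :]
        err = max(
            np.abs(p.sum(axis=2) - p_ab).max(),
            np.abs(p.sum(axis=1) - p_ac).max(),
        )
        if err <= tol:
            break

    # Product-form reference: P(a, b, c) = P(a, b) * P(a, c) / P(a).
    p_a = p_ab.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_a = np.where(p_a > 0, 1.0 / np.where(p_a > 0, p_a, 1.0), 0.0)
    product = p_ab[:, :, None] * p_ac[:, None, :] * inv_a[:, None, None]

    p_emp = np.zeros(shape)
    for (a, b, c), cnt in counts.joint.items():
        p_emp[a_idx[a], b_idx[b], c_idx[c]] = cnt / N

    def _h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    return MaxEntReport(
        distance=float(np.abs(p - product).max()),
        iterations=iterations,
        entropy_maxent=_h(p),
        entropy_empirical=_h(p_emp),
    )
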