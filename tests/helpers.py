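"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — direct tallies, direct entropy
sums, explicit fractional mass assignment — and shares no code with the
package's implementation paths it is used to check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from mcec import DiscreteTimeSeriesDataset


def naive_tally(data: DiscreteTimeSeriesDataset, n: int):
    """Brute-force (prefix, suffix, class) tally by exhaustive iteration."""
    joint = Counter()
    for j in range(data.n_instances):
        a = tuple(int(v) for row in data.symbols[j, :n] for v in row)
        b = tuple(int(v) for row in data.symbols[j, n:] for v in row)
        joint[(a, b, data.labels[j])] += 1
    return joint


def naive_entropy(counts) -> float:
    """Direct -sum p log2 p over a count table."""
    total = sum(counts)
    return -sum(c / total * math.log2(c / total) for c in counts if c > 0)


def naive_conditional_entropy(pairs) -> float:
    """H(T|G) by direct weighted summation over conditioning groups.

    ``pairs`` is a list of (g, t) observations.
    """
    total = len(pairs)
    by_g = {}
    for g, t in pairs:
        by_g.setdefault(g, []).append(t)
    h = 0.0
    for g, ts in by_g.items():
        h += len(ts) / total * naive_entropy(Counter(ts).values())
    return h


def naive_gap(data: DiscreteTimeSeriesDataset, n: int) -> float:
    """H(C|prefix) - H(C|full series) by direct summation."""
    prefixes = [
        tuple(int(v) for row in data.symbols[j, :n] for v in row)
        for j in range(data.n_instances)
    ]
    fulls = [
        tuple(int(v) for row in data.symbols[j] for v in row)
        for j in range(data.n_instances)
    ]
    labels = data.labels
    return naive_conditional_entropy(
        list(zip(prefixes, labels))
    ) - naive_conditional_entropy(list(zip(fulls, labels)))


def naive_structured_ll(data: DiscreteTimeSeriesDataset, n: int) -> float:
    """Per-instance sum of log2[P(a) P(b|a) P(c|a)] with plug-in frequencies."""
    N = data.n_instances
    a_of = [
        tuple(int(v) for row in data.symbols[j, :n] for v in row) for j in range(N)
    ]
    b_of = [
        tuple(int(v) for row in data.symbols[j, n:] for v in row) for j in range(N)
    ]
    ca = Counter(a_of)
    cab = Counter(zip(a_of, b_of))
    cac = Counter(zip(a_of, data.labels))
    ll = 0.0
    for j in range(N):
        pa = ca[a_of[j]] / N
        pb_a = cab[(a_of[j], b_of[j])] / ca[a_of[j]]
        pc_a = cac[(a_of[j], data.labels[j])] / ca[a_of[j]]
        ll += math.log2(pa * pb_a * pc_a)
    return ll


def fractional_paa(series, word_length: int):
    """Explicit fractional-mass PAA: each raw point covers a unit interval
    and its mass is split across the output segments it overlaps."""
    x = list(map(float, series))
    L, W = len(x), word_length
    seg_len = L / W
    out = []
    for k in range(W):
        lo, hi = k * seg_len, (k + 1) * seg_len
        acc = 0.0
        for i, v in enumerate(x):
            overlap = max(0.0, min(hi, i + 1) - max(lo, i))
            acc += v * overlap
        out.append(acc / seg_len)
    return np.array(out)


def random_discrete_dataset(rng, max_n=50, max_l=8, max_a=3, max_m=2):
    """A random small labelled discrete dataset for property tests."""
    N = int(rng.integers(2, max_n + 1))
    L = int(rng.integers(1, max_l + 1))
    m = int(rng.integers(1, max_m + 1))
    a = int(rng.integers(2, max_a + 1))
    K = int(rng.integers(1, 4))
    symbols = rng.integers(0, a, size=(N, L, m))
    labels = [f"k{int(v)}" for v in rng.integers(0, K, size=N)]
    return DiscreteTimeSeriesDataset(symbols, [a] * m, labels)
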