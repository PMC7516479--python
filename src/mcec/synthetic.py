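"""Synthetic labelled discrete time-series with a planted earliness point.

Each instance gets a class drawn uniformly over K labels.  Prefix symbols
(time points 1..n*) follow a class-specific categorical: with probability
``signal`` the symbol equals a deterministic class pattern, otherwise it is
uniform over the alphabet.  The pattern is a shared base sequence except in
the last few prefix positions, which spell the class index in mixed-radix
alphabet digits — so the class is pinned down only once the full prefix has
been read, and at ``signal = 1`` the conditional entropy of the class given
the prefix is exactly zero.

Suffix symbols (time points n*+1..L) never look at the class: they are
either i.i.d. uniform or a shared sticky Markov chain seeded from the last
prefix symbol.  Conditional independence of class and suffix given the
prefix therefore holds by construction, which is exactly the regime in
which the split point n* is the right answer.

Randomness is counter-based per instance (one stream keyed by
``(seed, instance)``), so growing N leaves earlier instances untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .dataset_io import DiscreteTimeSeriesDataset, RawTimeSeriesDataset

__all__ = ["SyntheticSpec", "generate", "generate_raw"]

_MARKOV_STAY = 0.6


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-earliness generator.

    Defaults match the planted-recovery benchmark used throughout the test
    suite: 500 instances of length 12, one ternary feature, two classes,
    planted split at n* = 4 with 0.9 signal and an i.i.d.-uniform suffix.
    """

    N: int = 500
    L: int = 12
    m: int = 1
    alphabet_size: int = 3
    n_classes: int = 2
    n_star: int = 4
    signal: float = 0.9
    suffix_model: str = "iid-uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.L < 1 or self.m < 1:
            raise ValueError("N, L and m must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 1 <= self.n_star <= self.L:
            raise ValueError("n_star must lie in 1..L")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if self.suffix_model not in ("iid-uniform", "markov-shared"):
            raise ValueError(f"unknown suffix_model {self.suffix_model!r}")
        if self.alphabet_size ** (self.n_star * self.m) < self.n_classes:
            raise ValueError(
                "prefix state space too small to encode the classes"
            )


def _class_pattern(spec: SyntheticSpec, c: int) -> np.ndarray:
    """Deterministic (n_star, m) symbol pattern for class c.

    Shared base symbols everywhere except the trailing prefix cells, which
    hold the base-a digits of c (least significant digit last).
    """
    a = spec.alphabet_size
    pat = np.fromfunction(
        lambda k, f: (k + f) % a, (spec.n_star, spec.m), dtype=np.int64
    )
    n_digit_cells = max(1, math.ceil(math.log(spec.n_classes, a)))
    flat = pat.reshape(-1)
    code = c
    for pos in range(1, n_digit_cells + 1):
        flat[-pos] = code % a
        code //= a
    return flat.reshape(spec.n_star, spec.m)


def generate(spec: SyntheticSpec) -> DiscreteTimeSeriesDataset:
    """Draw a labelled discrete dataset with the planted split at n*."""
    a = spec.alphabet_size
    patterns = [_class_pattern(spec, c) for c in range(spec.n_classes)]
    symbols = np.empty((spec.N, spec.L, spec.m), dtype=np.int64)
    labels: list[str] = []
    n_suffix = spec.L - spec.n_star
    for j in range(spec.N):
        rng = np.random.default_rng([spec.seed, j])
        c = int(rng.integers(spec.n_classes))
        labels.append(f"c{c}")
        use_pattern = rng.random((spec.n_star, spec.m)) < spec.signal
        noise = rng.integers(0, a, size=(spec.n_star, spec.m))
        symbols[j, : spec.n_star] = np.where(use_pattern, patterns[c], noise)
        if n_suffix:
            if spec.suffix_model == "iid-uniform":
                symbols[j, spec.n_star:] = rng.integers(
                    0, a, size=(n_suffix, spec.m)
                )
            else:  # sticky chain continued from the last prefix symbol
                state = symbols[j, spec.n_star - 1].copy()
                stay = rng.random((n_suffix, spec.m)) < _MARKOV_STAY
                jump = rng.integers(0, a, size=(n_suffix, spec.m))
                for k in range(n_suffix):
                    state = np.where(stay[k], state, jump[k])
                    symbols[j, spec.n_star + k] = state
    return DiscreteTimeSeriesDataset(symbols, [a] * spec.m, labels)


def generate_raw(spec: SyntheticSpec, noise_sd: float = 0.25) -> RawTimeSeriesDataset:
    """Embed the discrete construction into real values.

    Each symbol s maps to the center of its equiprobable standard-normal
    bin (the quantile at (s + 1/2)/a), plus Gaussian noise of standard
    deviation ``noise_sd``.  With small noise and matched breakpoints,
    discretization recovers the symbol sequence.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    discrete = generate(spec)
    a = spec.alphabet_size
    centers = _sps.norm.ppf((np.arange(a) + 0.5) / a)
    values = centers[discrete.symbols].astype(float)
    if noise_sd > 0:
        for j in range(spec.N):
            rng = np.random.default_rng([spec.seed, j, 1])
            values[j] += rng.normal(0.0, noise_sd, size=values[j].shape)
    return RawTimeSeriesDataset(values, list(discrete.labels))
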