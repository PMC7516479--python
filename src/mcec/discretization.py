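"""SAX-style symbolic discretization of real-valued series.

Each feature channel of each instance is (optionally) z-normalized, reduced
to ``word_length`` segments by piecewise aggregate approximation (PAA), and
symbolized against equiprobable standard-normal breakpoints.  Channels are
discretized independently with the same configuration.

Boundary convention: symbol intervals are right-open, so a value exactly on
a breakpoint is assigned the higher code.  A constant series z-normalizes to
all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset_io import DiscreteTimeSeriesDataset, RawTimeSeriesDataset

__all__ = [
    "DiscretizationConfig",
    "znormalize",
    "paa",
    "sax_breakpoints",
    "discretize_dataset",
]


@dataclass(frozen=True)
class DiscretizationConfig:
    """Symbolization parameters.

    word_length
        Number of output time points W (the discretized series length).
    alphabet_size
        Number of symbols a per channel; codes are 0..a-1.
    normalize
        Apply per-series, per-channel z-normalization before PAA.
    """

    word_length: int
    alphabet_size: int = 4
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")


def znormalize(series: np.ndarray) -> np.ndarray:
    """Shift/scale to sample mean 0 and standard deviation 1.

    A constant series maps to the all-zero vector; series whose spread is
    at rounding level relative to their magnitude are treated as constant,
    since normalizing them would only amplify representation noise.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("series must have length >= 1")
    sd = x.std()
    if sd == 0.0 or sd < 1e-10 * np.abs(x).max():
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def paa(series: np.ndarray, word_length: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``word_length`` segment means.

    When W divides L the segments are contiguous blocks of length L/W;
    otherwise each raw point's mass is split proportionally across the
    segments it overlaps (the standard fractional scheme).
    """
    x = np.asarray(series, dtype=float)
    L = x.shape[0]
    W = int(word_length)
    if not 1 <= W <= L:
        raise ValueError(f"word_length must be in 1..{L}, got {W}")
    if L % W == 0:
        return x.reshape(W, L // W).mean(axis=1)
    # Exact fractional assignment: upsample each point W-fold, then take
    # block means of length L.  Equivalent to proportional mass splitting.
    return np.repeat(x, W).reshape(W, L).mean(axis=1)


def sax_breakpoints(alphabet_size: int) -> np.ndarray:
    """The a-1 standard-normal quantiles at i/a, i = 1..a-1.

    These cut N(0, 1) into ``alphabet_size`` equiprobable intervals; the
    vector is strictly increasing and antisymmetric about zero.
    """
    a = int(alphabet_size)
    if a < 2:
        raise ValueError("alphabet_size must be >= 2")
    return stats.norm.ppf(np.arange(1, a) / a)


def symbolize(values: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    """Map real values to codes 0..len(breakpoints); right-open intervals."""
    return np.searchsorted(breakpoints, values, side="right").astype(np.int64)


def discretize_dataset(
    raw: RawTimeSeriesDataset, cfg: DiscretizationConfig
) -> DiscreteTimeSeriesDataset:
    """Discretize every channel of every instance; labels pass through.

    The output has length ``cfg.word_length`` and a uniform alphabet of
    ``cfg.alphabet_size`` symbols on every channel.
    """
    n, l_raw, m = raw.values.shape
    if cfg.word_length > l_raw:
        raise ValueError(
            f"word_length {cfg.word_length} exceeds series length {l_raw}"
        )
    bp = sax_breakpoints(cfg.alphabet_size)
    out = np.empty((n, cfg.word_length, m), dtype=np.int64)
    for j in range(n):
        for f in range(m):
            channel = raw.values[j, :, f]
            if cfg.normalize:
                channel = znormalize(channel)
            out[j, :, f] = symbolize(paa(channel, cfg.word_length), bp)
    return DiscreteTimeSeriesDataset(
        out, [cfg.alphabet_size] * m, list(raw.labels)
    )
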