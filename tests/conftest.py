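import numpy as np
import pytest

from mcec import DiscreteTimeSeriesDataset

# Six instances, m=1, L=3, binary symbols, two classes.  Small enough that
# every count and entropy can be re-derived by hand or by the naive oracles.
TOY_ROWS = [
    ((0, 0, 1), "a"),
    ((0, 1, 1), "a"),
    ((0, 0, 0), "a"),
    ((1, 1, 0), "b"),
    ((1, 0, 1), "b"),
    ((0, 1, 1), "b"),
]


@pytest.fixture
def toy_dataset() -> DiscreteTimeSeriesDataset:
    symbols = np.array([row for row, _ in TOY_ROWS])[:, :, None]
    labels = [c for _, c in TOY_ROWS]
    return DiscreteTimeSeriesDataset(symbols, [2], labels)


@pytest.fixture
def identical_dataset() -> DiscreteTimeSeriesDataset:
    """Ten copies of the same series and label: every score ties."""
    symbols = np.tile(np.array([1, 0, 2, 1])[None, :, None], (10, 1, 1))
    return DiscreteTimeSeriesDataset(symbols, [3], ["only"] * 10)


@pytest.fixture
def balanced_dataset() -> DiscreteTimeSeriesDataset:
    """Every (s1, s2) configuration once per class: the class is exactly
    independent of the series, so the entropy gap is identically zero."""
    rows, labels = [], []
    for s1 in (0, 1):
        for s2 in (0, 1):
            for c in ("a", "b"):
                rows.append((s1, s2))
                labels.append(c)
    return DiscreteTimeSeriesDataset(np.array(rows)[:, :, None], [2], labels)
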