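"""Dataset containers and the CSV contract for fixed-length labelled time-series.

A dataset is a collection of N series, each with L time points and m features
per time point, plus one categorical class label per series.  Two containers
are provided: :class:`RawTimeSeriesDataset` for real-valued measurements
(pre-discretization) and :class:`DiscreteTimeSeriesDataset` for symbol-coded
series, which is what the scoring machinery consumes.

CSV layout
----------
One instance per row.  The class label sits in the first column by default
(the convention of the UCR/UEA benchmark files) or in the last column.  For
multivariate series the m feature channels are either *feature-blocked* (all
L values of feature 1, then all of feature 2, ...) or *interleaved* by time
point (t1f1, t1f2, ..., t2f1, ...).  Headers are optional and auto-detected.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .result import CriterionResult, MCECResult

__all__ = [
    "LayoutConfig",
    "RawTimeSeriesDataset",
    "DiscreteTimeSeriesDataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "write_result",
    "read_result",
]


class DatasetError(ValueError):
    """Raised when a file or container violates the fixed-length contract."""


@dataclass(frozen=True)
class LayoutConfig:
    """How a CSV file maps onto (instance, time point, feature) axes.

    Parameters
    ----------
    label_column : {"first", "last"}
        Position of the class-label field in each row.
    n_features : int
        Number of feature channels m.  Each data row must then carry
        ``1 + L*m`` fields for some integer L.
    mts_layout : {"feature-blocked", "interleaved"}
        Channel ordering of the L*m series fields (irrelevant for m=1).
    delimiter : str
        Field delimiter, comma by default.
    discrete : bool
        Load the series directly as symbol codes.  Requires every series
        value to be a non-negative integer.
    header : {"auto", True, False}
        Whether the first row is a header.  "auto" treats a first row whose
        series fields are not all numeric as a header.
    """

    label_column: str = "first"
    n_features: int = 1
    mts_layout: str = "feature-blocked"
    delimiter: str = ","
    discrete: bool = False
    header: object = "auto"

    def __post_init__(self) -> None:
        if self.label_column not in ("first", "last"):
            raise DatasetError(f"unknown label_column: {self.label_column!r}")
        if self.mts_layout not in ("feature-blocked", "interleaved"):
            raise DatasetError(f"unknown mts_layout: {self.mts_layout!r}")
        if self.n_features < 1:
            raise DatasetError("n_features must be >= 1")


def _ordered_unique(items: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return list(seen)


@dataclass
class RawTimeSeriesDataset:
    """Real-valued series, shape (N, L_raw, m), with one label per instance."""

    values: np.ndarray
    labels: list[str]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # univariate convenience
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise DatasetError("values must be (N, L_raw, m)")
        n, l, m = self.values.shape
        if n < 1 or l < 1 or m < 1:
            raise DatasetError("need N >= 1, L_raw >= 1, m >= 1")
        if len(self.labels) != n:
            raise DatasetError("labels length must equal N")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("missing or non-finite values are not supported")
        if self.feature_names is not None and len(self.feature_names) != m:
            raise DatasetError("feature_names length must equal m")
        self.labels = [str(c) for c in self.labels]

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]


@dataclass
class DiscreteTimeSeriesDataset:
    """Symbol-coded series, shape (N, L, m); codes for feature f lie in
    ``0..alphabet_sizes[f]-1``.

    ``class_values`` is the ordered list of distinct labels (first
    appearance order), so the number of classes is ``len(class_values)``.
    """

    symbols: np.ndarray
    alphabet_sizes: Sequence[int]
    labels: list[str]
    class_values: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols)
        if self.symbols.ndim == 2:
            self.symbols = self.symbols[:, :, None]
        if self.symbols.ndim != 3:
            raise DatasetError("symbols must be (N, L, m)")
        if not np.issubdtype(self.symbols.dtype, np.integer):
            if np.any(self.symbols != np.floor(self.symbols)):
                raise DatasetError("symbol codes must be integers")
            self.symbols = self.symbols.astype(np.int64)
        n, l, m = self.symbols.shape
        if n < 1 or l < 1 or m < 1:
            raise DatasetError("need N >= 1, L >= 1, m >= 1")
        self.alphabet_sizes = [int(a) for a in self.alphabet_sizes]
        if len(self.alphabet_sizes) != m:
            raise DatasetError("alphabet_sizes length must equal m")
        for f, a in enumerate(self.alphabet_sizes):
            if a < 1:
                raise DatasetError("alphabet sizes must be >= 1")
            col = self.symbols[:, :, f]
            if col.min() < 0 or col.max() >= a:
                raise DatasetError(
                    f"feature {f}: codes outside 0..{a - 1}"
                )
        if len(self.labels) != n:
            raise DatasetError("labels length must equal N")
        self.labels = [str(c) for c in self.labels]
        observed = _ordered_unique(self.labels)
        if self.class_values is None:
            self.class_values = observed
        else:
            self.class_values = [str(c) for c in self.class_values]
            if sorted(self.class_values) != sorted(observed):
                raise DatasetError(
                    "class_values must be exactly the distinct observed labels"
                )

    @property
    def n_instances(self) -> int:
        return self.symbols.shape[0]

    @property
    def length(self) -> int:
        return self.symbols.shape[1]

    @property
    def n_features(self) -> int:
        return self.symbols.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_values)


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _deinterleave(fields: np.ndarray, m: int, layout: str) -> np.ndarray:
    """Reshape a flat row of L*m series values into (L, m)."""
    lm = fields.shape[0]
    L = lm // m
    if layout == "feature-blocked":
        return fields.reshape(m, L).T
    return fields.reshape(L, m)


def _interleave(block: np.ndarray, layout: str) -> np.ndarray:
    """Flatten an (L, m) block back into the declared row order."""
    if layout == "feature-blocked":
        return block.T.reshape(-1)
    return block.reshape(-1)


def read_dataset(
    path: str | Path, layout: LayoutConfig | None = None
) -> RawTimeSeriesDataset | DiscreteTimeSeriesDataset:
    """Read a fixed-length labelled time-series CSV file.

    Returns a :class:`DiscreteTimeSeriesDataset` when ``layout.discrete``
    is set (all series values must be non-negative integers), otherwise a
    :class:`RawTimeSeriesDataset`.

    Raises
    ------
    DatasetError
        On an empty file, ragged rows (fixed-length violation), a
        non-numeric series cell, or a row length not divisible by the
        declared feature count.
    """
    layout = layout or LayoutConfig()
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=layout.delimiter) if r]
    if not rows:
        raise DatasetError(f"{path}: empty dataset")

    start = 0
    if layout.header is True:
        start = 1
    elif layout.header == "auto":
        first = rows[0]
        series_cells = first[1:] if layout.label_column == "first" else first[:-1]
        if series_cells and not all(_is_number(t) for t in series_cells):
            start = 1
    data_rows = rows[start:]
    if not data_rows:
        raise DatasetError(f"{path}: empty dataset (header only)")

    width = len(data_rows[0])
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise DatasetError(
                f"{path}: fixed-length violation at data row {i + 1}: "
                f"{len(row)} fields, expected {width}"
            )
        if layout.label_column == "first":
            label, series = row[0], row[1:]
        else:
            label, series = row[-1], row[:-1]
        if len(series) % layout.n_features != 0:
            raise DatasetError(
                f"{path}: row has {len(series)} series fields, not a "
                f"multiple of m={layout.n_features}"
            )
        try:
            vals = np.array([float(t) for t in series], dtype=float)
        except ValueError as exc:
            raise DatasetError(
                f"{path}: non-numeric series cell at data row {i + 1}: {exc}"
            ) from None
        labels.append(label.strip())
        blocks.append(_deinterleave(vals, layout.n_features, layout.mts_layout))

    values = np.stack(blocks)
    if layout.discrete:
        if np.any(values != np.floor(values)) or values.min() < 0:
            raise DatasetError(
                f"{path}: discrete layout requires non-negative integer codes"
            )
        codes = values.astype(np.int64)
        alph = [int(codes[:, :, f].max()) + 1 for f in range(codes.shape[2])]
        return DiscreteTimeSeriesDataset(codes, alph, labels)
    return RawTimeSeriesDataset(values, labels)


def write_dataset(
    data: RawTimeSeriesDataset | DiscreteTimeSeriesDataset,
    path: str | Path,
    layout: LayoutConfig | None = None,
) -> None:
    """Write a dataset in the CSV dialect understood by :func:`read_dataset`."""
    layout = layout or LayoutConfig(
        discrete=isinstance(data, DiscreteTimeSeriesDataset)
    )
    arr = data.symbols if isinstance(data, DiscreteTimeSeriesDataset) else data.values
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=layout.delimiter)
        for j in range(arr.shape[0]):
            flat = _interleave(arr[j], layout.mts_layout)
            cells = [str(int(v)) if float(v).is_integer() else repr(float(v))
                     for v in flat]
            if layout.label_column == "first":
                writer.writerow([data.labels[j], *cells])
            else:
                writer.writerow([*cells, data.labels[j]])


# ---------------------------------------------------------------------------
# Result report I/O (JSON)
# ---------------------------------------------------------------------------

def _encode(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def _decode(x):
    return math.inf if x == "inf" else x


def write_result(result: MCECResult, path: str | Path) -> None:
    """Serialize an :class:`MCECResult` to a JSON report.

    The report maps each criterion to its chosen time point, earliness
    percentage and the full per-n curves; it round-trips losslessly through
    :func:`read_result`.
    """
    if not result.criteria:
        raise DatasetError("result contains no criterion outcomes")
    payload = {
        "dataset": {
            "n_instances": result.n_instances,
            "length": result.length,
            "n_features": result.n_features,
            "n_classes": result.n_classes,
        },
        "entropy_gap_curve": list(result.entropy_gap_curve),
        "criteria": {
            name: {
                "n": out.n,
                "earliness_percent": out.earliness_percent,
                "curve": [_encode(v) for v in out.curve],
            }
            for name, out in sorted(result.criteria.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_result(path: str | Path) -> MCECResult:
    """Read back a report written by :func:`write_result`."""
    with open(path) as fh:
        payload = json.load(fh)
    ds = payload["dataset"]
    criteria = {
        name: CriterionResult(
            criterion=name,
            n=entry["n"],
            earliness_percent=entry["earliness_percent"],
            curve=[_decode(v) for v in entry["curve"]],
        )
        for name, entry in payload["criteria"].items()
    }
    return MCECResult(
        n_instances=ds["n_instances"],
        length=ds["length"],
        n_features=ds["n_features"],
        n_classes=ds["n_classes"],
        entropy_gap_curve=list(payload["entropy_gap_curve"]),
        criteria=criteria,
    )
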