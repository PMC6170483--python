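"""Spectral dataset container, delimited-text I/O, mean centering and
Kennard-Stone calibration/test partitioning.

A :class:`SpectralDataset` is a samples x channels intensity matrix ``X``
with a strictly monotone channel axis (nm or cm^-1), a reference response
vector ``y`` (iodine value, g I2 / 100 g oil) and unique sample labels.

The on-disk format is a fixed CSV dialect: UTF-8, comma separated, "."
decimal, a header row holding the channel positions, a leading sample-id
column and a trailing response column (named ``IV`` by default).  The
dialect is deliberately rigid so that ``write_dataset(read_dataset(f))``
round-trips bit-identically for shortest-repr decimal inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "SpectralDataset",
    "SplitResult",
    "CenteringTransform",
    "read_dataset",
    "write_dataset",
    "mean_center",
    "kennard_stone_split",
]


@dataclass
class SpectralDataset:
    """Sample x channel spectra with channel axis and iodine-value response."""

    X: np.ndarray
    axis: np.ndarray
    y: np.ndarray
    instrument_label: str = ""
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.axis = np.asarray(self.axis, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        n, p = self.X.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 channels, got {n} x {p}")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(f"non-finite intensity at sample {i}, channel {j}")
        if not np.all(np.isfinite(self.y)):
            i = int(np.flatnonzero(~np.isfinite(self.y))[0])
            raise ValueError(f"non-finite response at sample {i}")
        if self.axis.size != p:
            raise ValueError(f"axis length {self.axis.size} != channel count {p}")
        if self.y.size != n:
            raise ValueError(f"response length {self.y.size} != sample count {n}")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel axis must be strictly monotone")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1:03d}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length mismatch")
            if len(set(self.sample_ids)) != n:
                raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def restrict(self, channels: np.ndarray) -> "SpectralDataset":
        """Dataset restricted to an ascending subset of channel indices."""
        idx = np.asarray(channels, dtype=int)
        if idx.size < 2:
            raise ValueError("need at least 2 channels")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("channel indices must be strictly ascending")
        return SpectralDataset(
            self.X[:, idx], self.axis[idx], self.y,
            instrument_label=self.instrument_label,
            sample_ids=list(self.sample_ids),
        )


@dataclass
class SplitResult:
    """Calibration/test partition; disjoint, covering all samples."""

    cal_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        self.cal_indices = np.asarray(self.cal_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if self.cal_indices.size < 2:
            raise ValueError("calibration set needs at least 2 samples")
        both = np.concatenate([self.cal_indices, self.test_indices])
        if len(set(both.tolist())) != both.size:
            raise ValueError("calibration and test sets overlap")

    @property
    def n_total(self) -> int:
        return self.cal_indices.size + self.test_indices.size


@dataclass
class CenteringTransform:
    """Column means of the calibration block; test data reuse these means."""

    x_means: np.ndarray
    y_mean: float

    def center_x(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) - self.x_means

    def center_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) - self.y_mean

    def uncenter_x(self, Xc: np.ndarray) -> np.ndarray:
        return np.asarray(Xc, dtype=float) + self.x_means

    def uncenter_y(self, yc: np.ndarray) -> np.ndarray:
        return np.asarray(yc, dtype=float) + self.y_mean


def _fmt(v: float) -> str:
    return repr(float(v))


def read_dataset(
    path,
    response_column: str = "IV",
    instrument_label: str = "",
) -> SpectralDataset:
    """Read the package CSV dialect into a validated :class:`SpectralDataset`.

    The header row holds the channel positions between the leading sample-id
    column and the trailing response column.  Missing or non-numeric cells
    are rejected with their row/column location; duplicate sample ids are
    rejected as well.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if response_column not in cols:
        raise ValueError(f"no response column named {response_column!r}")
    if cols.index(response_column) != len(cols) - 1:
        raise ValueError(f"response column {response_column!r} must be last")
    axis_cols = cols[1:-1]
    if len(axis_cols) < 2:
        raise ValueError("need at least 2 channel columns")
    try:
        axis = np.array([float(c) for c in axis_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric channel position in header: {exc}") from exc
    sample_ids = df.iloc[:, 0].tolist()
    seen: dict[str, int] = {}
    for i, sid in enumerate(sample_ids):
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r} at rows {seen[sid]} and {i}")
        seen[sid] = i
    n = len(df)
    p = len(axis_cols)
    X = np.empty((n, p))
    y = np.empty(n)
    for i in range(n):
        for j, c in enumerate(axis_cols):
            cell = df.iloc[i, 1 + j]
            if cell.strip() == "":
                raise ValueError(f"empty cell at row {i} (id {sample_ids[i]!r}), column {c!r}")
            try:
                X[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {i} (id {sample_ids[i]!r}), column {c!r}"
                ) from None
        cell = df.iloc[i, p + 1]
        if cell.strip() == "":
            raise ValueError(f"empty cell at row {i} (id {sample_ids[i]!r}), column {response_column!r}")
        try:
            y[i] = float(cell)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {cell!r} at row {i} (id {sample_ids[i]!r}), "
                f"column {response_column!r}"
            ) from None
    return SpectralDataset(X, axis, y, instrument_label=instrument_label, sample_ids=sample_ids)


def write_dataset(
    ds: SpectralDataset,
    path,
    response_column: str = "IV",
    id_column: str = "sample_id",
) -> None:
    """Write a dataset in the package CSV dialect (see module docstring)."""
    lines = [",".join([id_column, *(_fmt(a) for a in ds.axis), response_column])]
    for i in range(ds.n_samples):
        row = [ds.sample_ids[i], *(_fmt(v) for v in ds.X[i]), _fmt(ds.y[i])]
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def mean_center(ds: SpectralDataset, split: SplitResult):
    """Center calibration and test blocks with calibration-only means.

    Returns ``((Xc_cal, yc_cal), (Xc_test, yc_test), CenteringTransform)``;
    the test block is centered with the *calibration* means, never its own.
    """
    if split.n_total != ds.n_samples:
        raise ValueError("split does not cover this dataset")
    if split.cal_indices.size == 0:
        raise ValueError("empty calibration set")
    X_cal = ds.X[split.cal_indices]
    y_cal = ds.y[split.cal_indices]
    tr = CenteringTransform(X_cal.mean(axis=0), float(y_cal.mean()))
    cal = (tr.center_x(X_cal), tr.center_y(y_cal))
    X_te = ds.X[split.test_indices]
    y_te = ds.y[split.test_indices]
    test = (tr.center_x(X_te), tr.center_y(y_te))
    return cal, test, tr


def kennard_stone_split(ds: SpectralDataset, n_cal: int) -> SplitResult:
    """Kennard-Stone max-min-distance calibration/test partition.

    Seeds with the pair of samples at maximal Euclidean distance in raw
    spectral space, then greedily adds the sample whose minimum distance to
    the already-selected set is largest.  Deterministic: ties are broken by
    the lowest sample index (numpy argmax returns the first maximum).
    """
    n = ds.n_samples
    if n_cal < 2:
        raise ValueError("n_cal must be at least 2")
    if n_cal > n:
        raise ValueError(f"n_cal {n_cal} exceeds sample count {n}")
    D = cdist(ds.X, ds.X)
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    if i == j:  # all rows identical: every distance 0; fall back to index order
        i, j = 0, 1
    elif i > j:
        i, j = j, i
    selected = [int(i), int(j)]
    min_d = np.minimum(D[i], D[j])
    min_d[selected] = -np.inf
    while len(selected) < n_cal:
        k = int(np.argmax(min_d))
        selected.append(k)
        min_d = np.minimum(min_d, D[k])
        min_d[k] = -np.inf
    cal = np.array(selected, dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[cal] = False
    return SplitResult(cal, np.flatnonzero(mask))
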