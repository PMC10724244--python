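"""Readers/writers for matrices and labels, plus dissimilarity computation.

File formats are deliberately plain: dense CSV/TSV value grids for square
dissimilarity matrices and data matrices, MatrixMarket (.mtx) for sparse
count matrices, one-value-per-line text for condensed upper-triangle vectors
(row-major i<j order) and one-label-per-line text for cluster labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.io import mmread
from scipy.spatial.distance import pdist, squareform

from .core import DissimilarityMatrix, PartitionLabels
from .exceptions import InputError

__all__ = [
    "DataMatrix",
    "METRICS",
    "compute_dissimilarity",
    "adjacency_from_labels",
    "log2_normalize",
    "top_variance_features",
    "read_square_matrix",
    "write_square_matrix",
    "read_condensed",
    "write_condensed",
    "read_labels",
    "write_labels",
    "read_data_matrix",
    "write_data_matrix",
]

#: supported dissimilarities -> scipy.spatial.distance metric names.
#: "maximum" is the Chebyshev (L-infinity) distance; "binary" is the Jaccard
#: distance on nonzero indicators (fraction of discordant positions among
#: positions where at least one vector is nonzero).
METRICS = {
    "euclidean": "euclidean",
    "maximum": "chebyshev",
    "manhattan": "cityblock",
    "canberra": "canberra",
    "binary": "jaccard",
}


@dataclass(frozen=True)
class DataMatrix:
    """Dense observations x features matrix of finite reals."""

    values: np.ndarray
    row_ids: Optional[list] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InputError(f"data matrix must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise InputError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.row_ids is not None and len(self.row_ids) != v.shape[0]:
            raise InputError("row_ids length does not match row count")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def f(self) -> int:
        return self.values.shape[1]


def compute_dissimilarity(X, metric: str = "euclidean") -> DissimilarityMatrix:
    """Pairwise dissimilarity matrix under one of the five supported metrics.

    Canberra terms with a zero denominator are skipped, and a binary/canberra
    distance between two all-zero rows is 0 (with a warning), following the
    usual conventions.
    """
    if metric not in METRICS:
        raise InputError(
            f"unknown metric {metric!r}; choose from {sorted(METRICS)}"
        )
    V = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if V.ndim != 2:
        raise InputError(f"data matrix must be 2-D, got shape {V.shape}")
    if V.shape[1] < 1:
        raise InputError("need at least one feature")
    if metric in ("binary", "canberra") and np.any(~V.any(axis=1)):
        warnings.warn(
            f"all-zero rows present; their pairwise {metric} distance is 0",
            stacklevel=2,
        )
    if metric == "binary":
        with np.errstate(invalid="ignore"):
            d = pdist(V != 0, metric="jaccard")
        d = np.nan_to_num(d, nan=0.0)  # all-zero pairs: 0/0 -> 0
    else:
        d = pdist(V, metric=METRICS[metric])
    return DissimilarityMatrix(squareform(d, checks=False))


def adjacency_from_labels(labels) -> np.ndarray:
    """Condensed (row-major i<j) boolean mask: True for same-cluster pairs.

    Its popcount is |D_W|, the number of within-cluster distances.
    """
    labels = PartitionLabels.coerce(labels)
    codes = labels.codes
    iu, ju = np.triu_indices(labels.n, k=1)
    return codes[iu] == codes[ju]


def log2_normalize(X, pseudocount: float = 1.0) -> DataMatrix:
    """log2(x + pseudocount) transform, the usual count preprocessing."""
    V = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if np.any(V + pseudocount <= 0):
        raise InputError("log2 transform requires x + pseudocount > 0")
    return DataMatrix(np.log2(V + pseudocount),
                      row_ids=getattr(X, "row_ids", None))


def top_variance_features(X, n_features: int) -> DataMatrix:
    """Keep the n_features columns with the largest sample variance."""
    V = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if not 1 <= n_features <= V.shape[1]:
        raise InputError(
            f"n_features must be in [1, {V.shape[1]}], got {n_features}"
        )
    keep = np.sort(np.argsort(V.var(axis=0, ddof=1))[::-1][:n_features])
    return DataMatrix(V[:, keep], row_ids=getattr(X, "row_ids", None))


# ---------------------------------------------------------------------------
# file IO


def _delimiter_for(path: Path, delimiter: Optional[str]) -> Optional[str]:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _parse_grid(path: Path, delimiter: Optional[str], skip_header: bool) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.strip()
            if not line:
                continue
            cells = line.split(delimiter) if delimiter else line.split()
            try:
                row = [float(c) for c in cells]
            except ValueError as err:
                raise InputError(f"{path}, line {lineno}: non-numeric cell ({err})")
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise InputError(
                    f"{path}, line {lineno}: ragged row "
                    f"({len(row)} cells, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise InputError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_square_matrix(path, delimiter: str | None = None,
                       header: bool = False) -> DissimilarityMatrix:
    """Dense square dissimilarity matrix from CSV/TSV (delimiter by extension)."""
    path = Path(path)
    grid = _parse_grid(path, _delimiter_for(path, delimiter), header)
    return DissimilarityMatrix(grid)


def write_square_matrix(D: DissimilarityMatrix, path, delimiter: str | None = None) -> None:
    path = Path(path)
    np.savetxt(path, D.values, fmt="%.17g",
               delimiter=_delimiter_for(path, delimiter))


def read_condensed(path, n: int | None = None) -> DissimilarityMatrix:
    """Condensed upper-triangle vector, one value per line, row-major i<j.

    If ``n`` is given, the line count must equal n(n-1)/2 exactly.
    """
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as err:
                raise InputError(f"{path}, line {lineno}: non-numeric value ({err})")
    if n is not None and len(values) != n * (n - 1) // 2:
        raise InputError(
            f"{path}: {len(values)} values, but n={n} requires {n * (n - 1) // 2}"
        )
    return DissimilarityMatrix.from_condensed(values)


def write_condensed(D: DissimilarityMatrix, path) -> None:
    np.savetxt(Path(path), D.condensed(), fmt="%.17g")


def read_labels(path) -> PartitionLabels:
    """Plain-text labels, one per line, order matching the matrix rows."""
    with open(Path(path)) as fh:
        labels = [line.rstrip("\n") for line in fh if line.strip()]
    return PartitionLabels(labels)


def write_labels(labels, path) -> None:
    labels = PartitionLabels.coerce(labels)
    Path(path).write_text("".join(f"{l}\n" for l in labels.labels))


def read_data_matrix(path, delimiter: str | None = None,
                     header: bool = False) -> DataMatrix:
    """Observations x features matrix from dense CSV/TSV or sparse MTX."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        m = mmread(path)
        if hasattr(m, "todense"):
            m = m.todense()
        return DataMatrix(np.asarray(m, dtype=float))
    return DataMatrix(_parse_grid(path, _delimiter_for(path, delimiter), header))


def write_data_matrix(X: DataMatrix, path, delimiter: str | None = None) -> None:
    path = Path(path)
    np.savetxt(path, X.values, fmt="%.17g",
               delimiter=_delimiter_for(path, delimiter))
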