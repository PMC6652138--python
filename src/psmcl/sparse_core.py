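"""Compressed sparse column (CSC) matrices and column-wise kernels.

The flow matrices iterated by MCL-family algorithms are stored in CSC form:
three flat arrays ``val``, ``row_ind`` and ``col_ptr`` such that column ``j``
occupies the half-open slice ``col_ptr[j]:col_ptr[j+1]`` of ``val``/``row_ind``.
Storage is proportional to the number of nonzeros, never to ``n_rows *
n_cols``, which is what makes flow simulation on sparse biological networks
feasible.

Everything the flow iteration needs is expressed through two kernels:

* :func:`spmspv` — sparse matrix times sparse column, with a fixed
  accumulation order so results are bit-for-bit reproducible, and
* :func:`assemble` — gluing independently computed columns back into a
  matrix, with disjoint storage regions per column so assembly order
  (and hence worker scheduling) cannot affect the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "CscMatrix",
    "SparseColumn",
    "csc_from_entries",
    "column_slice_bounds",
    "nonzeros",
    "spmspv",
    "assemble",
]

# Entries whose magnitude falls below this after arithmetic are treated as
# rounding noise and dropped during canonicalization, preventing spurious
# fill-in over many iterations.
DROP_TOL = 1e-15


@dataclass(frozen=True)
class SparseColumn:
    """A sparse vector: strictly increasing row indices with aligned values."""

    length: int
    rows: np.ndarray  # int64, strictly increasing
    values: np.ndarray  # float64, finite, nonzero

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "values", values)
        if rows.shape != values.shape or rows.ndim != 1:
            raise ValueError("rows and values must be aligned 1-d arrays")
        if rows.size:
            if rows[0] < 0 or rows[-1] >= self.length:
                raise IndexError("row index out of range")
            if np.any(np.diff(rows) <= 0):
                raise ValueError("row indices must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite value in sparse column")

    @property
    def nnz(self) -> int:
        return int(self.rows.size)

    def entries(self) -> list[tuple[int, float]]:
        return [(int(i), float(x)) for i, x in zip(self.rows, self.values)]

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.length)
        out[self.rows] = self.values
        return out

    @classmethod
    def from_dense(cls, x: np.ndarray, drop_tol: float = DROP_TOL) -> "SparseColumn":
        x = np.asarray(x, dtype=np.float64)
        rows = np.flatnonzero(np.abs(x) > drop_tol)
        return cls(length=x.size, rows=rows, values=x[rows])

    def sum(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class CscMatrix:
    """Compressed sparse column matrix (``val`` / ``row_ind`` / ``col_ptr``).

    Canonical form: within each column row indices are strictly increasing
    and no explicit zeros are stored.  ``col_ptr`` has length ``n_cols + 1``,
    is non-decreasing, starts at 0 and ends at ``nnz``.
    """

    n_rows: int
    n_cols: int
    val: np.ndarray = field(repr=False)
    row_ind: np.ndarray = field(repr=False)
    col_ptr: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "val", np.asarray(self.val, dtype=np.float64))
        object.__setattr__(self, "row_ind", np.asarray(self.row_ind, dtype=np.int64))
        object.__setattr__(self, "col_ptr", np.asarray(self.col_ptr, dtype=np.int64))
        if self.col_ptr.size != self.n_cols + 1:
            raise ValueError("col_ptr must have length n_cols + 1")
        if self.col_ptr[0] != 0 or self.col_ptr[-1] != self.val.size:
            raise ValueError("col_ptr bounds inconsistent with storage")
        if np.any(np.diff(self.col_ptr) < 0):
            raise ValueError("col_ptr must be non-decreasing")
        if self.val.shape != self.row_ind.shape:
            raise ValueError("val and row_ind must be aligned")

    @property
    def nnz(self) -> int:
        return int(self.val.size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- accessors ---------------------------------------------------------

    def column(self, j: int) -> SparseColumn:
        a, b = self._slice(j)
        return SparseColumn(self.n_rows, self.row_ind[a:b], self.val[a:b])

    def _slice(self, j: int) -> tuple[int, int]:
        if not 0 <= j < self.n_cols:
            raise IndexError(f"column {j} out of range for {self.n_cols} columns")
        return int(self.col_ptr[j]), int(self.col_ptr[j + 1])

    def column_sums(self) -> np.ndarray:
        out = np.zeros(self.n_cols)
        if self.val.size:
            cols = np.repeat(np.arange(self.n_cols), np.diff(self.col_ptr))
            np.add.at(out, cols, self.val)
        return out

    def row_sums(self) -> np.ndarray:
        out = np.zeros(self.n_rows)
        np.add.at(out, self.row_ind, self.val)
        return out

    def entries(self) -> list[tuple[int, int, float]]:
        """All stored entries as (row, col, value), column-major order."""
        out: list[tuple[int, int, float]] = []
        for j in range(self.n_cols):
            a, b = self._slice(j)
            out.extend(
                (int(i), j, float(x))
                for i, x in zip(self.row_ind[a:b], self.val[a:b])
            )
        return out

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_rows, self.n_cols))
        for i, j, x in self.entries():
            out[i, j] = x
        return out

    def __iter__(self) -> Iterator[SparseColumn]:
        return (self.column(j) for j in range(self.n_cols))


def csc_from_entries(
    entries: Iterable[tuple[int, int, float]], n_rows: int, n_cols: int
) -> CscMatrix:
    """Build a canonical :class:`CscMatrix` from (row, col, value) triples.

    Duplicate (row, col) pairs are summed; entries whose summed value is
    (numerically) zero are not stored.
    """
    ent = list(entries)
    if not ent:
        return CscMatrix(n_rows, n_cols, np.empty(0), np.empty(0, np.int64),
                         np.zeros(n_cols + 1, np.int64))
    rows = np.array([e[0] for e in ent], dtype=np.int64)
    cols = np.array([e[1] for e in ent], dtype=np.int64)
    vals = np.array([e[2] for e in ent], dtype=np.float64)
    if rows.min() < 0 or rows.max() >= n_rows or cols.min() < 0 or cols.max() >= n_cols:
        raise IndexError("entry index out of range")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite entry value")
    # sum duplicates, then sort column-major
    order = np.lexsort((rows, cols))
    rows, cols, vals = rows[order], cols[order], vals[order]
    keep = np.ones(rows.size, dtype=bool)
    keep[1:] = (np.diff(rows) != 0) | (np.diff(cols) != 0)
    group_ids = np.cumsum(keep) - 1
    summed = np.zeros(int(group_ids[-1]) + 1)
    np.add.at(summed, group_ids, vals)
    rows, cols = rows[keep], cols[keep]
    nz = np.abs(summed) > DROP_TOL
    rows, cols, summed = rows[nz], cols[nz], summed[nz]
    col_ptr = np.zeros(n_cols + 1, dtype=np.int64)
    np.add.at(col_ptr, cols + 1, 1)
    np.cumsum(col_ptr, out=col_ptr)
    return CscMatrix(n_rows, n_cols, summed, rows, col_ptr)


def column_slice_bounds(M: CscMatrix, j: int) -> tuple[int, int]:
    """1-based inclusive storage bounds (a, b) of column ``j`` (0-based).

    ``a = colPtr[j]`` and ``b = colPtr[j+1] - 1`` in 1-based indexing, so an
    empty column yields ``b = a - 1``.  Provided in this convention for
    conformance with the textbook CSC access pattern; internal code uses
    0-based half-open slices.
    """
    a0, b0 = M._slice(j)
    return a0 + 1, b0


def nonzeros(M: CscMatrix, j: int) -> list[tuple[int, float]]:
    """Stored (row, value) pairs of column ``j``, rows increasing."""
    return M.column(j).entries()


def spmspv(M: CscMatrix, x: SparseColumn) -> SparseColumn:
    """Sparse matrix–sparse vector product ``M @ x``.

    Accumulates over x's entries in ascending column index; together with
    IEEE-deterministic numpy kernels this fixes the floating-point result
    independent of scheduling.
    """
    if x.length != M.n_cols:
        raise ValueError(f"dimension mismatch: {M.n_cols} columns vs vector of length {x.length}")
    acc = np.zeros(M.n_rows)
    for k, xv in zip(x.rows, x.values):
        a, b = int(M.col_ptr[k]), int(M.col_ptr[k + 1])
        acc[M.row_ind[a:b]] += xv * M.val[a:b]
    return SparseColumn.from_dense(acc)


def assemble(
    columns: Mapping[int, SparseColumn] | Sequence[SparseColumn],
    n_rows: int,
    n_cols: int,
) -> CscMatrix:
    """Glue per-column results into a canonical :class:`CscMatrix`.

    Every column index in ``range(n_cols)`` must be present exactly once.
    Each column's storage region is disjoint (computed up front from the
    column lengths), so the result does not depend on the order in which
    columns were produced.
    """
    if not isinstance(columns, Mapping):
        columns = dict(enumerate(columns))
    if set(columns) != set(range(n_cols)):
        raise ValueError("assemble requires each column index exactly once")
    counts = np.array([columns[j].nnz for j in range(n_cols)], dtype=np.int64)
    col_ptr = np.zeros(n_cols + 1, dtype=np.int64)
    np.cumsum(counts, out=col_ptr[1:])
    val = np.empty(int(col_ptr[-1]))
    row_ind = np.empty(int(col_ptr[-1]), dtype=np.int64)
    for j in range(n_cols):
        c = columns[j]
        if c.length != n_rows:
            raise ValueError("column length mismatch")
        a, b = col_ptr[j], col_ptr[j + 1]
        val[a:b] = c.values
        row_ind[a:b] = c.rows
    return CscMatrix(n_rows, n_cols, val, row_ind, col_ptr)
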