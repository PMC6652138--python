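"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from psmcl.graph_io import WeightedGraph
from psmcl.sparse_core import CscMatrix, csc_from_entries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_csc(rng: np.random.Generator, n_rows: int, n_cols: int, density: float = 0.3) -> CscMatrix:
    dense = rng.random((n_rows, n_cols)) * (rng.random((n_rows, n_cols)) < density)
    return csc_from_dense(dense)


def csc_from_dense(dense: np.ndarray) -> CscMatrix:
    entries = [
        (i, j, float(dense[i, j]))
        for i in range(dense.shape[0])
        for j in range(dense.shape[1])
        if dense[i, j] != 0
    ]
    return csc_from_entries(entries, dense.shape[0], dense.shape[1])


def random_graph(rng: np.random.Generator, n: int, p: float = 0.3,
                 weighted: bool = False, int_weights: bool = False) -> WeightedGraph:
    """Erdos-Renyi-style random graph; isolated nodes allowed."""
    g = WeightedGraph()
    for i in range(n):
        g.add_node(f"v{i}")
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                if int_weights:
                    w = float(rng.integers(1, 10))
                elif weighted:
                    w = float(rng.random() + 0.1)
                else:
                    w = 1.0
                g.add_edge(i, j, w)
    return g


def dense_column_normalize(A: np.ndarray) -> np.ndarray:
    sums = A.sum(axis=0)
    out = A.copy().astype(float)
    nz = sums > 0
    out[:, nz] /= sums[nz]
    return out


def dense_inflate(M: np.ndarray, r: float) -> np.ndarray:
    return dense_column_normalize(M**r)


def dense_prune(M: np.ndarray, threshold: float) -> np.ndarray:
    """Column-wise prune with largest-entry rescue, on dense arrays."""
    out = np.zeros_like(M)
    for j in range(M.shape[1]):
        col = M[:, j]
        keep = col >= threshold
        if keep.any():
            out[keep, j] = col[keep] / col[keep].sum()
        else:
            out[int(np.argmax(col)), j] = 1.0
    return out


def dense_balanced_regularizer(M: np.ndarray, M_G: np.ndarray, b: float) -> np.ndarray:
    if b == 0:
        return M_G.copy()
    mass = M.sum(axis=1)
    v = M.T @ mass
    scale = np.where(v > 0, v, 1.0) ** (-b)
    return dense_column_normalize(np.diag(scale) @ M_G)
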