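"""Per-slice k-nearest-neighbor spatial graphs and the normalized operator.

Graphs are built per slice, joined block-diagonally (no cross-slice
edges), and symmetrically normalized for use by graph convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "SpatialGraph",
    "build_knn_graph",
    "block_diagonal_join",
    "normalize_adjacency",
    "export_edge_list",
]

_METRICS = ("euclidean", "manhattan", "chebyshev", "cosine", "hamming")


@dataclass
class SpatialGraph:
    A: sp.csr_matrix  # symmetric binary, zero diagonal
    k: int
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel().astype(int)


def build_knn_graph(coords: np.ndarray, k: int = 8, metric: str = "euclidean") -> SpatialGraph:
    """Directed kNN edges under `metric`, symmetrized by A <- max(A, A^T).

    Neighbor ties are broken by lower spot index, making the graph
    deterministic.  For the hamming metric, coordinates are cast to an
    integer grid first (array-based platforms).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_spots={n}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    query = np.rint(coords).astype(float) if metric == "hamming" else coords
    cdist_metric = {"manhattan": "cityblock"}.get(metric, metric)
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=int)
    all_idx = np.arange(n)
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(query[start:stop], query, metric=cdist_metric)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf  # exclude self
        for local, i in enumerate(range(start, stop)):
            # lexsort: primary key distance, ties broken by lower index
            order = np.lexsort((all_idx, d[local]))
            cols[i * k : (i + 1) * k] = order[:k]
    A = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    A.data[:] = 1.0
    return SpatialGraph(A=A, k=k, metric=metric)


def block_diagonal_join(graphs: list[SpatialGraph]) -> SpatialGraph:
    """Join per-slice graphs into one adjacency with zero cross-slice blocks."""
    if not graphs:
        raise ValueError("need at least one graph")
    A = sp.block_diag([g.A for g in graphs], format="csr")
    return SpatialGraph(A=A, k=graphs[0].k, metric=graphs[0].metric)


def normalize_adjacency(A: sp.spmatrix, add_self_loops: bool = True) -> sp.csr_matrix:
    """Symmetric normalization D^{-1/2} A D^{-1/2}.

    With ``add_self_loops`` (default) the identity is added first and
    degrees are taken from A + I, the standard GCN operator whose spectrum
    lies in [-1, 1].  Without self-loops, isolated nodes get degree 1 so
    the operator stays finite.
    """
    A = sp.csr_matrix(A, dtype=float)
    if (abs(A - A.T)).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency must be non-negative")
    if add_self_loops:
        A = A + sp.eye(A.shape[0], format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    dinv = sp.diags(1.0 / np.sqrt(deg))
    return sp.csr_matrix(dinv @ A @ dinv)


def export_edge_list(graph: SpatialGraph, path: str | Path):
    """COO edge list TSV (0-based indices, i<j once per undirected edge)."""
    coo = sp.triu(graph.A, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("spot_i\tspot_j\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{i}\t{j}\n")
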