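"""Unified cell graph: expression-similarity kNN plus spatial-proximity kNN.

Edges are binary and symmetric (union symmetrization).  Each edge carries an
origin flag telling whether it came from expression similarity, spatial
proximity, or both; downstream attention decides how much each edge matters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

ORIGIN_EXPRESSION = "expression"
ORIGIN_SPATIAL = "spatial"
ORIGIN_BOTH = "both"


@dataclasses.dataclass
class CellGraph:
    adjacency: sp.csr_matrix  # symmetric, zero diagonal, binary weights
    edge_origin: dict  # (i, j) with i<j -> origin flag

    def __post_init__(self):
        A = sp.csr_matrix(self.adjacency)
        A.setdiag(0)
        A.eliminate_zeros()
        if (abs(A - A.T) > 1e-12).nnz:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_components(self) -> int:
        return connected_components(self.adjacency, directed=False)[0]

    def edges(self) -> np.ndarray:
        """Undirected edge list as an array of (i, j), i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    def directed_edges(self):
        """(src, dst) arrays covering both directions of every edge."""
        coo = self.adjacency.tocoo()
        return coo.col.astype(np.int64), coo.row.astype(np.int64)

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"i": i, "j": j, "weight": 1.0, "origin": self.edge_origin[(i, j)]}
            for i, j in map(tuple, self.edges())
        ]
        return pd.DataFrame(rows, columns=["i", "j", "weight", "origin"])


def _knn_union(points: np.ndarray, k: int, origin: str) -> CellGraph:
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, idx = nn.kneighbors(points)
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A = ((A + A.T) > 0).astype(np.float64)  # union symmetrization
    A = sp.csr_matrix(A)
    coo = sp.triu(A, k=1).tocoo()
    origins = {(int(i), int(j)): origin for i, j in zip(coo.row, coo.col)}
    return CellGraph(adjacency=A, edge_origin=origins)


def build_expression_graph(features: np.ndarray, k: int = 30) -> CellGraph:
    """kNN graph in feature space (top principal components of log S)."""
    return _knn_union(np.asarray(features, dtype=np.float64), k, ORIGIN_EXPRESSION)


def build_spatial_graph(coords: np.ndarray | None, k: int = 8) -> CellGraph:
    """kNN graph on 2-D tissue coordinates."""
    if coords is None:
        raise ValueError(
            "spatial coordinates absent; build the expression-only graph instead"
        )
    return _knn_union(np.asarray(coords, dtype=np.float64), k, ORIGIN_SPATIAL)


def unify_graphs(g_expr: CellGraph, g_spatial: CellGraph | None) -> CellGraph:
    """Union of expression and spatial edges with per-edge origin flags."""
    if g_spatial is None:
        return g_expr
    if g_expr.n_cells != g_spatial.n_cells:
        raise ValueError("graphs must share the same node set")
    A = ((g_expr.adjacency + g_spatial.adjacency) > 0).astype(np.float64)
    A = sp.csr_matrix(A)
    origins = {}
    coo = sp.triu(A, k=1).tocoo()
    for i, j in zip(coo.row, coo.col):
        key = (int(i), int(j))
        in_e = key in g_expr.edge_origin
        in_s = key in g_spatial.edge_origin
        origins[key] = ORIGIN_BOTH if (in_e and in_s) else (
            ORIGIN_EXPRESSION if in_e else ORIGIN_SPATIAL
        )
    return CellGraph(adjacency=A, edge_origin=origins)


def pca_features(logS: np.ndarray, d: int = 30, seed: int = 0) -> np.ndarray:
    """Top-d principal components of the log-normalized spliced features."""
    from sklearn.decomposition import PCA

    d = int(min(d, logS.shape[0] - 1, logS.shape[1]))
    d = max(d, 1)
    return PCA(n_components=d, svd_solver="full", random_state=seed).fit_transform(
        logS
    )


def smooth_moments(graph: CellGraph, X: np.ndarray) -> np.ndarray:
    """First-order moments: average X over each cell's closed neighborhood.

    Standard moment smoothing for velocity fitting — damps shot noise in the
    count layers before any kinetic quantity is computed.
    """
    A = graph.adjacency + sp.eye(graph.n_cells, format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (A @ X) / deg[:, None]
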