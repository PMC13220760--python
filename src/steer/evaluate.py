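"""Evaluation metrics: velocity cosine, latent-time correlation, CBDir,
local coherence, Moran's I, and adjusted Rand index."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from .graph import CellGraph


def velocity_cosine(v_pred: np.ndarray, v_true: np.ndarray, axis: str = "cells"):
    """Cosine similarity per cell (across genes) or per gene (across cells).

    Items where either vector is identically zero are excluded; their count
    is returned alongside the values.

    Returns ``(values, mean, n_excluded)``.
    """
    v_pred = np.asarray(v_pred, dtype=float)
    v_true = np.asarray(v_true, dtype=float)
    if v_pred.shape != v_true.shape:
        raise ValueError("velocity matrices must share shape")
    if axis == "genes":
        v_pred, v_true = v_pred.T, v_true.T
    elif axis != "cells":
        raise ValueError("axis must be 'cells' or 'genes'")
    np_norm = np.linalg.norm(v_pred, axis=1)
    nt_norm = np.linalg.norm(v_true, axis=1)
    valid = (np_norm > 0) & (nt_norm > 0)
    if not valid.any():
        raise ValueError("all items have a zero velocity vector")
    cos = (v_pred[valid] * v_true[valid]).sum(axis=1) / (
        np_norm[valid] * nt_norm[valid]
    )
    values = np.full(v_pred.shape[0], np.nan)
    values[valid] = cos
    return values, float(cos.mean()), int((~valid).sum())


def time_correlation(t_pred, t_true) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if undefined."""
    t_pred = np.asarray(t_pred, dtype=float)
    t_true = np.asarray(t_true, dtype=float)
    if len(t_pred) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(t_pred) == 0 or np.ptp(t_true) == 0:
        return float("nan")
    return float(spearmanr(t_pred, t_true).statistic)


def _neighbor_lists(graph: CellGraph):
    A = graph.adjacency.tocsr()
    return [A.indices[A.indptr[i]: A.indptr[i + 1]] for i in range(graph.n_cells)]


def cbdir(v_s, S, graph: CellGraph, labels, transitions):
    """Cross-boundary directionality.

    For each transition A→B, boundary cells are cells in A with at least one
    graph neighbor in B; each contributes the cosine between its velocity and
    the mean displacement toward its B-neighbors.  Transitions with no
    boundary cells are reported as missing (NaN) and excluded from the mean.

    Returns ``(per-transition dict, overall mean)``.
    """
    v_s = np.asarray(v_s, dtype=float)
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    neigh = _neighbor_lists(graph)
    scores = {}
    for a, b in transitions:
        cell_scores = []
        for i in np.nonzero(labels == a)[0]:
            js = [j for j in neigh[i] if labels[j] == b]
            if not js:
                continue
            disp = (S[js] - S[i]).mean(axis=0)
            nv, nd = np.linalg.norm(v_s[i]), np.linalg.norm(disp)
            if nv == 0 or nd == 0:
                continue
            cell_scores.append(float(v_s[i] @ disp / (nv * nd)))
        scores[(a, b)] = float(np.mean(cell_scores)) if cell_scores else float("nan")
    finite = [v for v in scores.values() if np.isfinite(v)]
    overall = float(np.mean(finite)) if finite else float("nan")
    return scores, overall


def local_coherence(v_s, graph: CellGraph):
    """Per-cell mean cosine between a cell's velocity and its neighbors'.

    Cells with zero velocity (or no nonzero-velocity neighbor) get NaN.
    Returns ``(per-cell values, mean over defined cells)``.
    """
    v_s = np.asarray(v_s, dtype=float)
    norms = np.linalg.norm(v_s, axis=1)
    neigh = _neighbor_lists(graph)
    values = np.full(graph.n_cells, np.nan)
    for i in range(graph.n_cells):
        if norms[i] == 0:
            continue
        js = [j for j in neigh[i] if norms[j] > 0]
        if not js:
            continue
        cos = (v_s[js] @ v_s[i]) / (norms[js] * norms[i])
        values[i] = cos.mean()
    defined = values[np.isfinite(values)]
    return values, float(defined.mean()) if defined.size else float("nan")


def morans_i(values, weights) -> float:
    """Global Moran's I of a per-cell scalar under a spatial weight matrix."""
    x = np.asarray(values, dtype=float)
    W = sp.csr_matrix(weights)
    n = len(x)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    w_sum = float(W.sum())
    cross = float(xc @ (W @ xc))
    return (n / w_sum) * cross / denom


def row_standardize(W) -> sp.csr_matrix:
    W = sp.csr_matrix(W, dtype=float)
    deg = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / deg, 0.0)
    return sp.diags(inv) @ W


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
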