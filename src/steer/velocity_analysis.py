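"""Velocity computation, 2-D projection of velocity fields, and dynamic time
warping of kinetic features along latent time."""

from __future__ import annotations

import numpy as np

from .graph import CellGraph


def compute_velocity(alpha, beta, gamma, U, S):
    """Velocities from the splicing ODE: v_u = α − βU, v_s = βU − γS.

    All inputs are cells×genes; the identities hold elementwise and exactly.
    Returns ``(v_u, v_s)``.
    """
    arrs = [np.asarray(a, dtype=float) for a in (alpha, beta, gamma, U, S)]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among rate/count matrices: {shapes}")
    alpha, beta, gamma, U, S = arrs
    return alpha - beta * U, beta * U - gamma * S


def project_velocity(
    v_s: np.ndarray,
    S: np.ndarray,
    coords: np.ndarray,
    graph: CellGraph,
    sigma: float = 0.1,
):
    """Project gene-space velocities onto 2-D coordinates.

    Transition weights toward each neighbor are a softmax (bandwidth
    ``sigma``) of the cosine between the cell's velocity and the expression
    displacement toward that neighbor; the arrow is the weighted mean of unit
    coordinate displacements minus the uniform-neighbor baseline, so a cell
    whose velocity carries no information (zero vector) gets a zero arrow.
    """
    v_s = np.asarray(v_s, dtype=float)
    S = np.asarray(S, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = graph.n_cells
    arrows = np.zeros((n, 2))
    A = graph.adjacency.tocsr()
    for i in range(n):
        js = A.indices[A.indptr[i]: A.indptr[i + 1]]
        if js.size == 0 or np.linalg.norm(v_s[i]) == 0:
            continue
        dS = S[js] - S[i]
        dS_norm = np.linalg.norm(dS, axis=1)
        v_norm = np.linalg.norm(v_s[i])
        cos = np.where(dS_norm > 0, dS @ v_s[i] / (np.maximum(dS_norm, 1e-300) * v_norm), 0.0)
        w = np.exp(cos / sigma)
        w /= w.sum()
        dC = coords[js] - coords[i]
        dC_norm = np.linalg.norm(dC, axis=1)
        unit = np.where(dC_norm[:, None] > 0, dC / np.maximum(dC_norm, 1e-300)[:, None], 0.0)
        arrows[i] = w @ unit - unit.mean(axis=0)
    return arrows


def bin_series(values: np.ndarray, t: np.ndarray, n_bins: int = 15) -> np.ndarray:
    """Mean of ``values`` within ``n_bins`` equal-count bins along ``t``."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    if n_bins > len(values):
        raise ValueError("more bins than observations")
    order = np.argsort(t, kind="stable")
    chunks = np.array_split(values[order], n_bins)
    return np.array([c.mean() for c in chunks])


def dtw_align(series_a, series_b):
    """Classic dynamic time warping with unit steps and squared local cost.

    The two (already binned, z-scored) series are aligned with the step set
    {(1,0),(0,1),(1,1)}.  Returns ``(path, total_cost)`` where ``path`` is a
    list of index pairs from (0,0) to (m−1, n−1).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("empty series")
    cost = (a[:, None] - b[None, :]) ** 2
    D = np.full((m, n), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(m):
        for j in range(n):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, D[i - 1, j])
            if j > 0:
                best = min(best, D[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1])
            D[i, j] = cost[i, j] + best
    # backtrack, preferring the diagonal on ties
    path = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return path, float(D[m - 1, n - 1])


def align_kinetic_features(
    feature_a: np.ndarray,
    feature_b: np.ndarray,
    t: np.ndarray,
    n_bins: int = 15,
):
    """Bin two per-cell kinetic features into equal-count latent-time bins,
    z-score the bin means, and DTW-align them.

    Returns ``(path, cost, binned_a, binned_b)``.
    """
    a = bin_series(feature_a, t, n_bins)
    b = bin_series(feature_b, t, n_bins)

    def zscore(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    a, b = zscore(a), zscore(b)
    path, cost = dtw_align(a, b)
    return path, cost, a, b
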