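"""Kinetic-time inference and temporal regularization.

The time encoder maps the bottleneck embedding z to a scalar t ∈ (0,1) per
cell.  Two differentiable penalties shape t: a quadratic edge-smoothness
term and a directionality term that penalizes time orderings contradicting
the locally observed transcriptional tendency (the residual of each gene
around its steady-state ratio U ≈ k·S, whose sign predicts the direction of
spliced-expression change).
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, gather_rows
from ._nn import MLP, Module
from .graph import CellGraph


class TimeEncoder(Module):
    """Feed-forward map z → t, squashed to (0,1) by a logistic function."""

    def __init__(self, rng, d_z: int, hidden: int = 64):
        self.net = MLP(rng, [d_z, hidden, 1])

    def __call__(self, z: Tensor) -> Tensor:
        return self.net(z).reshape(-1).sigmoid()


def local_tendency(U: np.ndarray, S: np.ndarray, coarse_groups, q: float = 0.05):
    """Per-cell-gene tendency delta = U − k_g·S.

    k_g is fit by least squares through the origin on the cells in the
    extreme S-quantiles (top and bottom fraction ``q`` within each coarse
    group, pooled), the standard steady-state slope estimate.  The sign of
    delta predicts dS/dt up to a positive factor.  Genes with all-zero S get
    a zero column.

    Returns ``(delta, k)`` with delta cells×genes and k per gene.
    """
    U = np.asarray(U, dtype=float)
    S = np.asarray(S, dtype=float)
    groups = np.asarray(coarse_groups)
    n, g = S.shape
    sel = np.zeros((n, g), dtype=bool)
    for grp in np.unique(groups):
        idx = np.nonzero(groups == grp)[0]
        m = max(1, int(np.ceil(q * len(idx))))
        order = idx[np.argsort(S[idx], axis=0, kind="stable")]  # per-gene sort
        for j in range(g):
            sel[order[:m, j], j] = True
            sel[order[-m:, j], j] = True
    num = (U * S * sel).sum(axis=0)
    den = (S * S * sel).sum(axis=0)
    k = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    delta = U - k[None, :] * S
    delta[:, np.ptp(S, axis=0) == 0] = 0.0
    zero_s = (S == 0).all(axis=0)
    delta[:, zero_s] = 0.0
    return delta, k


def smoothness_loss(t, graph: CellGraph):
    """Mean squared time difference over undirected edges: Σ (t_i−t_j)²/|E|."""
    t = t if isinstance(t, Tensor) else Tensor(t)
    edges = graph.edges()
    if len(edges) == 0:
        return Tensor(0.0)
    d = gather_rows(t, edges[:, 0]) - gather_rows(t, edges[:, 1])
    return (d * d).mean()


def edge_projections(S: np.ndarray, delta: np.ndarray, src, dst,
                     normalize: bool = True) -> np.ndarray:
    """d_ij = ⟨S_j − S_i, delta_i⟩ per directed edge (i=dst side is the
    anchor cell; src is the neighbor j), scale-stabilized by the mean |d|."""
    d = ((S[src] - S[dst]) * delta[dst]).sum(axis=1)
    if normalize:
        scale = np.abs(d).mean()
        if scale > 0:
            d = d / scale
    return d


def directionality_loss(t, graph: CellGraph, tendency: np.ndarray, S: np.ndarray,
                        sign_scale: float = 1.0):
    """Softplus hinge penalizing t orderings that contradict the tendency.

    For each directed edge (i,j): loss_ij = softplus(−c·(t_j−t_i)·d_ij) with
    d_ij the tendency-projected displacement; mean over edges.
    """
    t = t if isinstance(t, Tensor) else Tensor(t)
    src, dst = graph.directed_edges()  # edge (dst=i → src=j neighbor)
    if len(src) == 0:
        return Tensor(np.log(2.0))
    d = edge_projections(np.asarray(S, float), np.asarray(tendency, float), src, dst)
    dt = gather_rows(t, src) - gather_rows(t, dst)  # t_j − t_i
    return (dt * Tensor(-sign_scale * d)).softplus().mean()


def directionality_agreement(t: np.ndarray, graph: CellGraph,
                             tendency: np.ndarray, S: np.ndarray) -> float:
    """Mean of sign(t_j−t_i)·d_ij over edges — positive when the learned
    ordering runs with the transcriptional tendency; used to orient t."""
    src, dst = graph.directed_edges()
    if len(src) == 0:
        return 0.0
    d = edge_projections(np.asarray(S, float), np.asarray(tendency, float), src, dst)
    return float(np.mean(np.sign(np.asarray(t)[src] - np.asarray(t)[dst]) * d))


def minmax_normalize(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    span = t.max() - t.min()
    if span == 0:
        return np.zeros_like(t)
    return (t - t.min()) / span
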