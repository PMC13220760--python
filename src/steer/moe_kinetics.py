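"""Gated mixture-of-experts over kinetic regimes.

A soft gating network maps the cell representation [z‖t] to a distribution
over K experts; each expert is an independent feed-forward network mapping
[z‖t] to per-cell, per-gene transcription/splicing/degradation rates
(softplus-positive).  A MinCUT relaxation regularizes the routing toward
graph-coherent, balanced clusters, and an entropy-elbow sweep selects K.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ._autograd import Tensor, concat
from ._nn import MLP, Module

RATE_EPS = 1e-6


def cell_representation(z: Tensor, t: Tensor) -> Tensor:
    """[z ‖ t] — the latent state concatenated with kinetic time."""
    return concat([z, t.reshape(-1, 1)], axis=1)


class GatingNetwork(Module):
    """Feed-forward gate with per-row softmax at temperature τ."""

    def __init__(self, rng, d_in: int, K: int, hidden: int = 64, tau: float = 1.0):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = K
        self.tau = tau
        self.net = MLP(rng, [d_in, hidden, K]) if K > 1 else None

    def __call__(self, rep: Tensor) -> Tensor:
        n = rep.shape[0]
        if self.K == 1:
            return Tensor(np.ones((n, 1)))
        logits = self.net(rep) * (1.0 / self.tau)
        shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant
        e = (logits - shift).exp()
        return e / e.sum(axis=1, keepdims=True)


class ExpertNetwork(Module):
    """One kinetic regime: per-gene rate curves over latent time.

    The latent state informs rates only through the discrete regime
    assignment — within a regime, rates are functions of t alone — so each
    expert is a feed-forward map t → (α, β, γ) per gene.  Softplus plus a
    small floor keeps every rate strictly positive.  ``d_in`` is the input
    width (1 for time-only experts; d_z+1 if a caller opts into
    latent-conditioned experts).
    """

    def __init__(self, rng, d_in: int, n_genes: int, hidden: int = 64,
                 out_scale: float = 1.0):
        self.n_genes = n_genes
        self.d_in = d_in
        # rates per unit latent time can be large (a compressed time axis
        # inflates them); a data-derived output gain keeps the softplus
        # pre-activations in a trainable range
        self.out_scale = float(out_scale)
        self.net = MLP(rng, [d_in, hidden, 3 * n_genes])

    def __call__(self, rep: Tensor):
        out = self.net(rep).softplus() * self.out_scale + RATE_EPS
        g = self.n_genes
        return out[:, :g], out[:, g:2 * g], out[:, 2 * g:]


def mixture_rates(W: Tensor, expert_rates, mode: str = "soft"):
    """Combine per-expert rates under the gating matrix.

    ``mode="soft"`` (training): rates = Σ_k W[:,k]·rates_k.
    ``mode="hard"`` (inference): rates of the argmax expert per cell.
    Returns (alpha, beta, gamma).
    """
    if mode == "soft":
        out = [None, None, None]
        for k, rates_k in enumerate(expert_rates):
            wk = W[:, k].reshape(-1, 1)
            for r in range(3):
                term = wk * rates_k[r]
                out[r] = term if out[r] is None else out[r] + term
        return tuple(out)
    if mode == "hard":
        Wd = W.data if isinstance(W, Tensor) else np.asarray(W)
        labels = Wd.argmax(axis=1)
        stacked = [
            np.stack([(rk[r].data if isinstance(rk[r], Tensor) else rk[r])
                      for rk in expert_rates])
            for r in range(3)
        ]
        rows = np.arange(len(labels))
        return tuple(s[labels, rows, :] for s in stacked)
    raise ValueError(f"unknown mode {mode!r}")


def expert_labels(W) -> np.ndarray:
    """Argmax expert per cell (ties go to the smallest index), 0-based."""
    Wd = W.data if isinstance(W, Tensor) else np.asarray(W)
    return Wd.argmax(axis=1)


def _sparse_matmul(A: sp.csr_matrix, X: Tensor) -> Tensor:
    """A @ X for constant sparse A and Tensor X (backward: Aᵀ @ grad)."""
    X = Tensor.as_tensor(X)

    def backward(g):
        if X.requires_grad:
            X._accum(A.T @ g)

    return X._make(A @ X.data, (X,), backward)


def mincut_loss(W, adjacency) -> Tensor:
    """Differentiable MinCUT relaxation with orthogonality.

    loss = −Tr(WᵀAW)/Tr(WᵀDW) + ‖ WᵀW/‖WᵀW‖_F − I_K/√K ‖_F

    The cut term is −1 exactly when clusters are unions of connected
    components with one-hot W; the orthogonality term favors balanced,
    near-hard assignments.  An empty graph makes the cut term 0.
    """
    W = Tensor.as_tensor(W)
    A = sp.csr_matrix(adjacency, dtype=float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    K = W.shape[1]

    tr_d = float((deg[:, None] * W.data * W.data).sum())
    if tr_d == 0:
        cut = Tensor(0.0)
    else:
        num = (W * _sparse_matmul(A, W)).sum()
        den = (Tensor(deg.reshape(-1, 1)) * W * W).sum()
        cut = -(num / den)

    M = W.T @ W
    frob = (M * M).sum().sqrt()
    eye = np.eye(K) / np.sqrt(K)
    diff = M / frob - Tensor(eye)
    orth = (diff * diff).sum().sqrt()
    return cut + orth


def gating_entropy(W) -> float:
    """Mean per-cell entropy of the gating distribution (natural log)."""
    Wd = W.data if isinstance(W, Tensor) else np.asarray(W)
    p = np.clip(Wd, 1e-12, None)
    return float(-(p * np.log(p)).sum(axis=1).mean())


def elbow_index(xs, ys, tol_frac: float = 0.01):
    """Kneedle-style elbow: the point with maximum perpendicular distance
    from the chord joining the curve's endpoints.

    Returns ``(index, distances, weak)`` — ``weak`` flags a max distance
    below ``tol_frac``·range(y).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        raise ValueError("elbow undefined for fewer than 3 candidates")
    p0 = np.array([xs[0], ys[0]])
    p1 = np.array([xs[-1], ys[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    pts = np.column_stack([xs, ys]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / max(norm, 1e-300)
    idx = int(dist.argmax())
    weak = bool(dist[idx] < tol_frac * max(np.ptp(ys), 1e-300))
    return idx, dist, weak


def select_num_experts(data, K_candidates, config=None, sweep_epochs=(30, 30, 40)):
    """Entropy-elbow selection of the expert count.

    For each candidate K a short three-stage training run (fixed seed,
    reduced epochs) is executed and the mean gating entropy recorded; the
    elbow of the (K, H) curve is returned together with the curve and a
    weak-elbow flag.
    """
    from .training import TrainConfig, fit

    K_candidates = sorted(int(k) for k in K_candidates)
    if len(K_candidates) < 3:
        raise ValueError("need at least 3 K candidates for an elbow")
    if any(k < 2 for k in K_candidates):
        raise ValueError("all K candidates must be >= 2")
    entropies = []
    for K in K_candidates:
        cfg = TrainConfig(**{**(config.__dict__ if config else {}),
                             "K": K, "epochs": tuple(sweep_epochs)})
        model = fit(data, cfg)
        entropies.append(gating_entropy(model.W))
    idx, dist, weak = elbow_index(K_candidates, entropies)
    return {
        "K": K_candidates[idx],
        "K_candidates": K_candidates,
        "entropy": entropies,
        "distances": dist.tolist(),
        "weak_elbow": weak,
    }
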