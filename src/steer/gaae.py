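"""Graph-attention autoencoder (GAAE).

Two attention layers encode the node features (log1p U‖S over the selected
genes) into a bottleneck embedding z.  The first layer learns the attention
matrix; the second layer and the decoder *reuse* that matrix and only apply
their own feature transforms — one attention matrix exists per model, which
preserves first-order neighborhood structure and limits over-smoothing.
Self-loops are always added so isolated cells stay well-defined (their
attention collapses onto the self-loop).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ._autograd import Tensor, spmm_edges
from ._nn import GraphAttention, Linear, Module
from .graph import CellGraph


def edge_arrays(graph: CellGraph):
    """(src, dst) index arrays for all directed edges plus self-loops."""
    src, dst = graph.directed_edges()
    loops = np.arange(graph.n_cells, dtype=np.int64)
    return np.concatenate([src, loops]), np.concatenate([dst, loops])


class GAAE(Module):
    """Two-layer graph-attention encoder with an attention-reusing decoder."""

    def __init__(self, rng, d_in: int, hidden: int = 128, d_z: int = 32,
                 heads: int = 2, slope: float = 0.2):
        self.layer1 = GraphAttention(rng, d_in, hidden, heads=heads, slope=slope)
        self.layer2 = GraphAttention(rng, hidden, d_z, heads=1, slope=slope)
        self.dec = Linear(rng, d_z, d_in)
        self.slope = slope
        self.d_in = d_in
        self.d_z = d_z

    # -- spec surface ---------------------------------------------------------
    def attention_coefficients(self, X: Tensor, src, dst, n: int) -> Tensor:
        """Per-edge attention weights of the first layer (rows sum to 1)."""
        return self.layer1.attention(X, src, dst, n)

    def encode(self, X: Tensor, src, dst, n: int, reuse: bool = True):
        """Returns (z, attention).  ``reuse=False`` is the ablation where the
        second layer learns its own attention (kept only for testing that
        reuse is actually wired)."""
        h1, attn = self.layer1(X, src, dst, n)
        h1 = h1.leaky_relu(self.slope)
        z, _ = self.layer2(h1, src, dst, n, attn=attn if reuse else None)
        if not np.all(np.isfinite(z.data)):
            raise FloatingPointError("non-finite activations in encoder layer 2")
        return z, attn

    def decode(self, z: Tensor, attn: Tensor, src, dst, n: int) -> Tensor:
        """Attention-weighted linear map from z back to the input dimension."""
        h = self.dec(z)
        return spmm_edges(attn, h, src, dst, n)

    def reconstruction_loss(self, X: Tensor, src, dst, n: int) -> Tensor:
        z, attn = self.encode(X, src, dst, n)
        x_hat = self.decode(z, attn, src, dst, n)
        diff = x_hat - X
        return (diff * diff).mean(), z, attn


def attention_matrix(graph: CellGraph, attn_values: np.ndarray) -> sp.csr_matrix:
    """Sparse n×n attention matrix (support = graph edges + self-loops)."""
    src, dst = edge_arrays(graph)
    n = graph.n_cells
    return sp.coo_matrix((np.asarray(attn_values).ravel(), (dst, src)),
                         shape=(n, n)).tocsr()
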