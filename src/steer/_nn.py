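"""Small neural building blocks on top of :mod:`steer._autograd`.

Initialization is Glorot-uniform from an explicit ``numpy.random.Generator``
so that every model in the package is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, gather_rows, segment_softmax, spmm_edges

__all__ = ["Linear", "MLP", "GraphAttention", "Module"]


class Module:
    """Base class: parameter collection and train/eval bookkeeping."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_arrays(self):
        """Flat list of parameter ndarrays (stable order) for checkpointing."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = np.array(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        self.W = _glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Feed-forward net with leaky-rectifier hidden activations."""

    def __init__(self, rng, dims, slope: float = 0.2):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.leaky_relu(self.slope)
        return x


class GraphAttention(Module):
    """One multi-head graph-attention layer on a fixed edge list.

    Edges are given as (src, dst) index arrays that must include self-loops.
    Per head h: e_ij = LeakyReLU(a_dst·(W_h x_i) + a_src·(W_h x_j)), then a
    softmax over each destination's neighborhood, then the attention-weighted
    sum of transformed neighbor features.  Head outputs and head attention
    weights are averaged, so a single per-edge attention vector is exposed
    for reuse by deeper layers and the decoder.
    """

    def __init__(self, rng, d_in: int, d_out: int, heads: int = 1, slope: float = 0.2):
        self.heads = heads
        self.slope = slope
        self.W = [_glorot(rng, d_in, d_out) for _ in range(heads)]
        self.a_src = [_glorot(rng, d_out, 1, shape=(d_out, 1)) for _ in range(heads)]
        self.a_dst = [_glorot(rng, d_out, 1, shape=(d_out, 1)) for _ in range(heads)]
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def attention(self, x: Tensor, src: np.ndarray, dst: np.ndarray, n: int) -> Tensor:
        """Averaged per-edge attention weights (rows sum to 1 over dst)."""
        weights = None
        for h in range(self.heads):
            H = x @ self.W[h]
            # project to per-node scalars first, then gather along edges
            u = (H @ self.a_dst[h]).reshape(-1)
            v = (H @ self.a_src[h]).reshape(-1)
            score = (gather_rows(u, dst) + gather_rows(v, src)).leaky_relu(self.slope)
            w = segment_softmax(score, dst, n)
            weights = w if weights is None else weights + w
        return weights * (1.0 / self.heads)

    def __call__(self, x: Tensor, src, dst, n: int, attn: Tensor | None = None):
        """Returns (output, per-edge attention used).

        If ``attn`` is given the layer reuses it (shared attention) and only
        applies its own feature transform, averaged across heads.
        """
        if attn is None:
            attn = self.attention(x, src, dst, n)
        out = None
        for h in range(self.heads):
            H = x @ self.W[h]
            agg = spmm_edges(attn, H, src, dst, n)
            out = agg if out is None else out + agg
        out = out * (1.0 / self.heads) + self.b
        return out, attn
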