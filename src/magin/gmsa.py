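"""Graph-convolution + multi-head self-attention encoder (GMSA).

The block is GCN1 -> ReLU -> dense multi-head self-attention over the
graph's nodes -> GCN2 -> LayerNorm.  The graph convolution uses the
symmetric-normalized adjacency with self-connections,
``ReLU(A_hat H W)``; attention is full (every node attends to every
node), which is what lets this branch carry long-range dependencies the
purely local GIN branch cannot.  Dense attention costs O(m^2) memory and
time in the node count m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .graph_features import PpiGraph, normalized_adjacency


@dataclass
class AttentionConfig:
    """Multi-head self-attention shape parameters.

    ``d_model`` must split exactly into ``heads`` blocks; the per-head
    width is ``d_model // heads`` (128 at the default 1024 / 8).  With
    ``projection_free`` the query/key/value triple is literally the input
    split into heads; otherwise three learned d_model x d_model
    projections produce Q, K and V first.
    """

    d_model: int = 1024
    heads: int = 8

    def __post_init__(self):
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"d_model {self.d_model} not divisible by heads {self.heads}")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.heads


class GcnLayer:
    """Symmetric-normalized graph convolution, optional ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: bool = True, name: str = "gcn"):
        self.W = ad.parameter(ad.glorot(rng, d_in, d_out), name=f"{name}.W")
        self.activation = activation

    def __call__(self, H: Tensor, Ahat: sp.csr_matrix) -> Tensor:
        out = ad.spmm(Ahat, ad.matmul(H, self.W))
        return ad.relu(out) if self.activation else out

    def parameters(self):
        return [self.W]


def gcn_layer(H: np.ndarray, Ahat, W: np.ndarray) -> np.ndarray:
    """Plain-array ReLU(A_hat H W) for direct use and oracle checks."""
    return np.maximum(Ahat @ (np.asarray(H) @ np.asarray(W)), 0.0)


class MultiHeadSelfAttention:
    """Scaled dot-product attention across graph nodes, h parallel heads.

    Per head i: ``softmax(Q_i K_i^T / sqrt(D)) V_i``; head outputs are
    concatenated back to d_model.  No output projection is applied after
    the concat.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator,
                 projection_free: bool = False, name: str = "mhsa"):
        self.cfg = cfg
        self.projection_free = projection_free
        if not projection_free:
            d = cfg.d_model
            self.Wq = ad.Linear(d, d, rng, name=f"{name}.Wq")
            self.Wk = ad.Linear(d, d, rng, name=f"{name}.Wk")
            self.Wv = ad.Linear(d, d, rng, name=f"{name}.Wv")
        self.last_attention: list[np.ndarray] = []

    def __call__(self, F: Tensor) -> Tensor:
        cfg = self.cfg
        if self.projection_free:
            Q = K = V = F
        else:
            Q, K, V = self.Wq(F), self.Wk(F), self.Wv(F)
        scale = 1.0 / np.sqrt(cfg.head_dim)
        outs = []
        self.last_attention = []
        for i in range(cfg.heads):
            a, b = i * cfg.head_dim, (i + 1) * cfg.head_dim
            Qi, Ki, Vi = (ad.slice_cols(t, a, b) for t in (Q, K, V))
            scores = ad.scale(ad.matmul(Qi, _transpose(Ki)), scale)
            attn = ad.softmax_rows(scores)
            self.last_attention.append(attn.data)
            outs.append(ad.matmul(attn, Vi))
        return ad.concat_cols(outs)

    def parameters(self):
        if self.projection_free:
            return []
        return (self.Wq.parameters() + self.Wk.parameters()
                + self.Wv.parameters())


def _transpose(x: Tensor) -> Tensor:
    out = Tensor(x.data.T, (x,))
    out._backward = lambda g: x.requires_grad and x.accumulate(g.T)
    return out


def multihead_attention(F: np.ndarray, block: MultiHeadSelfAttention) -> np.ndarray:
    """Plain-array attention forward (eval mode)."""
    return block(ad.constant(F)).data


@dataclass
class GmsaConfig:
    d_in: int = 2560
    d_out: int = 1024
    heads: int = 8
    projection_free: bool = False
    gcn2_relu: bool = True   # keep Eq-style ReLU inside the closing GCN
    dropout: float = 0.0     # hook only; the block itself uses none


class GmsaEncoder:
    """GCN1 -> attention -> GCN2 -> LayerNorm over node features."""

    def __init__(self, cfg: GmsaConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.attn_cfg = AttentionConfig(cfg.d_out, cfg.heads)
        self.gcn1 = GcnLayer(cfg.d_in, cfg.d_out, rng, activation=True,
                             name="gmsa.gcn1")
        self.attention = MultiHeadSelfAttention(
            self.attn_cfg, rng, projection_free=cfg.projection_free,
            name="gmsa.mhsa")
        self.gcn2 = GcnLayer(cfg.d_out, cfg.d_out, rng,
                             activation=cfg.gcn2_relu, name="gmsa.gcn2")
        self.norm = ad.LayerNormParams(cfg.d_out, name="gmsa.ln")

    def __call__(self, X: Tensor, graph: PpiGraph, *, Ahat=None,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        if Ahat is None:
            Ahat = normalized_adjacency(graph)
        h = self.gcn1(X, Ahat)
        a = self.attention(h)
        if rng is not None and self.cfg.dropout > 0:
            a = ad.dropout(a, self.cfg.dropout, rng, training)
        return self.norm(self.gcn2(a, Ahat))

    def parameters(self):
        return (self.gcn1.parameters() + self.attention.parameters()
                + self.gcn2.parameters() + self.norm.parameters())


def gmsa_encode(graph: PpiGraph, encoder: GmsaEncoder) -> np.ndarray:
    """Eval-mode forward on the graph's own features."""
    return encoder(ad.constant(graph.X), graph).data
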