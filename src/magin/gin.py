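"""Two-layer graph isomorphism network (GIN) encoder over the PPI graph.

Each layer computes ``MLP((1 + eps) * x_v + agg_{u in N(v)} x_u)`` with a
learnable scalar ``eps`` (initialized to 0) and, by default, elementwise
*max* aggregation over the neighborhood; the max over an empty
neighborhood is the zero vector, so isolated nodes reduce to
``MLP((1 + eps) x_v)``.  After the first layer the raw input features are
concatenated back onto the hidden representation (a cross-layer skip) and
the widened matrix feeds the second layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph_features import PpiGraph, normalized_adjacency


@dataclass
class GinConfig:
    """Structural configuration of the GIN encoder.

    ``d_out`` is both the hidden and the output width of each layer
    (default 1024); the per-layer MLP is input -> ``mlp_hidden`` -> d_out
    with a ReLU between the two affine maps.  ``cross_layer`` selects what
    is concatenated to the first-layer output: the raw input features
    (``"raw"``, the skip-connection reading) or the one-hop smoothed
    features A_hat X (``"adj"``); ``"none"`` disables the concat.
    """

    d_in: int = 2560
    d_out: int = 1024
    mlp_hidden: int = 1024
    n_layers: int = 2
    aggregation: str = "max"          # "max" or "sum"
    cross_layer: str = "raw"          # "raw", "adj" or "none"
    dropout: float = 0.3


class GinLayer:
    """One GIN convolution: learnable eps + two-affine MLP."""

    def __init__(self, d_in: int, d_out: int, mlp_hidden: int,
                 rng: np.random.Generator, aggregation: str = "max",
                 name: str = "gin"):
        if aggregation not in ("max", "sum"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        self.aggregation = aggregation
        self.eps = ad.parameter(0.0, name=f"{name}.eps")
        self.fc1 = ad.Linear(d_in, mlp_hidden, rng, name=f"{name}.fc1")
        self.fc2 = ad.Linear(mlp_hidden, d_out, rng, name=f"{name}.fc2")

    def __call__(self, X: Tensor, neighbors) -> Tensor:
        if self.aggregation == "max":
            agg = ad.neighbor_max(X, neighbors)
        else:
            agg = _neighbor_sum(X, neighbors)
        one_plus_eps = ad.add(self.eps, ad.constant(1.0))
        h = ad.add(ad.mul(X, one_plus_eps), agg)
        return self.fc2(ad.relu(self.fc1(h)))

    def parameters(self):
        return [self.eps] + self.fc1.parameters() + self.fc2.parameters()


def _neighbor_sum(X: Tensor, neighbors) -> Tensor:
    import scipy.sparse as sp
    m = X.data.shape[0]
    rows = [v for v, nb in enumerate(neighbors) for _ in nb]
    cols = [int(u) for nb in neighbors for u in nb]
    S = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    return ad.spmm(S, X)


class GinEncoder:
    """Stacked GIN layers with the cross-layer feature concat."""

    def __init__(self, cfg: GinConfig, rng: np.random.Generator):
        self.cfg = cfg
        extra = cfg.d_in if cfg.cross_layer in ("raw", "adj") else 0
        self.layer1 = GinLayer(cfg.d_in, cfg.d_out, cfg.mlp_hidden, rng,
                               cfg.aggregation, name="gin1")
        self.layer2 = GinLayer(cfg.d_out + extra, cfg.d_out, cfg.mlp_hidden,
                               rng, cfg.aggregation, name="gin2")

    def __call__(self, X: Tensor, graph: PpiGraph, *, neighbors=None,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        if neighbors is None:
            neighbors = graph.neighbor_lists()
        h1 = self.layer1(X, neighbors)
        if rng is not None:
            h1 = ad.dropout(h1, self.cfg.dropout, rng, training)
        if self.cfg.cross_layer == "raw":
            h1 = ad.concat_cols([h1, X])
        elif self.cfg.cross_layer == "adj":
            Ahat = normalized_adjacency(graph)
            h1 = ad.concat_cols([h1, ad.spmm(Ahat, X)])
        h2 = self.layer2(h1, neighbors)
        if rng is not None:
            h2 = ad.dropout(h2, self.cfg.dropout, rng, training)
        return h2

    def parameters(self):
        return self.layer1.parameters() + self.layer2.parameters()


def gin_layer(X: np.ndarray, graph: PpiGraph, layer: GinLayer) -> np.ndarray:
    """Evaluate a single GIN layer on a plain array (no grad, eval mode)."""
    out = layer(ad.constant(X), graph.neighbor_lists())
    return out.data


def gin_encode(graph: PpiGraph, encoder: GinEncoder) -> np.ndarray:
    """Eval-mode forward of the full encoder on the graph's own features."""
    return encoder(ad.constant(graph.X), graph).data
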