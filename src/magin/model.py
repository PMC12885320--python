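"""The full predictor: dual graph encoders fused with GO context into a
residual multi-label classifier.

Default dimensions match the reference configuration: node features
d1 = 2560 (mean-pooled protein-language-model embeddings), branch width
d2 = 1024, 8 attention heads (128 per head), GO-term embeddings d0 = 128.
Desk-scale runs shrink d1/d0/d2 through the config.  Ablation switches
drop whole branches (the dropped branch allocates no parameters), and a
registry swaps the first encoder's convolution between GIN, GCN, GAT and
GraphSAGE while leaving everything else unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gin import GinConfig, GinEncoder, GinLayer
from .gmsa import GmsaConfig, GmsaEncoder
from .fusion import FusionConfig, FusionHead
from .graph_features import PpiGraph, normalized_adjacency

CONV_VARIANTS = ("gin", "gcn", "gat", "sage")


@dataclass
class ModelConfig:
    d1: int = 2560            # node-feature width
    d0: int = 128             # GO-term embedding width
    d2: int = 1024            # shared branch width
    heads: int = 8
    gin_hidden: int = 1024
    dropout: float = 0.3
    aggregation: str = "max"
    cross_layer: str = "raw"
    projection_free: bool = False
    gcn2_relu: bool = True
    fusion: str = "add"
    use_gin: bool = True
    use_gmsa: bool = True
    use_go: bool = True
    conv_variant: str = "gin"

    def __post_init__(self):
        if self.conv_variant not in CONV_VARIANTS:
            raise ValueError(f"unknown conv variant {self.conv_variant!r}; "
                             f"choose from {CONV_VARIANTS}")
        if self.d2 % self.heads != 0:
            raise ValueError("d2 must be divisible by the head count")
        if not (self.use_gin or self.use_gmsa or self.use_go):
            raise ValueError("at least one branch must be enabled")

    @property
    def head_dim(self) -> int:
        return self.d2 // self.heads


# -- alternative first-encoder convolutions ----------------------------------

class _DenseGcnConv:
    """ReLU(A_hat H W) used as a drop-in for the GIN convolution."""

    def __init__(self, d_in, d_out, rng, name):
        self.W = ad.parameter(ad.glorot(rng, d_in, d_out), name=f"{name}.W")

    def __call__(self, X: Tensor, ctx) -> Tensor:
        return ad.relu(ad.spmm(ctx["Ahat"], ad.matmul(X, self.W)))

    def parameters(self):
        return [self.W]


class _SageConv:
    """GraphSAGE mean variant: ReLU(W_self x + W_nbr mean(neighbors))."""

    def __init__(self, d_in, d_out, rng, name):
        self.Ws = ad.Linear(d_in, d_out, rng, name=f"{name}.self")
        self.Wn = ad.parameter(ad.glorot(rng, d_in, d_out), name=f"{name}.nbr")

    def __call__(self, X: Tensor, ctx) -> Tensor:
        nbr = ad.mean_neighbors(X, ctx["neighbors"])
        return ad.relu(ad.add(self.Ws(X), ad.matmul(nbr, self.Wn)))

    def parameters(self):
        return self.Ws.parameters() + [self.Wn]


class _GatConv:
    """Single-head graph attention with LeakyReLU edge scoring.

    Attention is computed densely with off-graph entries masked to -inf
    (self-loops included), which is exact and cheap at desk scale.
    """

    def __init__(self, d_in, d_out, rng, name):
        self.W = ad.parameter(ad.glorot(rng, d_in, d_out), name=f"{name}.W")
        self.a_src = ad.parameter(ad.glorot(rng, d_out, 1), name=f"{name}.asrc")
        self.a_dst = ad.parameter(ad.glorot(rng, d_out, 1), name=f"{name}.adst")

    def __call__(self, X: Tensor, ctx) -> Tensor:
        H = ad.matmul(X, self.W)
        s = ad.matmul(H, self.a_src)             # m x 1
        t = ad.matmul(H, self.a_dst)             # m x 1
        e = ad.leaky_relu(ad.add(s, _row(t)))    # m x m scores
        attn = ad.softmax_rows(e, mask=ctx["gat_mask"])
        return ad.relu(ad.matmul(attn, H))

    def parameters(self):
        return [self.W, self.a_src, self.a_dst]


def _row(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, (t,))
    out._backward = lambda g: t.requires_grad and t.accumulate(g.T)
    return out


class _GinConvAdapter:
    def __init__(self, d_in, d_out, hidden, rng, aggregation, name):
        self.layer = GinLayer(d_in, d_out, hidden, rng, aggregation, name)

    def __call__(self, X: Tensor, ctx) -> Tensor:
        return self.layer(X, ctx["neighbors"])

    def parameters(self):
        return self.layer.parameters()


def conv_variant_registry(name: str):
    """Constructor for the named graph convolution, signature
    ``(d_in, d_out, cfg, rng, layer_name) -> layer``."""
    if name == "gin":
        return lambda di, do, cfg, rng, nm: _GinConvAdapter(
            di, do, cfg.gin_hidden, rng, cfg.aggregation, nm)
    if name == "gcn":
        return lambda di, do, cfg, rng, nm: _DenseGcnConv(di, do, rng, nm)
    if name == "sage":
        return lambda di, do, cfg, rng, nm: _SageConv(di, do, rng, nm)
    if name == "gat":
        return lambda di, do, cfg, rng, nm: _GatConv(di, do, rng, nm)
    raise ValueError(f"unknown conv variant {name!r}; choose from "
                     f"{CONV_VARIANTS}")


class _VariantEncoder:
    """Two conv layers of a registry variant, keeping the GIN branch's
    cross-layer concat and dropout placement."""

    def __init__(self, cfg: ModelConfig, rng):
        make = conv_variant_registry(cfg.conv_variant)
        extra = cfg.d1 if cfg.cross_layer in ("raw", "adj") else 0
        self.cfg = cfg
        self.layer1 = make(cfg.d1, cfg.d2, cfg, rng, "enc1")
        self.layer2 = make(cfg.d2 + extra, cfg.d2, cfg, rng, "enc2")

    def __call__(self, X: Tensor, ctx, rng=None, training=False) -> Tensor:
        h1 = self.layer1(X, ctx)
        if rng is not None:
            h1 = ad.dropout(h1, self.cfg.dropout, rng, training)
        if self.cfg.cross_layer == "raw":
            h1 = ad.concat_cols([h1, X])
        elif self.cfg.cross_layer == "adj":
            h1 = ad.concat_cols([h1, ad.spmm(ctx["Ahat"], X)])
        h2 = self.layer2(h1, ctx)
        if rng is not None:
            h2 = ad.dropout(h2, self.cfg.dropout, rng, training)
        return h2

    def parameters(self):
        return self.layer1.parameters() + self.layer2.parameters()


class MaginModel:
    """End-to-end multi-label GO-term predictor over a PPI graph."""

    def __init__(self, cfg: ModelConfig, n_terms: int, seed: int = 0):
        self.cfg = cfg
        self.n_terms = n_terms
        rng = np.random.default_rng(seed)
        self.gin = None
        self.gmsa = None
        if cfg.use_gin:
            if cfg.conv_variant == "gin":
                self.gin = GinEncoder(GinConfig(
                    d_in=cfg.d1, d_out=cfg.d2, mlp_hidden=cfg.gin_hidden,
                    aggregation=cfg.aggregation, cross_layer=cfg.cross_layer,
                    dropout=cfg.dropout), rng)
            else:
                self.gin = _VariantEncoder(cfg, rng)
        if cfg.use_gmsa:
            self.gmsa = GmsaEncoder(GmsaConfig(
                d_in=cfg.d1, d_out=cfg.d2, heads=cfg.heads,
                projection_free=cfg.projection_free,
                gcn2_relu=cfg.gcn2_relu), rng)
        self.head = FusionHead(
            FusionConfig(d_go=cfg.d0, d_model=cfg.d2, dropout=cfg.dropout,
                         mode=cfg.fusion),
            n_terms, rng, use_go=cfg.use_go)

    # -- introspection --------------------------------------------------------

    @property
    def head_dim(self) -> int:
        return self.cfg.head_dim

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.gin is not None:
            ps += self.gin.parameters()
        if self.gmsa is not None:
            ps += self.gmsa.parameters()
        ps += self.head.parameters()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward --------------------------------------------------------------

    def _context(self, graph: PpiGraph) -> dict:
        ctx: dict = {"neighbors": graph.neighbor_lists(),
                     "Ahat": normalized_adjacency(graph)}
        if self.cfg.conv_variant == "gat":
            A = graph.adjacency().toarray()
            np.fill_diagonal(A, 1.0)
            ctx["gat_mask"] = np.where(A > 0, 0.0, -np.inf)
        return ctx

    def forward(self, graph: PpiGraph, G: np.ndarray, *,
                rng: np.random.Generator | None = None,
                training: bool = False, ctx: dict | None = None) -> Tensor:
        """Per-term logits for every node, shape m x L."""
        if ctx is None:
            ctx = self._context(graph)
        X = ad.constant(graph.X)
        m = graph.m
        branches: list[Tensor] = []
        if self.gin is not None:
            if isinstance(self.gin, GinEncoder):
                branches.append(self.gin(X, graph,
                                         neighbors=ctx["neighbors"],
                                         rng=rng, training=training))
            else:
                branches.append(self.gin(X, ctx, rng=rng, training=training))
        if self.gmsa is not None:
            branches.append(self.gmsa(X, graph, Ahat=ctx["Ahat"],
                                      rng=rng, training=training))
        if self.cfg.use_go:
            branches.append(self.head.go_context(
                ad.constant(G), m, rng=rng, training=training))
        if not branches:
            raise ValueError("all branches disabled")
        # a disabled branch simply contributes nothing to the fusion sum;
        # under "concat"/"weighted" fusion all three branches are required
        if self.cfg.fusion != "add" and len(branches) != 3:
            raise ValueError(f"{self.cfg.fusion!r} fusion needs all branches")
        return self.head(branches, rng=rng, training=training)

    def predict(self, graph: PpiGraph, G: np.ndarray) -> np.ndarray:
        """Eval-mode score matrix in (0, 1), shape m x L."""
        from .fusion import predict_scores
        return predict_scores(self.forward(graph, G).data)

    # -- serialization --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        names: dict[str, int] = {}
        out = {}
        for p in self.parameters():
            key = p.name or "param"
            names[key] = names.get(key, -1) + 1
            out[f"{key}#{names[key]}"] = p.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        names: dict[str, int] = {}
        for p in self.parameters():
            key = p.name or "param"
            names[key] = names.get(key, -1) + 1
            data = np.asarray(state[f"{key}#{names[key]}"], dtype=float)
            if data.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}: "
                                 f"{data.shape} vs {p.data.shape}")
            p.data = data.copy()
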