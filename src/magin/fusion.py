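"""GO-embedding context, three-way feature fusion, residual block and the
per-term sigmoid classifier.

The L term-embedding rows are mean-pooled into a single ontology context
vector, lifted to the model width by a two-layer MLP
(ReLU / LayerNorm / Dropout on top), and broadcast to every protein row.
The three branches (GIN, GMSA, GO context) are fused — elementwise
addition by default — then passed through one pre-activation residual
block and a linear layer producing one logit per GO term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class FusionConfig:
    d_go: int = 128           # term-embedding width (d0)
    d_model: int = 1024       # shared branch width (d2)
    mlp_hidden: int = 1024
    dropout: float = 0.3
    mode: str = "add"         # "add", "concat" or "weighted"


class FusionHead:
    """Everything downstream of the two graph encoders."""

    def __init__(self, cfg: FusionConfig, n_terms: int,
                 rng: np.random.Generator, use_go: bool = True):
        self.cfg = cfg
        self.n_terms = n_terms
        self.use_go = use_go
        d2 = cfg.d_model
        if use_go:
            self.go_fc1 = ad.Linear(cfg.d_go, cfg.mlp_hidden, rng, "go.fc1")
            self.go_fc2 = ad.Linear(cfg.mlp_hidden, d2, rng, "go.fc2")
            self.go_norm = ad.LayerNormParams(d2, "go.ln")
        if cfg.mode == "concat":
            self.mix = ad.Linear(3 * d2, d2, rng, "fuse.mix")
        elif cfg.mode == "weighted":
            self.mix_w = ad.parameter(np.zeros(3), name="fuse.w")
        self.res_fc = ad.Linear(d2, d2, rng, "res.fc")
        self.res_norm = ad.LayerNormParams(d2, "res.ln")
        self.out = ad.Linear(d2, n_terms, rng, "out")

    # -- stages ---------------------------------------------------------------

    def go_context(self, G: Tensor, m: int,
                   rng: np.random.Generator | None = None,
                   training: bool = False) -> Tensor:
        """Pooled, lifted and broadcast GO context: m identical rows."""
        if G.data.shape[0] < 1:
            raise ValueError("empty term-embedding matrix")
        pooled = ad.mean_rows(G)                       # 1 x d0
        h = self.go_fc2(ad.relu(self.go_fc1(pooled)))  # 1 x d2
        h = self.go_norm(ad.relu(h))
        if rng is not None:
            h = ad.dropout(h, self.cfg.dropout, rng, training)
        return ad.broadcast_rows(h, m)

    def fuse(self, branches: list[Tensor]) -> Tensor:
        if self.cfg.mode == "add":
            return ad.add_n(branches)
        if self.cfg.mode == "concat":
            return self.mix(ad.concat_cols(branches))
        if self.cfg.mode == "weighted":
            w = ad.softmax_rows(
                Tensor(self.mix_w.data[None, :], (self.mix_w,),
                       lambda g: self.mix_w.accumulate(g.ravel()),
                       name="fuse.w.row"))
            terms = [ad.mul(b, ad.slice_cols(w, i, i + 1))
                     for i, b in enumerate(branches)]
            return ad.add_n(terms)
        raise ValueError(f"unknown fusion mode {self.cfg.mode!r}")

    def residual_block(self, x: Tensor, rng: np.random.Generator | None = None,
                       training: bool = False) -> Tensor:
        h = self.res_norm(ad.relu(self.res_fc(x)))
        if rng is not None:
            h = ad.dropout(h, self.cfg.dropout, rng, training)
        return ad.add(h, x)

    def logits(self, x_res: Tensor) -> Tensor:
        return self.out(x_res)

    def __call__(self, branches: list[Tensor],
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        x_all = self.fuse(branches)
        x_res = self.residual_block(x_all, rng, training)
        return self.logits(x_res)

    def parameters(self):
        ps = []
        if self.use_go:
            ps += (self.go_fc1.parameters() + self.go_fc2.parameters()
                   + self.go_norm.parameters())
        if self.cfg.mode == "concat":
            ps += self.mix.parameters()
        elif self.cfg.mode == "weighted":
            ps += [self.mix_w]
        ps += (self.res_fc.parameters() + self.res_norm.parameters()
               + self.out.parameters())
        return ps


# -- plain-array conveniences -------------------------------------------------

def fuse(*branches: np.ndarray) -> np.ndarray:
    """Elementwise-addition fusion of same-shape branch outputs."""
    shapes = {b.shape for b in branches}
    if len(shapes) != 1:
        raise ValueError(f"branch shapes differ: {shapes}")
    out = np.zeros_like(np.asarray(branches[0], dtype=float))
    for b in branches:
        out = out + b
    return out


def predict_scores(logits: np.ndarray) -> np.ndarray:
    """Sigmoid scores in (0, 1) from per-term logits."""
    z = np.asarray(logits, dtype=float)
    return np.where(z >= 0, 1 / (1 + np.exp(-np.clip(z, 0, None))),
                    np.exp(np.clip(z, None, 0))
                    / (1 + np.exp(np.clip(z, None, 0))))


def max_propagate_scores(scores: np.ndarray, terms: list[str],
                         dag) -> np.ndarray:
    """Optional postprocessor: ancestor score = max over its descendants.

    Makes the score matrix hierarchy-consistent (every ancestor scores at
    least as high as any descendant).  Off by default in the pipeline.
    """
    idx = {t: i for i, t in enumerate(terms)}
    out = np.array(scores, dtype=float)
    for t in terms:
        for a in dag.ancestors(t):
            if a in idx:
                j, i = idx[a], idx[t]
                out[:, j] = np.maximum(out[:, j], out[:, i])
    return out


def write_predictions_tsv(path, proteins: list[str], terms: list[str],
                          scores: np.ndarray, min_score: float = 0.01) -> None:
    """`protein_id<TAB>go_id<TAB>score` rows (6 decimals) above a cutoff."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, p in enumerate(proteins):
            for j, t in enumerate(terms):
                if scores[i, j] >= min_score:
                    fh.write(f"{p}\t{t}\t{scores[i, j]:.6f}\n")
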