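"""Per-ontology training loop, checkpointing and evaluation.

Training is transductive: every step runs the full-graph forward, and the
multi-label binary cross-entropy loss is taken on mini-batches of protein
rows (batch size 37 by default).  Adam drives the updates; early stopping
monitors the validation loss with a fixed patience, and the checkpoint
returned is the best-validation one.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autodiff as ad
from .fixtures import FixtureBundle
from .metrics import evaluate_scores, naive_baseline
from .model import MaginModel, ModelConfig
from .ontology import information_content, term_depths
from .fusion import predict_scores

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings; model architecture lives in ``model``."""

    model: ModelConfig = field(default_factory=ModelConfig)
    learning_rate: float = 1e-3
    batch_size: int = 37
    max_epochs: int = 256
    patience: int = 10
    early_stopping: bool = True   # False: run all epochs, keep final weights
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["model"] = ModelConfig(**d.get("model", {}))
        return cls(**d)


@dataclass
class Checkpoint:
    """Best-validation model weights plus the config and loss history."""

    config: TrainConfig
    n_terms: int
    state: dict[str, np.ndarray]
    epoch: int
    history: dict[str, list[float]]

    def save(self, path) -> None:
        meta = json.dumps({"config": self.config.to_dict(),
                           "n_terms": self.n_terms,
                           "epoch": self.epoch,
                           "history": self.history})
        np.savez(path, __meta__=np.array(meta), **self.state)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            state = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(TrainConfig.from_dict(meta["config"]), meta["n_terms"],
                   state, meta["epoch"], meta["history"])

    def build_model(self) -> MaginModel:
        model = MaginModel(self.config.model, self.n_terms,
                           seed=self.config.seed)
        model.load_state_dict(self.state)
        return model


def _truth_and_rows(bundle: FixtureBundle, proteins: list[str]):
    idx = np.array([bundle.graph.index[p] for p in proteins], dtype=int)
    return idx, bundle.truth_matrix(proteins)


def train(bundle: FixtureBundle, cfg: TrainConfig,
          log_stream=None) -> Checkpoint:
    """Fit the model on the bundle's training split.

    Returns the checkpoint with the lowest validation loss seen; training
    stops after ``patience`` epochs without improvement or at
    ``max_epochs``.  Raises on NaN loss with the offending epoch.
    """
    if not bundle.annotations.propagated:
        raise ValueError("annotations must be propagated")
    terms = bundle.terms
    if not terms:
        raise ValueError("empty term set")
    model = MaginModel(cfg.model, len(terms), seed=cfg.seed)
    rng = np.random.default_rng([cfg.seed, 100])
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    graph, G = bundle.graph, bundle.term_embeddings.subset(terms).X
    ctx = model._context(graph)
    tr_idx, tr_truth = _truth_and_rows(bundle, bundle.splits["train"])
    va_idx, va_truth = _truth_and_rows(bundle, bundle.splits["valid"])

    history: dict[str, list[float]] = {"train_loss": [], "valid_loss": []}
    best_loss, best_state, best_epoch = np.inf, model.state_dict(), 0
    wait = 0
    stream = log_stream if log_stream is not None else sys.stderr
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(tr_idx))
        ep_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward(graph, G, rng=rng, training=True, ctx=ctx)
            loss = ad.bce_with_logits(
                ad.take_rows(logits, tr_idx[batch]), tr_truth[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        eval_logits = model.forward(graph, G, ctx=ctx).data
        tr_loss = _bce(eval_logits[tr_idx], tr_truth)
        va_loss = _bce(eval_logits[va_idx], va_truth)
        history["train_loss"].append(tr_loss)
        history["valid_loss"].append(va_loss)
        print(f"epoch {epoch:4d}  train_loss {tr_loss:.5f}  "
              f"valid_loss {va_loss:.5f}", file=stream)
        if not cfg.early_stopping:
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        elif va_loss < best_loss - 1e-7:
            best_loss, best_epoch, wait = va_loss, epoch, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    return Checkpoint(cfg, len(terms), best_state, best_epoch, history)


def _bce(logits: np.ndarray, truth: np.ndarray) -> float:
    z, y = logits, truth.astype(float)
    return float((np.maximum(z, 0) - z * y
                  + np.log1p(np.exp(-np.abs(z)))).mean())


def predict(ckpt: Checkpoint, bundle: FixtureBundle) -> np.ndarray:
    """Eval-mode score matrix for every graph node."""
    model = ckpt.build_model()
    terms = bundle.terms
    G = bundle.term_embeddings.subset(terms).X
    return predict_scores(model.forward(bundle.graph, G).data)


def evaluate(ckpt: Checkpoint, bundle: FixtureBundle, split: str,
             with_naive: bool = True) -> dict:
    """Full metric suite on one split, plus the Naive baseline on the
    same split for comparison."""
    if split not in bundle.splits:
        raise KeyError(f"unknown split {split!r}")
    proteins = bundle.splits[split]
    unknown = [p for p in proteins if p not in bundle.graph.index]
    if unknown:
        raise ValueError(f"split proteins missing from graph: {unknown}")
    terms = bundle.terms
    scores = predict(ckpt, bundle)
    idx = np.array([bundle.graph.index[p] for p in proteins], dtype=int)
    truth = bundle.truth_matrix(proteins)
    train_ann = bundle.annotations.restrict(bundle.splits["train"])
    ic = information_content(bundle.dag, train_ann)
    depths = term_depths(bundle.dag)
    report = evaluate_scores(scores[idx], truth, terms, ic,
                             train_ann=train_ann, depths=depths)
    out = {"split": split, "n_proteins": len(proteins),
           "model": report.to_dict()}
    if with_naive:
        nv = naive_baseline(train_ann, terms, proteins)
        out["naive"] = evaluate_scores(nv, truth, terms, ic).to_dict()
    return out
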