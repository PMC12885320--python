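# magin

Multi-label protein function prediction over protein–protein interaction
(PPI) networks, for computational biologists who want a transparent,
CPU-scale implementation of a dual graph-neural-network GO-term predictor
together with the CAFA-style evaluation stack (Fmax, Smin, AUPR,
class-centric AUC) and the Naive annotation-frequency baseline.

## The model

Proteins are nodes of an undirected PPI graph `g = (V, X)`; each node
carries a sequence-derived feature vector (mean-pooled per-residue
embeddings from a protein language model, `d1 = 2560` at reference scale).
Two encoders read the graph in parallel:

- **GIN branch** — two graph-isomorphism-network convolutions,
  `x_v ← MLP((1 + ε) x_v + max_{u∈N(v)} x_u)`, with the raw input features
  concatenated back onto the first layer's output (a cross-layer skip)
  before the second layer. Output `X_GIN ∈ R^{m×d2}`, `d2 = 1024`.
- **GMSA branch** — a symmetric-normalized graph convolution
  `ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)` feeding 8-head scaled dot-product
  self-attention over all nodes (`softmax(Q_i K_iᵀ/√D) V_i`, `D = d2/8 =
  128`), closed by a second graph convolution and LayerNorm:
  `X_GMSA ∈ R^{m×d2}`.

GO-term embedding rows `G ∈ R^{L×d0}` (`d0 = 128`, ancestry-aware term
vectors) are mean-pooled, lifted by an MLP and broadcast to every protein
(`X_GO`). The branches fuse additively, `X_all = X_GIN + X_GMSA + X_GO`,
pass one residual block `X_res = Dropout(LayerNorm(ReLU(W1 X_all + b1))) +
X_all`, and a linear layer with a sigmoid yields one score per (protein,
GO term) pair. Scores are trained with multi-label binary cross-entropy
(Adam, lr 0.001, batch 37 protein rows over a full-graph forward), and
predictions are hierarchy-aware through the ontology machinery: training
annotations are closed under the true-path rule, and Smin weights errors
by each term's information content `IC(t) = −log2 P(t | parents(t))`.

Everything runs on a small in-package reverse-mode autodiff engine over
numpy — no GPU or deep-learning framework required — which keeps the desk
scale deliberately small and every numerical step inspectable.

## Worked example

```python
import io
from magin import (FixtureSpec, build_fixture, ModelConfig, TrainConfig,
                   train, evaluate)

bundle = build_fixture(FixtureSpec(seed=0))      # 60 proteins, 24 GO terms
cfg = TrainConfig(model=ModelConfig(d1=64, d0=16, d2=256, heads=8,
                                    gin_hidden=256),
                  max_epochs=300, patience=40, seed=0)
ckpt = train(bundle, cfg, log_stream=io.StringIO())
report = evaluate(ckpt, bundle, "test")
```

prints (via `report["model"]` / `report["naive"]`):

```
best epoch: 19
fmax 0.792 (threshold 0.47)   smin 1.750   aupr 0.850   auc 0.743
naive baseline: aupr 0.827    auc 0.500
```

Reading the numbers: the synthetic bundle plants a logistic signal on
graph-smoothed node features, so the trained model separates held-out
proteins (class-centric AUC 0.743 vs the 0.500 of any constant-score
predictor) and beats the annotation-frequency Naive baseline in
micro-AUPR (0.850 vs 0.827). Smin is in bits of information content:
lower means the missed and spurious terms are semantically cheaper.

The same flow is available from a shell:

```sh
magin make-fixtures --out fx --seed 0
magin train --fixtures fx --out model.npz --d2 256
magin predict --ckpt model.npz --fixtures fx --out predictions.tsv
magin evaluate --ckpt model.npz --fixtures fx --split test --out report.json
```

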