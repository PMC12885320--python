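# Methods

## Problem setting

Protein function prediction is cast as transductive multi-label node
classification: every protein in a PPI graph receives a score in (0,1)
for every GO term of one sub-ontology (MF, BP or CC are handled as
separate models). Annotations obey the true-path rule — a protein
annotated with a term is implicitly annotated with all of the term's
`is_a`/`part_of` ancestors — so training labels are ancestor-closed
before fitting and all evaluation is performed on closed label sets.

## Ontology machinery

The OBO parser keeps `[Term]` stanzas with `is_a` and
`relationship: part_of` edges, drops obsolete terms (annotations that
reference them are dropped with a warning), and hard-fails on cycles or
unknown parents. Closures run over both relations by default; a
constructor switch restricts to `is_a`.

Information content follows the conditional-frequency convention used
with the semantic-distance metric: `IC(t) = −log2(n(t) / n(parents(t)))`
with `n(parents(t))` the number of training proteins carrying *all*
parents of `t` (total protein count for roots). The log base is a
parameter (bits by default). Terms never seen in training receive the
maximum observed IC rather than infinity so Smin stays finite. Term
depth is the BFS shortest parent-path to the namespace root.

## Encoders

**GIN.** Max aggregation over the neighborhood as stated in the layer
definition (sum is available by flag; sum is what gives GIN its
Weisfeiler–Lehman discriminative power, max is the faithful default
here). The max over an empty neighborhood is defined as the zero vector,
so isolated proteins reduce to `MLP((1+ε)x)`. ε is a learnable scalar per
layer, initialized at 0. Each layer's MLP is affine → ReLU → affine with
hidden width 1024 at reference scale. The "cross-layer" enhancement is
implemented as concatenating the raw input features to the first layer's
output (a skip connection) — the reading that type-checks with the
stated dimensions; concatenating `ÂX` instead is available via
`cross_layer="adj"`.

**GMSA.** `GCN1 → multi-head self-attention → GCN2 → LayerNorm`. The GCN
layer is `ReLU(Â H W)` with `Â = D̃^{-1/2}(A+I)D̃^{-1/2}`. The GCN1
output enters the attention block identically as query, key and value;
the block applies its own learned `d2×d2` Q/K/V projections before
splitting into 8 heads of width `d2/8` (a `projection_free` flag
reproduces the literal Q=K=V split). Attention is dense over all m nodes
— O(m²), intentional at desk scale — and head outputs are concatenated
without an output projection. GCN2 keeps the ReLU of the layer
definition by default (`gcn2_relu=False` disables it). LayerNorm is
per-node over features with learnable affine.

## Fusion head

The L term-embedding rows are mean-pooled to a single ontology context
vector, lifted `d0 → 1024 → d2` (two affine maps, ReLU between), passed
through ReLU/LayerNorm/Dropout, and broadcast to all proteins. Fusion is
elementwise addition; concatenation and learned-weight variants exist
behind flags only to mirror the fusion comparison, and ablation switches
(`use_gin`, `use_gmsa`, `use_go`) drop a branch *and* its parameters.
The residual block uses `W1 ∈ R^{d2×d2}`: the printed `d2×d1` shape in
the source description is incompatible with the residual addition that
follows, so the conforming square map is used. Scores are sigmoids of a
final `d2×L` linear layer; no hierarchy post-processing is applied by
default (an optional max-propagation postprocessor makes scores
ancestor-consistent on request).

## Training

Multi-label binary cross-entropy on sigmoid scores (computed stably from
logits), Adam at lr 0.001, batch size 37: each step runs the full-graph
forward and takes the loss on one mini-batch of protein rows — the only
reading of a fixed batch size that is consistent with a whole-graph
encoder. 256 epochs maximum, early stopping on validation loss with
patience 10, best-validation weights returned (`early_stopping=False`
runs all epochs and keeps the final weights, used for overfitting
diagnostics). One seed drives initialization, dropout and batch
shuffling; eval-mode forwards are bit-deterministic.

All tensor operations run on an in-package reverse-mode autodiff engine
(`magin.autodiff`) over float64 numpy arrays; every backward rule is
verified against central finite differences in the test suite.

## Evaluation metrics

Thresholded metrics sweep the inclusive grid {0.00, 0.01, …, 1.00}.

- **Fmax** (protein-centric): at each threshold, precision is averaged
  over proteins with ≥1 predicted term, recall over proteins with ≥1
  true term; ties in F return the smallest threshold.
- **Smin**: `min_t sqrt(ru(t)² + mi(t)²)` with ru/mi the per-protein
  average IC of missed / spurious terms. The sweep excludes t = 0, where
  every term is trivially predicted and the point carries no ranking
  information (this matches the stated behaviour of the degenerate
  all-zero-score case).
- **AUPR** is micro (pair-pooled) by the trapezoidal rule; a macro
  variant exists behind a flag.
- **Class-centric AUC** is the rank-based per-term ROC AUC (ties count
  0.5), averaged over terms with both classes present; this tie handling
  is what makes any constant-score predictor — in particular the Naive
  annotation-frequency baseline — score exactly 0.500.
- **Error strata**: per-term best-over-threshold F1, bucketed by
  training frequency (≥100 / 10–99 / <10) and depth (0–3 / 4–6 / 7–20).

## Synthetic fixtures

The generator emulates the five pipeline inputs at desk scale with
defaults m = 60 proteins, L = 24 terms over a 4-level single-root DAG,
d1 = 64, d0 = 16, edge density 0.10, β = 4, label-noise 0.02, base rate
0.30:

- **DAG**: chains plus ~40 % second-parent diamonds, valid OBO text,
  byte-identical per seed.
- **PPI**: Erdős–Rényi edges at the target density; node features are
  standard Gaussians mixed half-and-half with their one-hop
  `Â`-smoothing, so adjacent proteins are correlated (homophily).
- **Term embeddings**: each term's vector is the sum of random basis
  vectors of itself and its ancestors plus small noise, so cosine
  similarity grows with shared ancestry.
- **Labels**: per leaf term, membership is Bernoulli with logit
  `β·s + logit(base_rate)` where `s` is a per-leaf linear score of the
  node features smoothed once more over `Â` and standardized to unit
  variance (so β is a signal strength in s.d. units). Noise flips are
  applied to leaves, ancestors are then propagated, proteins are split
  70/10/20, and the draw is resampled (bounded retries) until every term
  has a training positive.

Because features and label logits share the same graph smoothing, the
graph genuinely carries signal: a held-out logistic probe on the
smoothed features recovers leaf membership well above the majority-class
rate, and a trained model beats the Naive baseline on held-out
micro-AUPR. What passing these checks does **not** show: behaviour on
real PPI networks (degree heavy-tails, confidence-weighted edges),
realistic GO DAG sizes (tens of thousands of terms), annotation sparsity
and bias, or language-model feature geometry. The full-scale benchmark
numbers of the reference setting require GPU-scale training on external
data and are out of scope here.

## Desk-scale run sizes

Reference architecture defaults (d1 = 2560, d2 = 1024, 8 heads, d0 =
128) are preserved for configuration introspection. Fitted runs in the
examples, tests and diagnostics use the fixture widths (d1 = 64,
d0 = 16) with d2 = 256 and GIN hidden width 256 — sizes chosen once so a
full train/evaluate cycle takes seconds on one CPU while keeping every
architectural element (two encoders, 8 heads, fusion, residual head)
intact. The learning-sanity diagnostic that asserts a strictly
decreasing loss curve runs full-batch with dropout disabled: with
stochastic mini-batches and dropout resampling the recorded per-epoch
loss is a noisy estimate and strict monotonicity would reflect sampling
luck rather than optimizer health. The overfitting diagnostic and the
baseline comparison keep the stochastic defaults.

## Numerical choices and degenerate inputs

- float64 throughout; Glorot-uniform initialization; LayerNorm ε = 1e-5;
  Adam (0.9, 0.999, 1e-8).
- Sigmoid/BCE computed in the stable piecewise form; BCE at ±1000 logits
  is exact.
- Empty neighborhoods aggregate to zero (GIN) or a zero mean row
  (GraphSAGE); degree-0 nodes are kept and get self-loop-only rows in Â.
- Neighbor-max gradients route to the first argmax on ties (numpy
  convention).
- Obsolete-term annotations are dropped with a warning; unknown terms
  are hard errors listing the offenders.
- Checkpoints round-trip bit-exactly through `.npz`.

## Known limitations

Dense attention and dense per-head softmax limit m to a few thousand
nodes; the autodiff engine is single-threaded numpy and has no GPU path;
the GAT variant is single-head; confidence scores on PPI edges are
accepted but ignored; bootstrap confidence intervals for the metrics are
not implemented.
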