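"""Self-contained synthetic datasets with the statistical structure the
predictor assumes.

The generator emulates the five inputs of the pipeline at desk scale: a
small single-namespace GO DAG (chain and diamond motifs over a handful of
levels), an Erdős–Rényi PPI graph, Gaussian node features smoothed over
that graph so connected proteins are correlated, ancestry-correlated
term embeddings, and hierarchy-consistent annotations whose leaf labels
follow a logistic model on the (graph-smoothed) node features.  Because
the features and the leaf-label logits are both smoothed with the same
normalized adjacency, the graph genuinely carries label signal — a graph
encoder can beat the annotation-frequency baseline on held-out proteins.

Everything is bit-reproducible from (spec, seed): each stage draws from
its own child generator of the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .graph_features import (FeatureMatrix, PpiGraph, build_graph,
                             normalized_adjacency)
from .ontology import AnnotationTable, GoDag, parse_obo, propagate


@dataclass
class FixtureSpec:
    """Knobs of the synthetic study conditions.

    ``beta`` scales the planted logistic signal in the leaf labels (0
    removes it); ``noise_rate`` flips leaf labels before propagation;
    ``base_rate`` is the marginal leaf-positive probability at beta = 0.
    The reduced widths (d1 = 64, d0 = 16) keep desk-scale runs fast;
    full-scale widths remain ordinary parameter values.
    """

    n_proteins: int = 60
    n_terms: int = 24
    n_levels: int = 4
    d1: int = 64
    d0: int = 16
    edge_density: float = 0.10
    beta: float = 4.0
    noise_rate: float = 0.02
    base_rate: float = 0.30
    feature_smoothing: float = 0.5
    seed: int = 0

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def protein_ids(spec: FixtureSpec) -> list[str]:
    return [f"P{i:04d}" for i in range(spec.n_proteins)]


# -- ontology -----------------------------------------------------------------

def make_toy_dag(spec: FixtureSpec) -> str:
    """OBO text for a single-namespace DAG with one root.

    Terms are laid out over ``n_levels`` levels below the root; every
    non-root term has one parent on the previous level (chains) and, with
    probability 0.4, a second parent on any shallower level (diamonds).
    """
    if spec.n_terms < 4:
        raise ValueError("need at least 4 terms")
    rng = spec.rng(1)
    ids = [f"GO:{i + 1:07d}" for i in range(spec.n_terms)]
    levels = [0] + [1 + (i - 1) % spec.n_levels
                    for i in range(1, spec.n_terms)]
    by_level: dict[int, list[int]] = {}
    for i, lv in enumerate(levels):
        by_level.setdefault(lv, []).append(i)
    parents: dict[int, list[int]] = {0: []}
    for i in range(1, spec.n_terms):
        lv = levels[i]
        prev = by_level.get(lv - 1) or [0]
        ps = [int(rng.choice(prev))]
        if lv >= 2 and rng.random() < 0.4:
            shallower = [j for j in range(spec.n_terms)
                         if levels[j] < lv and j not in ps]
            extra = int(rng.choice(shallower))
            ps.append(extra)
        parents[i] = ps
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for i, tid in enumerate(ids):
        lines += ["[Term]", f"id: {tid}", f"name: toy term {i}",
                  "namespace: biological_process"]
        for p in parents[i]:
            lines.append(f"is_a: {ids[p]} ! toy term {p}")
        lines.append("")
    return "\n".join(lines)


# -- PPI graph ----------------------------------------------------------------

def make_ppi(spec: FixtureSpec) -> tuple[list[tuple[str, str]], FeatureMatrix]:
    """Erdős–Rényi edges plus graph-smoothed Gaussian node features."""
    if spec.n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = spec.rng(2)
    ids = protein_ids(spec)
    m = spec.n_proteins
    iu = np.triu_indices(m, k=1)
    mask = rng.random(len(iu[0])) < spec.edge_density
    edges = [(ids[int(a)], ids[int(b)])
             for a, b in zip(iu[0][mask], iu[1][mask])]
    Z = rng.standard_normal((m, spec.d1))
    feats = FeatureMatrix(ids, Z)
    graph = build_graph(edges, feats)
    Ahat = normalized_adjacency(graph)
    rho = spec.feature_smoothing
    X = (1 - rho) * Z + rho * (Ahat @ Z)
    return edges, FeatureMatrix(ids, X)


# -- term embeddings ----------------------------------------------------------

def make_term_embeddings(spec: FixtureSpec, dag: GoDag) -> FeatureMatrix:
    """Ancestry-sum embeddings: each term's vector is the sum of random
    basis vectors of itself and its ancestors, plus a small noise term, so
    cosine similarity grows with shared ancestry."""
    rng = spec.rng(3)
    terms = sorted(dag.terms)
    basis = {t: rng.standard_normal(spec.d0) / np.sqrt(spec.d0)
             for t in terms}
    rows = []
    for t in terms:
        v = basis[t].copy()
        for a in dag.ancestors(t):
            v += basis[a]
        v += 0.1 * rng.standard_normal(spec.d0)
        rows.append(v)
    return FeatureMatrix(terms, np.array(rows))


# -- labels -------------------------------------------------------------------

def _leaves(dag: GoDag) -> list[str]:
    has_child: set[str] = set()
    for t in dag.terms.values():
        for p, _ in t.parents:
            has_child.add(p)
    return sorted(t for t in dag.terms if t not in has_child)


def make_labels(spec: FixtureSpec, dag: GoDag, graph: PpiGraph,
                max_retries: int = 20
                ) -> tuple[AnnotationTable, dict[str, list[str]]]:
    """Hierarchy-consistent annotations with a planted, graph-coupled signal.

    Per leaf term, a logistic model on the node features (logits smoothed
    once over the normalized adjacency, scaled by ``beta``) draws protein
    membership; noise flips are applied to the leaf labels, ancestors are
    then propagated, and proteins are split 70/10/20.  Resamples up to
    ``max_retries`` times until every DAG term has a training positive.
    """
    rng = spec.rng(4)
    ids = graph.node_ids
    m = graph.m
    Ahat = normalized_adjacency(graph)
    leaves = _leaves(dag)
    b0 = np.log(spec.base_rate / (1 - spec.base_rate))
    for _ in range(max_retries):
        order = rng.permutation(m)
        n_train = int(round(0.7 * m))
        n_valid = int(round(0.1 * m))
        splits = {
            "train": sorted(ids[i] for i in order[:n_train]),
            "valid": sorted(ids[i] for i in order[n_train:n_train + n_valid]),
            "test": sorted(ids[i] for i in order[n_train + n_valid:]),
        }
        pairs: list[tuple[str, str]] = []
        for leaf in leaves:
            w = rng.standard_normal(graph.d) / np.sqrt(graph.d)
            s = Ahat @ (graph.X @ w)         # couple the signal to the graph
            sd = s.std()
            if sd > 0:
                s = s / sd                   # beta is in s.d. units of signal
            p = 1.0 / (1.0 + np.exp(-(spec.beta * s + b0)))
            y = rng.random(m) < p
            flips = rng.random(m) < spec.noise_rate
            y = y ^ flips
            pairs += [(ids[i], leaf) for i in np.nonzero(y)[0]]
        ann = propagate(dag, AnnotationTable(pairs))
        train_ann = ann.restrict(splits["train"])
        covered = train_ann.terms()
        if all(t in covered for t in dag.terms):
            return ann, splits
    raise RuntimeError(
        f"could not cover every term with a training positive in "
        f"{max_retries} attempts; raise base_rate or n_proteins")


# -- bundle I/O ---------------------------------------------------------------

@dataclass
class FixtureBundle:
    spec: FixtureSpec
    dag: GoDag
    graph: PpiGraph
    term_embeddings: FeatureMatrix
    annotations: AnnotationTable          # propagated
    splits: dict[str, list[str]]

    @property
    def terms(self) -> list[str]:
        return sorted(self.dag.terms)

    def truth_matrix(self, proteins: list[str]) -> np.ndarray:
        terms = self.terms
        M = np.zeros((len(proteins), len(terms)), dtype=int)
        for i, p in enumerate(proteins):
            ts = self.annotations.by_protein.get(p, ())
            for j, t in enumerate(terms):
                if t in ts:
                    M[i, j] = 1
        return M


def build_fixture(spec: FixtureSpec, outdir=None) -> FixtureBundle:
    """Generate the full bundle; optionally write it to *outdir* in the
    exact on-disk formats the pipeline reads."""
    import tempfile

    obo_text = make_toy_dag(spec)
    if outdir is None:
        with tempfile.NamedTemporaryFile(
                "w", suffix=".obo", delete=False) as fh:
            fh.write(obo_text)
            obo_path = fh.name
        dag = parse_obo(obo_path)
        Path(obo_path).unlink()
    else:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        obo_path = outdir / "ontology.obo"
        obo_path.write_text(obo_text)
        dag = parse_obo(obo_path)

    edges, feats = make_ppi(spec)
    graph = build_graph(edges, feats)
    emb = make_term_embeddings(spec, dag)
    ann, splits = make_labels(spec, dag, graph)
    bundle = FixtureBundle(spec, dag, graph, emb, ann, splits)

    if outdir is not None:
        with open(outdir / "edges.tsv", "w", encoding="utf-8") as fh:
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        feats.to_tsv(outdir / "features.tsv")
        emb.to_tsv(outdir / "term_embeddings.tsv")
        ann.to_tsv(outdir / "annotations.tsv")
        for name, prots in splits.items():
            (outdir / f"{name}.txt").write_text(
                "".join(p + "\n" for p in prots))
        (outdir / "fixture_spec.json").write_text(
            json.dumps(asdict(spec), indent=1) + "\n")
    return bundle


def load_fixture(indir) -> FixtureBundle:
    """Load a bundle previously written by :func:`build_fixture`."""
    indir = Path(indir)
    spec = FixtureSpec(**json.loads(
        (indir / "fixture_spec.json").read_text()))
    dag = parse_obo(indir / "ontology.obo")
    feats = FeatureMatrix.from_tsv(indir / "features.tsv")
    graph = build_graph(indir / "edges.tsv", feats)
    emb = FeatureMatrix.from_tsv(indir / "term_embeddings.tsv")
    ann = AnnotationTable.from_tsv(indir / "annotations.tsv")
    ann = propagate(dag, ann)
    splits = {name: (indir / f"{name}.txt").read_text().split()
              for name in ("train", "valid", "test")}
    return FixtureBundle(spec, dag, graph, emb, ann, splits)
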