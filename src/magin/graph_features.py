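"""PPI graph construction and the node-feature / term-embedding containers.

Proteins are nodes; physical or functional interactions are undirected
edges.  Node features are precomputed sequence embeddings (e.g. mean-pooled
per-residue vectors from a protein language model) supplied as a dense
matrix keyed by protein id.  GO-term embeddings arrive the same way, keyed
by term accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


def mean_pool(B: np.ndarray) -> np.ndarray:
    """Column-wise mean of a residue-embedding matrix (M residues x d1).

    This is the pooling that turns per-residue language-model embeddings
    into a single per-protein feature vector.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] < 1:
        raise ValueError("residue embedding must be a non-empty M x d matrix")
    if not np.all(np.isfinite(B)):
        raise ValueError("residue embedding contains non-finite entries")
    return B.mean(axis=0)


@dataclass
class FeatureMatrix:
    """Dense float matrix with a row-id index (proteins or GO terms)."""

    ids: list[str]
    X: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("id list and matrix row count disagree")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def row(self, id_: str) -> np.ndarray:
        return self.X[self._index[id_]]

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def subset(self, ids) -> "FeatureMatrix":
        idx = [self._index[i] for i in ids]
        return FeatureMatrix(list(ids), self.X[idx])

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    # -- I/O: whitespace TSV (id first column) and npz container ------------

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        ids, rows = [], []
        with open(path, encoding="utf-8") as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                try:
                    rows.append([float(x) for x in parts[1:]])
                except ValueError as e:
                    raise ValueError(f"{path}: malformed line {ln}") from e
                ids.append(parts[0])
        return cls(ids, np.array(rows, dtype=float))

    def to_tsv(self, path, fmt: str = "%.8g") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, id_ in enumerate(self.ids):
                fh.write(id_ + "\t" + "\t".join(fmt % v for v in self.X[i]) + "\n")

    @classmethod
    def from_npz(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls([str(s) for s in z["ids"]], z["X"])

    def to_npz(self, path) -> None:
        np.savez(path, ids=np.array(self.ids), X=self.X)


#: GO-term embedding matrix: identical container, kept as a domain alias.
TermEmbeddings = FeatureMatrix


class PpiGraph:
    """Undirected protein graph with an aligned node-feature matrix.

    Node order is the insertion order of ``node_ids``; edges are stored as
    a deduplicated set of index pairs (i < j), with no self-loops (the
    self-connection enters only through adjacency normalization).
    """

    def __init__(self, node_ids: list[str], edges, features: np.ndarray):
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("duplicate node ids")
        self.node_ids = list(node_ids)
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        self.X = np.asarray(features, dtype=float)
        if self.X.shape[0] != len(node_ids):
            raise ValueError("feature rows do not match node count")
        es = set()
        for a, b in edges:
            if a == b:
                continue
            i, j = sorted((a, b))
            es.add((i, j))
        self.edges = sorted(es)

    @property
    def m(self) -> int:
        return len(self.node_ids)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric binary adjacency without self-loops (sparse CSR)."""
        if not self.edges:
            return sp.csr_matrix((self.m, self.m))
        rows = [i for i, j in self.edges] + [j for i, j in self.edges]
        cols = [j for i, j in self.edges] + [i for i, j in self.edges]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.m, self.m))

    def neighbor_lists(self) -> list[np.ndarray]:
        nbrs: list[list[int]] = [[] for _ in range(self.m)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(n), dtype=int) for n in nbrs]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.m, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def permute(self, perm: np.ndarray) -> "PpiGraph":
        """Relabelled copy: new node k is old node perm[k]."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        ids = [self.node_ids[p] for p in perm]
        edges = [(int(inv[i]), int(inv[j])) for i, j in self.edges]
        return PpiGraph(ids, edges, self.X[perm])


def read_edge_tsv(path) -> list[tuple[str, str]]:
    """Read `protein_a<TAB>protein_b[<TAB>score]` lines; score ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ValueError(f"{path}: malformed edge line {ln}: {line!r}")
            out.append((cols[0], cols[1]))
    return out


def build_graph(edges, features: FeatureMatrix) -> PpiGraph:
    """Assemble the PPI graph over the union of edge endpoints and feature ids.

    Every endpoint must have a feature row; proteins that appear only in the
    feature matrix are retained as isolated (degree-0) nodes so that they
    still receive predictions.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "__fspath__"):
        edges = read_edge_tsv(edges)
    missing = sorted({p for e in edges for p in e if p not in features})
    if missing:
        raise ValueError(f"edge endpoints without features: {missing}")
    node_ids = list(features.ids)
    index = {n: i for i, n in enumerate(node_ids)}
    idx_edges = [(index[a], index[b]) for a, b in edges]
    return PpiGraph(node_ids, idx_edges, features.X)


def normalized_adjacency(g: PpiGraph) -> sp.csr_matrix:
    """Symmetric-normalized adjacency with self-connections.

    A_hat = D~^{-1/2} (A + I) D~^{-1/2} with D~_ii the row sums of A + I.
    The self-loop guarantees every degree is at least one, so the inverse
    square root is always defined; the spectral radius is at most 1.
    """
    if g.m < 1:
        raise ValueError("empty graph")
    At = g.adjacency() + sp.identity(g.m, format="csr")
    dinv = 1.0 / np.sqrt(np.asarray(At.sum(axis=1)).ravel())
    D = sp.diags(dinv)
    return (D @ At @ D).tocsr()
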