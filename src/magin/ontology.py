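"""Gene Ontology machinery: OBO parsing, ancestor closure, true-path
propagation, information content and term depths.

The ontology is modelled as a directed acyclic graph whose nodes are GO
terms and whose edges point from a term to its ``is_a`` / ``part_of``
parents.  Annotating a protein with a term implies annotation with every
ancestor of that term (the true-path rule); most of this module exists to
make that closure, and the statistics derived from it, explicit and
testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

log = logging.getLogger(__name__)

NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

#: Parent relations traversed by default (GO true-path practice).
DEFAULT_RELATIONS = ("is_a", "part_of")


@dataclass
class GoTerm:
    """A single GO term with its parent edges."""

    id: str
    name: str = ""
    namespace: str = ""
    #: list of (parent id, relation) with relation in {"is_a", "part_of"}
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False


class GoDag:
    """Parsed ontology: term map, namespace roots and ancestor queries.

    Parameters
    ----------
    terms
        Mapping from GO accession to :class:`GoTerm`.  Obsolete terms must
        already have been removed.
    relations
        Which parent relations participate in closures; defaults to
        ``("is_a", "part_of")``.
    """

    def __init__(self, terms: dict[str, GoTerm],
                 relations: Iterable[str] = DEFAULT_RELATIONS):
        self.terms = terms
        self.relations = tuple(relations)
        self._validate()
        self.roots = tuple(sorted(
            t.id for t in terms.values() if not self._parent_ids(t.id)))
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _parent_ids(self, tid: str) -> list[str]:
        return [p for p, rel in self.terms[tid].parents
                if rel in self.relations]

    def _validate(self) -> None:
        for t in self.terms.values():
            for pid, rel in t.parents:
                if pid not in self.terms:
                    raise ValueError(
                        f"term {t.id} has unknown parent {pid} ({rel})")
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        u, v = cycle[0][0], cycle[0][1]
        raise ValueError(f"ontology graph is cyclic: edge {u} -> {v}")

    def to_networkx(self) -> nx.DiGraph:
        """Child -> parent digraph over the configured relations."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for pid, rel in t.parents:
                if rel in self.relations:
                    g.add_edge(t.id, pid, relation=rel)
        return g

    # -- queries --------------------------------------------------------------

    def __contains__(self, tid: str) -> bool:
        return tid in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def edge_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.terms.values():
            for _, rel in t.parents:
                counts[rel] = counts.get(rel, 0) + 1
        return counts

    def ancestors(self, tid: str) -> frozenset[str]:
        """Transitive parents of *tid* (excluding *tid* itself)."""
        if tid not in self.terms:
            raise KeyError(f"unknown term {tid}")
        cached = self._anc_cache.get(tid)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self._parent_ids(tid))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self._parent_ids(p))
        res = frozenset(out)
        self._anc_cache[tid] = res
        return res

    def namespace_terms(self, ns: str) -> list[str]:
        return sorted(t.id for t in self.terms.values() if t.namespace == ns)


def ancestors(dag: GoDag, term: str) -> frozenset[str]:
    """Module-level alias for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term)


# -- OBO parsing --------------------------------------------------------------

def parse_obo(path) -> GoDag:
    """Parse an OBO 1.2 flat file into a :class:`GoDag`.

    Only ``[Term]`` stanzas are read; ``is_a`` and ``relationship: part_of``
    parent edges are retained.  Obsolete terms are dropped entirely (their
    ids are remembered so that annotations referencing them can be warned
    about downstream).  Raises ``ValueError`` on cycles or unknown parents.
    """
    terms: dict[str, GoTerm] = {}
    obsolete: set[str] = set()
    cur: GoTerm | None = None
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                if cur is not None:
                    _commit(cur, terms, obsolete)
                    cur = None
                in_term = line == "[Term]"
                if in_term:
                    cur = GoTerm(id="")
                continue
            if not in_term or cur is None or not line or line.startswith("!"):
                continue
            if ":" not in line:
                continue
            key, _, val = line.partition(":")
            val = val.split("!")[0].strip()
            key = key.strip()
            if key == "id":
                cur.id = val
            elif key == "name":
                cur.name = val
            elif key == "namespace":
                cur.namespace = NAMESPACES.get(val, val)
            elif key == "is_a":
                cur.parents.append((val.split()[0], "is_a"))
            elif key == "relationship":
                parts = val.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    cur.parents.append((parts[1], "part_of"))
            elif key == "is_obsolete" and val.lower() == "true":
                cur.obsolete = True
    if cur is not None:
        _commit(cur, terms, obsolete)
    dag = GoDag(terms)
    dag.obsolete_ids = frozenset(obsolete)  # type: ignore[attr-defined]
    return dag


def _commit(term: GoTerm, terms: dict[str, GoTerm], obsolete: set[str]) -> None:
    if not term.id:
        raise ValueError("[Term] stanza without an id")
    if term.obsolete:
        obsolete.add(term.id)
        return
    terms[term.id] = term


# -- annotations --------------------------------------------------------------

class AnnotationTable:
    """Deduplicated (protein id, term id) pairs, optionally ancestor-closed."""

    def __init__(self, pairs: Iterable[tuple[str, str]], propagated: bool = False):
        by_protein: dict[str, set[str]] = {}
        for p, t in pairs:
            by_protein.setdefault(p, set()).add(t)
        self.by_protein = by_protein
        self.propagated = propagated

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for i, raw in enumerate(fh, 1):
                line = raw.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                cols = line.split("\t")
                if i == 1 and cols[:2] == ["protein_id", "go_id"]:
                    continue
                if len(cols) < 2:
                    raise ValueError(f"{path}: malformed line {i}: {line!r}")
                pairs.append((cols[0], cols[1]))
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for p in sorted(self.by_protein):
                for t in sorted(self.by_protein[p]):
                    fh.write(f"{p}\t{t}\n")

    def pairs(self) -> list[tuple[str, str]]:
        return [(p, t) for p in sorted(self.by_protein)
                for t in sorted(self.by_protein[p])]

    def proteins(self) -> list[str]:
        return sorted(self.by_protein)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.by_protein.values():
            out |= ts
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_protein.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        p, t = pair
        return t in self.by_protein.get(p, ())

    def restrict(self, proteins: Iterable[str]) -> "AnnotationTable":
        keep = set(proteins)
        out = AnnotationTable([], propagated=self.propagated)
        out.by_protein = {p: set(ts) for p, ts in self.by_protein.items()
                          if p in keep}
        return out


def propagate(dag: GoDag, ann: AnnotationTable) -> AnnotationTable:
    """Close an annotation table under the true-path rule.

    Every (protein, term) pair gains (protein, ancestor) for all ancestors
    of the term.  Terms absent from the DAG raise; terms the DAG recorded
    as obsolete are dropped with a warning instead.
    """
    obsolete = getattr(dag, "obsolete_ids", frozenset())
    unknown = sorted(t for t in ann.terms()
                     if t not in dag and t not in obsolete)
    if unknown:
        raise ValueError(f"annotation references unknown terms: {unknown}")
    out: dict[str, set[str]] = {}
    dropped = 0
    for p, terms in ann.by_protein.items():
        closed: set[str] = set()
        for t in terms:
            if t in obsolete:
                dropped += 1
                continue
            closed.add(t)
            closed |= dag.ancestors(t)
        out[p] = closed
    if dropped:
        log.warning("dropped %d annotations to obsolete terms", dropped)
    res = AnnotationTable([], propagated=True)
    res.by_protein = out
    return res


# -- information content ------------------------------------------------------

def information_content(dag: GoDag, train_ann: AnnotationTable,
                        base: float = 2.0) -> dict[str, float]:
    """Per-term information content from training annotation frequencies.

    IC(t) = -log_base( n(t) / n(parents(t)) ) where n(t) counts training
    proteins annotated with t and n(parents(t)) counts proteins annotated
    with *all* parents of t (for roots: the total protein count).  Terms
    never seen in training receive the maximum observed IC so that the
    semantic-distance metric built on top stays finite.
    """
    if len(train_ann) == 0:
        raise ValueError("empty training annotation table")
    if not train_ann.propagated:
        raise ValueError("training annotations must be propagated first")
    n_total = len(train_ann.by_protein)
    protein_terms = list(train_ann.by_protein.values())
    counts = {tid: 0 for tid in dag.terms}
    for terms in protein_terms:
        for t in terms:
            if t in counts:
                counts[t] += 1
    ic: dict[str, float] = {}
    missing: list[str] = []
    for tid in dag.terms:
        c = counts[tid]
        if c == 0:
            missing.append(tid)
            continue
        parents = dag._parent_ids(tid)
        if parents:
            pset = set(parents)
            denom = sum(1 for terms in protein_terms if pset <= terms)
        else:
            denom = n_total
        # propagation guarantees c <= denom
        ic[tid] = -math.log(c / denom) / math.log(base)
    max_ic = max(ic.values(), default=0.0)
    for tid in missing:
        ic[tid] = max_ic
    return ic


def term_depths(dag: GoDag) -> dict[str, int]:
    """Shortest parent-path length from each term to its namespace root.

    Computed by breadth-first search from the roots over reversed parent
    edges; roots have depth 0.
    """
    g = dag.to_networkx().reverse(copy=False)
    depths: dict[str, int] = {}
    for root in dag.roots:
        for tid, d in nx.single_source_shortest_path_length(g, root).items():
            if tid not in depths or d < depths[tid]:
                depths[tid] = d
    return depths
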