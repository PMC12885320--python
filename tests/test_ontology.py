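"""Ontology machinery: OBO parsing, closures, true-path propagation,
information content and depths, each against exhaustive oracles."""

import math

import numpy as np
import pytest

from magin.ontology import (AnnotationTable, GoDag, GoTerm, ancestors,
                            information_content, parse_obo, propagate,
                            term_depths)

from conftest import make_chain_dag, make_diamond_dag, random_dag

OBO_3TERM = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: grandchild
namespace: biological_process
is_a: GO:0000002 ! child
"""


def dfs_ancestors(dag: GoDag, tid: str) -> set:
    """Independent oracle: exhaustive DFS over parent edges."""
    out = set()

    def walk(t):
        for p, _ in dag.terms[t].parents:
            if p not in out:
                out.add(p)
                walk(p)
    walk(tid)
    return out


class TestParseObo:
    def test_three_term_chain(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text(OBO_3TERM)
        dag = parse_obo(p)
        assert len(dag) == 3
        assert dag.roots == ("GO:0000001",)
        assert dag.terms["GO:0000003"].parents == [("GO:0000002", "is_a")]

    def test_multiple_parents_and_part_of(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text(OBO_3TERM + """
[Term]
id: GO:0000004
name: multi
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000003
""")
        dag = parse_obo(p)
        assert sorted(dag.terms["GO:0000004"].parents) == [
            ("GO:0000002", "is_a"), ("GO:0000003", "part_of")]
        assert dag.edge_counts() == {"is_a": 3, "part_of": 1}

    def test_obsolete_excluded(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text(OBO_3TERM + """
[Term]
id: GO:0000009
name: dead
namespace: biological_process
is_obsolete: true
""")
        dag = parse_obo(p)
        assert "GO:0000009" not in dag
        assert "GO:0000009" in dag.obsolete_ids

    def test_cycle_is_hard_error(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text("""[Term]
id: GO:0000001
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000002
namespace: biological_process
is_a: GO:0000001
""")
        with pytest.raises(ValueError, match="cyclic"):
            parse_obo(p)

    def test_unknown_parent_is_hard_error(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text("""[Term]
id: GO:0000001
namespace: biological_process
is_a: GO:0009999
""")
        with pytest.raises(ValueError, match="unknown parent"):
            parse_obo(p)

    def test_agrees_with_obonet(self, tmp_path):
        """Independent parser cross-check on the same file."""
        obonet = pytest.importorskip("obonet")
        p = tmp_path / "t.obo"
        p.write_text(OBO_3TERM)
        theirs = obonet.read_obo(p)
        dag = parse_obo(p)
        assert set(dag.terms) == set(theirs.nodes)
        for t in dag.terms.values():
            theirs_parents = set(theirs.successors(t.id))
            assert {p for p, r in t.parents if r == "is_a"} == theirs_parents


class TestAncestors:
    def test_root_has_none(self):
        dag = make_chain_dag(3)
        assert ancestors(dag, "GO:0000001") == frozenset()

    def test_chain(self):
        dag = make_chain_dag(3)
        assert ancestors(dag, "GO:0000003") == {"GO:0000001", "GO:0000002"}

    def test_diamond_vs_dfs_oracle(self):
        dag = make_diamond_dag()
        assert ancestors(dag, "GO:0000004") == {
            "GO:0000001", "GO:0000002", "GO:0000003"}
        for t in dag.terms:
            assert ancestors(dag, t) == dfs_ancestors(dag, t)

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError):
            ancestors(make_chain_dag(3), "GO:0099999")

    @pytest.mark.parametrize("seed", range(10))
    def test_random_dags_vs_dfs_oracle(self, seed):
        dag = random_dag(np.random.default_rng(seed), 15)
        for t in dag.terms:
            assert ancestors(dag, t) == dfs_ancestors(dag, t)

    def test_nesting_through_parents(self):
        """ancestors(t) contains ancestors(p) + {p} for every parent p,
        and equals their union over all parents."""
        dag = random_dag(np.random.default_rng(3), 20)
        for t in dag.terms.values():
            union = set()
            for p, _ in t.parents:
                assert ancestors(dag, t.id) >= ancestors(dag, p) | {p}
                union |= ancestors(dag, p) | {p}
            assert ancestors(dag, t.id) == union


class TestPropagate:
    def test_chain_fills_ancestors(self, chain_ann):
        dag, ann = chain_ann
        out = propagate(dag, ann)
        assert out.propagated
        assert out.by_protein["p1"] == {
            "GO:0000001", "GO:0000002", "GO:0000003"}

    def test_idempotent_and_monotone(self, chain_ann):
        dag, ann = chain_ann
        once = propagate(dag, ann)
        twice = propagate(dag, once)
        assert once.by_protein == twice.by_protein
        for p, ts in ann.by_protein.items():
            assert ts <= once.by_protein[p]

    def test_diamond_shared_ancestor_once(self):
        dag = make_diamond_dag()
        out = propagate(dag, AnnotationTable([("p1", "GO:0000004")]))
        # set-union oracle over per-term closures
        expect = {"GO:0000004"} | dfs_ancestors(dag, "GO:0000004")
        assert out.by_protein["p1"] == expect
        assert len(out) == len(expect)

    def test_unknown_term_lists_offenders(self):
        dag = make_chain_dag(3)
        with pytest.raises(ValueError, match="GO:0099999"):
            propagate(dag, AnnotationTable([("p1", "GO:0099999")]))


class TestInformationContent:
    def five_protein_table(self):
        """root annotated in all 5, mid in 4, leaf in 2 of those 4."""
        dag = make_chain_dag(3)
        root, mid, leaf = sorted(dag.terms)
        rows = ([(f"p{i}", root) for i in range(5)]
                + [(f"p{i}", mid) for i in range(4)]
                + [(f"p{i}", leaf) for i in range(2)])
        return dag, propagate(dag, AnnotationTable(rows))

    def test_hand_counted_values(self):
        dag, ann = self.five_protein_table()
        ic = information_content(dag, ann)
        assert ic["GO:0000001"] == pytest.approx(0.0)          # 5/5
        assert ic["GO:0000002"] == pytest.approx(-math.log2(4 / 5))
        assert ic["GO:0000003"] == pytest.approx(1.0)          # 2/4 -> 1 bit

    def test_zero_count_term_gets_max_ic(self):
        dag = make_chain_dag(4)
        ids = sorted(dag.terms)
        ann = propagate(dag, AnnotationTable(
            [("p1", ids[2]), ("p2", ids[1]), ("p3", ids[1]), ("p4", ids[0])]))
        ic = information_content(dag, ann)
        observed = [v for t, v in ic.items() if t != ids[3]]
        assert ic[ids[3]] == pytest.approx(max(observed))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            information_content(make_chain_dag(3), AnnotationTable(
                [], propagated=True))

    def test_unpropagated_raises(self):
        dag = make_chain_dag(3)
        with pytest.raises(ValueError, match="propagated"):
            information_content(dag, AnnotationTable([("p1", "GO:0000001")]))

    def test_more_annotations_never_raise_ic(self):
        """IC is non-increasing when the term gains annotated proteins
        (parents' counts held fixed by annotating already-covered ones)."""
        dag, ann = self.five_protein_table()
        ic0 = information_content(dag, ann)["GO:0000003"]
        extra = AnnotationTable([], propagated=True)
        extra.by_protein = {p: set(ts) for p, ts in ann.by_protein.items()}
        extra.by_protein["p2"].add("GO:0000003")  # p2 already had the parent
        ic1 = information_content(dag, extra)["GO:0000003"]
        assert ic1 <= ic0

    def test_nats_base(self):
        dag, ann = self.five_protein_table()
        ic = information_content(dag, ann, base=math.e)
        assert ic["GO:0000003"] == pytest.approx(math.log(2.0))


class TestTermDepths:
    def test_root_and_chain(self):
        dag = make_chain_dag(4)
        d = term_depths(dag)
        assert [d[t] for t in sorted(dag.terms)] == [0, 1, 2, 3]

    def test_shortest_path_wins(self):
        """Node reachable at depth 2 via one branch and 5 via another."""
        ids = [f"GO:{i:07d}" for i in range(1, 9)]
        terms = {ids[0]: GoTerm(ids[0], "root", "BP")}
        for i in range(1, 6):  # long chain ids[1..5]
            terms[ids[i]] = GoTerm(ids[i], "", "BP",
                                   parents=[(ids[i - 1], "is_a")])
        terms[ids[6]] = GoTerm(ids[6], "", "BP", parents=[(ids[0], "is_a")])
        terms[ids[7]] = GoTerm(ids[7], "", "BP",
                               parents=[(ids[6], "is_a"), (ids[5], "is_a")])
        d = term_depths(GoDag(terms))
        assert d[ids[7]] == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_vs_exhaustive_path_enumeration(self, seed):
        import networkx as nx
        dag = random_dag(np.random.default_rng(seed), 12)
        g = dag.to_networkx()

        def all_path_min(t):
            if t == dag.roots[0]:
                return 0
            return min(len(p) - 1 for p in nx.all_simple_paths(
                g, t, dag.roots[0]))
        d = term_depths(dag)
        for t in dag.terms:
            assert d[t] == all_path_min(t)
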