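import numpy as np
import pytest

from magin.fixtures import FixtureSpec, build_fixture
from magin.ontology import AnnotationTable, GoDag, GoTerm


def make_chain_dag(n: int = 3) -> GoDag:
    """root <- t1 <- ... <- t(n-1), single namespace."""
    terms = {}
    ids = [f"GO:{i + 1:07d}" for i in range(n)]
    terms[ids[0]] = GoTerm(ids[0], "root", "BP")
    for i in range(1, n):
        terms[ids[i]] = GoTerm(ids[i], f"t{i}", "BP",
                               parents=[(ids[i - 1], "is_a")])
    return GoDag(terms)


def make_diamond_dag() -> GoDag:
    """a <- b, a <- c, d is_a b and c."""
    a, b, c, d = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"
    return GoDag({
        a: GoTerm(a, "a", "BP"),
        b: GoTerm(b, "b", "BP", parents=[(a, "is_a")]),
        c: GoTerm(c, "c", "BP", parents=[(a, "is_a")]),
        d: GoTerm(d, "d", "BP", parents=[(b, "is_a"), (c, "is_a")]),
    })


def random_dag(rng: np.random.Generator, n: int) -> GoDag:
    """Random single-root DAG: term i>0 gets 1-2 parents among 0..i-1."""
    ids = [f"GO:{i + 1:07d}" for i in range(n)]
    terms = {ids[0]: GoTerm(ids[0], "root", "BP")}
    for i in range(1, n):
        k = 1 + int(rng.random() < 0.4 and i > 1)
        ps = rng.choice(i, size=min(k, i), replace=False)
        terms[ids[i]] = GoTerm(ids[i], f"t{i}", "BP",
                               parents=[(ids[int(p)], "is_a") for p in ps])
    return GoDag(terms)


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted-signal fixture (60 proteins, 24 terms, seed 0)."""
    return build_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def small_model_config():
    """Desk-scale model dims shared across training tests."""
    return dict(d1=64, d0=16, d2=256, heads=8, gin_hidden=256)


@pytest.fixture
def chain_ann():
    dag = make_chain_dag(3)
    ids = sorted(dag.terms)
    return dag, AnnotationTable([("p1", ids[2])])
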