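import io

import pytest

from phenomap.annotations import AnnotationSet
from phenomap.ontology import OntologyDAG, Term, parse_obo

CHAIN_OBO = """format-version: 1.2
ontology: toy

[Term]
id: HP:0000001
name: a

[Term]
id: HP:0000002
name: b
is_a: HP:0000001

[Term]
id: HP:0000003
name: c
is_a: HP:0000002
"""


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """Three-term chain c is_a b is_a a."""
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def flat_dag() -> OntologyDAG:
    """One root with three leaf children a, b, c (plus a spare d)."""
    terms = {
        "HP:0000001": Term(name="root"),
        "HP:0000002": Term(name="a"),
        "HP:0000003": Term(name="b"),
        "HP:0000004": Term(name="c"),
        "HP:0000005": Term(name="d"),
    }
    edges = {(tid, "HP:0000001", "is_a") for tid in list(terms)[1:]}
    return OntologyDAG(terms, edges)


def random_corpora(seed: int, n_genes: int = 200, n_hpo: int = 50, n_go: int = 80,
                   rate: float = 0.02) -> tuple[AnnotationSet, AnnotationSet]:
    """Unstructured random annotation corpora over a shared gene universe."""
    import numpy as np

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    hpo = {
        (genes[g], f"HP:{t + 1:07d}")
        for g, t in zip(*np.nonzero(rng.random((n_genes, n_hpo)) < rate))
    }
    go = {
        (genes[g], f"GO:{t + 1:07d}")
        for g, t in zip(*np.nonzero(rng.random((n_genes, n_go)) < rate))
    }
    return AnnotationSet(hpo, namespace="HPO"), AnnotationSet(go, namespace="GO")
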