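"""Synthetic annotation corpora with planted cross-ontology signal.

The generator emulates the statistical structure the mapping method relies
on: a shared gene universe where some HPO-GO term pairs are co-annotated on
the same genes (planted signal) on top of independent Bernoulli background
annotations.  Planted pairs should survive threshold selection; background
pairs, which co-occur only by chance, should be filtered out.  All
generators are pure functions of their configuration, so fixtures are
byte-reproducible per seed and never shipped as data files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, NamedTuple, Sequence

import numpy as np

from .annotations import AnnotationSet
from .evaluation import BenchmarkSet
from .ontology import OntologyDAG, Term, TermInformationContent, information_content, propagate_annotations
from .prediction import Prediction, PredictionSet


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the planted-signal corpus.

    Defaults size the corpus like a sparse desk-scale annotation snapshot:
    1,000 genes, 150 phenotype and 200 function terms, 50 planted
    co-annotated pairs seeded on 3-6 genes each, and a 0.002 per-(gene, term)
    background annotation probability (about two background annotations per
    term on average).
    """

    n_genes: int = 1000
    n_hpo_terms: int = 150
    n_go_terms: int = 200
    n_planted_pairs: int = 50
    planted_coannotation_range: tuple[int, int] = (3, 6)
    background_rate: float = 0.002
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.planted_coannotation_range
        if lo < 1 or hi < lo:
            raise ValueError("planted_coannotation_range must satisfy 1 <= min <= max")
        if not (0 <= self.background_rate < 1):
            raise ValueError("background_rate must lie in [0, 1)")
        for name in ("n_genes", "n_hpo_terms", "n_go_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_planted_pairs < 0:
            raise ValueError("n_planted_pairs must be >= 0 (0 = pure-noise corpus)")
        if self.n_planted_pairs > min(self.n_hpo_terms, self.n_go_terms):
            raise ValueError("more planted pairs than available terms on one side")
        if hi > self.n_genes:
            raise ValueError("planted co-annotation size exceeds the gene universe")


class PlantedPair(NamedTuple):
    hpo_id: str
    go_id: str
    genes: frozenset[str]


@dataclass(frozen=True)
class PlantedTruth:
    """The planted (hpo, go) associations with their seeded gene sets."""

    pairs: tuple[PlantedPair, ...]

    def keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((p.hpo_id, p.go_id) for p in self.pairs)


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _hpo_id(i: int) -> str:
    return f"HP:{i + 1:07d}"


def _go_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_planted_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[AnnotationSet, AnnotationSet, PlantedTruth]:
    """Build the (HPO corpus, GO corpus, planted truth) triple.

    Planted pairs use term-disjoint HPO and GO terms; each pair's gene
    subset carries both annotations.  Background annotations are independent
    Bernoulli draws per (gene, term) over the whole universe.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = [_gene_id(i) for i in range(config.n_genes)]
    hpo_terms = [_hpo_id(i) for i in range(config.n_hpo_terms)]
    go_terms = [_go_id(i) for i in range(config.n_go_terms)]

    n_pairs = config.n_planted_pairs
    planted_hpo = rng.choice(config.n_hpo_terms, size=n_pairs, replace=False)
    planted_go = rng.choice(config.n_go_terms, size=n_pairs, replace=False)
    lo, hi = config.planted_coannotation_range
    sizes = rng.integers(lo, hi + 1, size=n_pairs)

    if int(sizes.sum()) > config.n_genes:
        raise ValueError(
            f"planted load of {int(sizes.sum())} genes exceeds the {config.n_genes}-gene universe"
        )
    gene_perm = rng.permutation(config.n_genes)

    hpo_pairs: set[tuple[str, str]] = set()
    go_pairs: set[tuple[str, str]] = set()
    planted: list[PlantedPair] = []
    offset = 0
    for hi_idx, gi_idx, k in zip(planted_hpo, planted_go, sizes):
        # planted gene blocks are pairwise disjoint: no cross-pair co-annotation
        gene_set = frozenset(genes[g] for g in gene_perm[offset:offset + int(k)])
        offset += int(k)
        h, g = hpo_terms[hi_idx], go_terms[gi_idx]
        for gene in gene_set:
            hpo_pairs.add((gene, h))
            go_pairs.add((gene, g))
        planted.append(PlantedPair(h, g, gene_set))

    if config.background_rate > 0:
        bg_h = rng.random((config.n_genes, config.n_hpo_terms)) < config.background_rate
        bg_g = rng.random((config.n_genes, config.n_go_terms)) < config.background_rate
        for gi, ti in zip(*np.nonzero(bg_h)):
            hpo_pairs.add((genes[gi], hpo_terms[ti]))
        for gi, ti in zip(*np.nonzero(bg_g)):
            go_pairs.add((genes[gi], go_terms[ti]))

    return (
        AnnotationSet(hpo_pairs, namespace="HPO"),
        AnnotationSet(go_pairs, namespace="GO"),
        PlantedTruth(tuple(planted)),
    )


def generate_toy_dag(
    n_terms: int,
    branching: int = 2,
    seed: int = 0,
    prefix: str = "HP",
    extra_edges: int = 0,
) -> OntologyDAG:
    """Random rooted DAG: a random tree plus optional extra is_a edges.

    Term ``i`` (i >= 1) attaches to a uniformly chosen earlier term among the
    most recent ``branching`` candidates' ancestry pool; extra edges connect
    a term to a random earlier non-parent, keeping the graph acyclic by
    construction (edges always point from later to earlier terms).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}:{i + 1:07d}" for i in range(n_terms)]
    terms = {tid: Term(name=f"synthetic term {i + 1}") for i, tid in enumerate(ids)}
    edges: set[tuple[str, str, str]] = set()
    parent_of: dict[int, set[int]] = {0: set()}
    for i in range(1, n_terms):
        lo = max(0, i - branching * 2)
        parent = int(rng.integers(lo, i))
        edges.add((ids[i], ids[parent], "is_a"))
        parent_of[i] = {parent}
    for _ in range(extra_edges):
        if n_terms < 3:
            break
        child = int(rng.integers(2, n_terms))
        parent = int(rng.integers(0, child))
        if parent not in parent_of[child]:
            edges.add((ids[child], ids[parent], "is_a"))
            parent_of[child].add(parent)
    return OntologyDAG(terms, edges)


class BenchmarkCase(NamedTuple):
    """A synthetic prediction/benchmark pair plus the supporting ontology."""

    predictions: PredictionSet
    benchmark: BenchmarkSet
    dag: OntologyDAG
    ic: TermInformationContent


def generate_benchmark_case(
    config: SyntheticConfig = SyntheticConfig(),
    separability: float = 1.0,
    n_proteins: int = 40,
    terms_per_protein: int = 3,
    term_pool: int = 12,
) -> BenchmarkCase:
    """Sample a benchmark with controllable positive/negative score separation.

    A shared pool of ``term_pool`` leaf terms hangs under a single root; each
    protein draws ``terms_per_protein`` truth terms from the pool and receives
    a prediction score for *every* pool term, so term-centric negatives carry
    real scores rather than the implicit zero.  ``separability`` in [0, 1]
    interpolates between exchangeable positive and negative scores (0) and
    perfectly separated ones (1): with probability ``separability`` a
    positive score is drawn from U(0.51, 1.0) and a negative from
    U(0.01, 0.50); otherwise both come from U(0.01, 1.0).
    """
    if not (0 <= separability <= 1):
        raise ValueError("separability must lie in [0, 1]")
    if term_pool <= terms_per_protein:
        raise ValueError("term_pool must exceed terms_per_protein")
    rng = np.random.default_rng(config.seed)
    # flat ontology: term 1 is the root, everything else is a direct child
    ids = [f"HP:{i + 1:07d}" for i in range(term_pool + 1)]
    terms = {tid: Term(name=f"synthetic term {i}") for i, tid in enumerate(ids)}
    edges = {(tid, ids[0], "is_a") for tid in ids[1:]}
    dag = OntologyDAG(terms, edges)
    leaf_ids = ids[1:]

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    truth_pairs: set[tuple[str, str]] = set()
    predictions: list[Prediction] = []
    for protein in proteins:
        chosen = set(rng.choice(term_pool, size=terms_per_protein, replace=False).tolist())
        for i, t in enumerate(leaf_ids):
            is_pos = i in chosen
            if is_pos:
                truth_pairs.add((protein, t))
            separated = rng.random() < separability
            if separated:
                score = rng.uniform(0.51, 1.0) if is_pos else rng.uniform(0.01, 0.50)
            else:
                score = rng.uniform(0.01, 1.0)
            predictions.append(Prediction(protein, t, float(score), via_go=""))

    truth = AnnotationSet(truth_pairs, namespace="HPO")
    bench = BenchmarkSet.from_annotations(truth, dag, proteins=proteins, mode="full")
    propagated = propagate_annotations(truth, dag)
    ic = information_content(propagated, dag)
    preds = PredictionSet(predictions, metadata={"separability": separability})
    return BenchmarkCase(preds, bench, dag, ic)


def write_hpo_fixture(hpo: AnnotationSet, stream: IO[str]) -> int:
    """Emit the corpus in the genes_to_phenotype dialect the parser reads."""
    stream.write("#entrez-gene-id\tgene-symbol\thpo-term-name\thpo-term-id\n")
    n = 0
    for i, (gene, term) in enumerate(sorted(hpo.pairs)):
        stream.write(f"{10000 + i}\t{gene}\tsynthetic phenotype\t{term}\n")
        n += 1
    return n


def write_go_fixture(go: AnnotationSet, stream: IO[str], evidence: str = "EXP") -> int:
    """Emit the corpus in the QuickGO-style dialect the parser reads."""
    stream.write("#gene-symbol\tgo-id\tevidence\taspect\n")
    n = 0
    for gene, term in sorted(go.pairs):
        stream.write(f"{gene}\t{term}\t{evidence}\tP\n")
        n += 1
    return n
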