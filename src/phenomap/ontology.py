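"""Ontology DAGs: OBO parsing, ancestor closure, true-path-rule propagation
and information-content estimation.

Both HPO and GO are rooted directed acyclic graphs whose semantics follow the
true path rule: an entity annotated with a term is implicitly annotated with
every ancestor of that term.  Only ``is_a`` and ``part_of`` edges are treated
as parent edges (the standard convention for annotation propagation); other
relationship types are ignored with a log line.

Information content is estimated as information accretion: for a term ``v``
with parents ``P``, ``ia(v) = -log2 Pr(v | P)`` where the conditional
probability is the fraction of entities annotated with every parent that are
also annotated with ``v``, counted on a propagated corpus.  Root terms
therefore carry zero information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

from .annotations import AnnotationSet

log = logging.getLogger(__name__)

PROPAGATING_RELATIONS = ("is_a", "part_of")


class OntologyStructureError(ValueError):
    """Structural defect in an ontology file (cycle, dangling parent id)."""


@dataclass(frozen=True)
class Term:
    name: str
    namespace: str = ""
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


class OntologyDAG:
    """A rooted DAG of ontology terms with typed parent edges.

    ``edges`` holds (child, parent, relation) triples restricted to the
    propagating relations; obsolete terms are retained but never appear in an
    edge.  Alternate ids resolve to their primary term at lookup time.
    """

    def __init__(self, terms: Mapping[str, Term], edges: Iterable[tuple[str, str, str]]):
        self.terms: dict[str, Term] = dict(terms)
        self.edges: frozenset[tuple[str, str, str]] = frozenset(edges)
        self._alt: dict[str, str] = {}
        for tid, term in self.terms.items():
            for alt in term.alt_ids:
                if alt in self._alt and self._alt[alt] != tid:
                    raise OntologyStructureError(
                        f"alt_id {alt} claimed by both {self._alt[alt]} and {tid}"
                    )
                self._alt[alt] = tid
        self._parents: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for child, parent, relation in self.edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyStructureError(
                        f"edge ({child}, {parent}, {relation}) references undeclared term {endpoint}"
                    )
            self._parents[child].add(parent)
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        graph.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyStructureError(
                f"ontology contains a cycle; offending edge {cycle[0][0]} -> {cycle[0][1]}"
            )
        self._graph = graph
        self.roots: frozenset[str] = frozenset(
            tid for tid, term in self.terms.items()
            if not self._parents[tid] and not term.obsolete
        )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise KeyError(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def parents(self, term_id: str) -> frozenset[str]:
        return frozenset(self._parents[self.resolve(term_id)])

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable via parent edges, excluding the term itself."""
        tid = self.resolve(term_id)
        cached = self._ancestor_cache.get(tid)
        if cached is None:
            out: set[str] = set()
            stack = list(self._parents[tid])
            while stack:
                p = stack.pop()
                if p not in out:
                    out.add(p)
                    stack.extend(self._parents[p])
            cached = frozenset(out)
            self._ancestor_cache[tid] = cached
        return cached

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OntologyDAG)
            and self.terms == other.terms
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"OntologyDAG({len(self.terms)} terms, {len(self.edges)} edges, roots={sorted(self.roots)})"


@dataclass(frozen=True)
class TermInformationContent:
    """Per-term information content (bits by default) plus corpus size."""

    ic: Mapping[str, float]
    source_count: int

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic


def parse_obo(stream: IO[str] | str) -> OntologyDAG:
    """Parse an OBO 1.2 file (path or text stream) into an :class:`OntologyDAG`.

    Non-obsolete stanzas contribute terms and their ``is_a``/``part_of``
    parent edges; obsolete terms are retained but flagged and edge-free.
    Cycles and parent references to undeclared terms raise
    :class:`OntologyStructureError`.
    """
    graph = obonet.read_obo(stream, ignore_obsolete=False)
    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data and graph.in_degree(node) > 0 and not data:
            # node materialized only because some stanza pointed at it
            raise OntologyStructureError(f"dangling parent id {node}")
        terms[node] = Term(
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            alt_ids=tuple(data.get("alt_id", ())),
        )
    edges: set[tuple[str, str, str]] = set()
    ignored_relations: set[str] = set()
    for child, parent, relation in graph.edges(keys=True):
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        if relation in PROPAGATING_RELATIONS:
            edges.add((child, parent, relation))
        else:
            ignored_relations.add(relation)
    if ignored_relations:
        log.info("ignored non-propagating relations: %s", sorted(ignored_relations))
    return OntologyDAG(terms, edges)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Serialize a DAG back to OBO 1.2; parse(write(dag)) == dag."""
    stream.write("format-version: 1.2\nontology: phenomap-export\n")
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in dag.edges:
        by_child.setdefault(child, []).append((relation, parent))
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        stream.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
        if term.namespace:
            stream.write(f"namespace: {term.namespace}\n")
        for alt in term.alt_ids:
            stream.write(f"alt_id: {alt}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
        for relation, parent in sorted(by_child.get(tid, [])):
            if relation == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {relation} {parent}\n")


def ancestors(dag: OntologyDAG, term_id: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyDAG.ancestors`."""
    return dag.ancestors(term_id)


def propagate_annotations(
    annot: AnnotationSet,
    dag: OntologyDAG,
    on_missing: str = "drop",
) -> AnnotationSet:
    """Close an annotation set under the true path rule.

    Every (entity, term) pair gains (entity, ancestor) for all ancestors of
    the term; alt_ids are rewritten to primary ids.  Terms absent from the
    DAG are dropped with a warning by default (``on_missing="error"`` makes
    this fatal).  The operation is idempotent.
    """
    if on_missing not in ("drop", "error"):
        raise ValueError(f"on_missing must be 'drop' or 'error', got {on_missing!r}")
    out: set[tuple[str, str]] = set()
    missing: set[str] = set()
    for entity, term in annot:
        if term not in dag:
            if on_missing == "error":
                raise KeyError(f"annotated term {term} absent from ontology")
            missing.add(term)
            continue
        tid = dag.resolve(term)
        out.add((entity, tid))
        for anc in dag.ancestors(tid):
            out.add((entity, anc))
    if missing:
        log.warning("dropped annotations to %d term(s) absent from the ontology", len(missing))
    return AnnotationSet(out, namespace=annot.namespace)


def is_propagated(annot: AnnotationSet, dag: OntologyDAG) -> bool:
    """True iff the set is closed under ancestors (cheap per-edge subset check)."""
    for term, entities in annot.by_term.items():
        if term not in dag:
            return False
        for parent in dag.parents(term):
            if not entities <= annot.by_term.get(parent, frozenset()):
                return False
    return True


def information_content(
    propagated: AnnotationSet, dag: OntologyDAG, base: float = 2.0
) -> TermInformationContent:
    """Estimate per-term information accretion from a propagated corpus.

    ``ic(t) = -log_base( |entities with t| / |entities with every parent of t| )``.
    For root terms the denominator is the whole annotated-entity universe, so
    a root annotated everywhere has zero information.  Terms without
    propagated annotations are absent from the result.
    """
    if not is_propagated(propagated, dag):
        raise ValueError("information_content requires an ancestor-closed annotation set")
    all_entities = propagated.entities()
    ic: dict[str, float] = {}
    for term, entities in propagated.by_term.items():
        parents = dag.parents(term)
        if parents:
            denom_set = set(all_entities)
            for p in parents:
                denom_set &= propagated.by_term.get(p, frozenset())
        else:
            denom_set = set(all_entities)
        if not denom_set:
            continue
        ratio = len(entities) / len(denom_set)
        ic[term] = max(0.0, -math.log(ratio, base))
    return TermInformationContent(ic=ic, source_count=len(all_entities))
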