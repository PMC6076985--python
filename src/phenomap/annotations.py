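"""Annotation corpora: entity <-> ontology-term association tables.

The two training inputs of the pipeline are (i) an HPO gene->phenotype
annotation table (the ``genes_to_phenotype.txt`` dialect distributed by the
HPO project) and (ii) a GO annotation export (QuickGO/GOA-style TSV or
GAF 2.1).  Both are reduced to a deduplicated set of (entity, term) pairs
joined on the gene symbol; evidence codes are only used to filter GO rows.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"GO:\d{7}$")

#: Curator-assigned GO evidence codes used for the default training corpus.
CURATED_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "IBA", "IC", "IKR", "ISS", "NAS", "ND", "TAS"}
)


class AnnotationParseError(ValueError):
    """A malformed row in an annotation file (carries the 1-based line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class EvidenceFilter:
    """Whitelist of GO evidence codes; rows with other codes are dropped."""

    allowed_codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.allowed_codes:
            raise ValueError("EvidenceFilter requires a non-empty code set")

    @classmethod
    def curated(cls, include_iea: bool = False) -> "EvidenceFilter":
        codes = set(CURATED_EVIDENCE_CODES)
        if include_iea:
            codes.add("IEA")
        return cls(frozenset(codes))

    def __contains__(self, code: str) -> bool:
        return code in self.allowed_codes


class AnnotationSet:
    """Deduplicated set of (entity, term) pairs with bidirectional indices.

    Entities are gene symbols or protein accessions; terms are ontology ids.
    The structure is immutable: derived corpora (filtered, propagated,
    randomized) are new instances.
    """

    __slots__ = ("_pairs", "_by_entity", "_by_term", "namespace")

    def __init__(self, pairs: Iterable[tuple[str, str]], namespace: str = ""):
        self._pairs = frozenset((str(e), str(t)) for e, t in pairs)
        by_entity: dict[str, set[str]] = {}
        by_term: dict[str, set[str]] = {}
        for e, t in self._pairs:
            by_entity.setdefault(e, set()).add(t)
            by_term.setdefault(t, set()).add(e)
        self._by_entity = {e: frozenset(ts) for e, ts in by_entity.items()}
        self._by_term = {t: frozenset(es) for t, es in by_term.items()}
        self.namespace = namespace

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return self._pairs

    @property
    def by_entity(self) -> Mapping[str, frozenset[str]]:
        return self._by_entity

    @property
    def by_term(self) -> Mapping[str, frozenset[str]]:
        return self._by_term

    def entities(self) -> frozenset[str]:
        return frozenset(self._by_entity)

    def terms(self) -> frozenset[str]:
        return frozenset(self._by_term)

    def term_count(self, term: str) -> int:
        """Number of entities annotated with *term* (N_term of the similarity score)."""
        return len(self._by_term.get(term, ()))

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationSet) and self._pairs == other._pairs

    def __hash__(self) -> int:
        return hash(self._pairs)

    def __repr__(self) -> str:
        return (
            f"AnnotationSet({len(self._pairs)} pairs, {len(self._by_entity)} entities, "
            f"{len(self._by_term)} terms, namespace={self.namespace!r})"
        )


def read_hpo_gene_annotations(stream: IO[str]) -> AnnotationSet:
    """Parse the HPO ``genes_to_phenotype`` dialect into an AnnotationSet.

    Expected columns (tab-separated): entrez gene id, gene symbol, HPO term
    name, HPO term id.  Lines starting with ``#`` are skipped.  The entity id
    is the gene symbol, exact and case-preserved; the term-name column is
    logged but carries no logic.
    """
    pairs: set[tuple[str, str]] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise AnnotationParseError(
                f"expected 4 tab-separated columns, got {len(cols)}", lineno
            )
        _entrez, symbol, _term_name, term_id = cols
        pairs.add((symbol, term_id))
    if not pairs:
        log.warning("HPO annotation input contained no data rows")
    return AnnotationSet(pairs, namespace="HPO")


#: Default column layout of a QuickGO-style annotation export (0-based).
QUICKGO_COLUMNS = {"symbol": 0, "go_id": 1, "evidence": 2, "aspect": 3}
#: GAF 2.1 column layout (0-based): DB Object Symbol, GO ID, Evidence Code.
GAF_COLUMNS = {"symbol": 2, "go_id": 4, "evidence": 6, "aspect": 8}


def read_go_annotations(
    stream: IO[str],
    evidence_filter: EvidenceFilter | None = None,
    columns: Mapping[str, int] = QUICKGO_COLUMNS,
) -> AnnotationSet:
    """Parse a GO annotation TSV, filter by evidence code, deduplicate.

    ``columns`` maps the logical fields (symbol, go_id, evidence, aspect) to
    0-based column indices; pass :data:`GAF_COLUMNS` for GAF 2.1 input (GAF
    comment lines start with ``!`` and are skipped too).  Pairs surviving the
    evidence filter are deduplicated across evidence codes and aspects.
    """
    need = max(columns.values()) + 1
    pairs: set[tuple[str, str]] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < need:
            raise AnnotationParseError(
                f"expected at least {need} tab-separated columns, got {len(cols)}", lineno
            )
        go_id = cols[columns["go_id"]]
        if not GO_ID_RE.match(go_id):
            raise AnnotationParseError(f"malformed GO id {go_id!r}", lineno)
        evidence = cols[columns["evidence"]]
        if evidence_filter is not None and evidence not in evidence_filter:
            continue
        pairs.add((cols[columns["symbol"]], go_id))
    if not pairs:
        log.warning("GO annotation input contained no surviving data rows")
    return AnnotationSet(pairs, namespace="GO")


def write_annotation_set(annot: AnnotationSet, stream: IO[str]) -> int:
    """Write a two-column (entity, term) TSV in lexicographic order; returns row count."""
    n = 0
    for entity, term in sorted(annot.pairs):
        stream.write(f"{entity}\t{term}\n")
        n += 1
    return n


def read_annotation_set(stream: IO[str], namespace: str = "") -> AnnotationSet:
    """Read the two-column TSV written by :func:`write_annotation_set`."""
    pairs = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise AnnotationParseError(
                f"expected 2 tab-separated columns, got {len(cols)}", lineno
            )
        pairs.add((cols[0], cols[1]))
    return AnnotationSet(pairs, namespace=namespace)
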