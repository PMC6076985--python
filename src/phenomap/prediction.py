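"""Phenotype-term prediction for proteins from their GO annotations.

A filtered HPO-GO mapping table acts as a rule set: a protein annotated with
GO term ``g`` receives every HPO term mapped to ``g``, scored with the
mapping's co-occurrence similarity S (already in (0, 1], so it doubles as a
probabilistic score).  When several of a protein's GO terms map to the same
HPO term, the maximum S wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from .annotations import AnnotationSet
from .mapping import MappingTable
from .ontology import OntologyDAG

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Prediction:
    protein_id: str
    hpo_id: str
    score: float
    via_go: str


class PredictionSet:
    """Scored (protein, HPO term) predictions, unique per key."""

    def __init__(self, predictions: Iterable[Prediction], metadata: Mapping[str, object] | None = None):
        preds = sorted(predictions, key=lambda p: (p.protein_id, p.hpo_id))
        self._index = {(p.protein_id, p.hpo_id): p for p in preds}
        if len(self._index) != len(preds):
            raise ValueError("duplicate (protein, hpo) keys in prediction set")
        for p in preds:
            if not (0 < p.score <= 1):
                raise ValueError(f"score out of (0, 1]: {p}")
        self.predictions: tuple[Prediction, ...] = tuple(preds)
        self.metadata: dict[str, object] = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self) -> Iterator[Prediction]:
        return iter(self.predictions)

    def proteins(self) -> frozenset[str]:
        return frozenset(p.protein_id for p in self.predictions)

    def by_protein(self) -> dict[str, list[Prediction]]:
        out: dict[str, list[Prediction]] = {}
        for p in self.predictions:
            out.setdefault(p.protein_id, []).append(p)
        return out

    def get(self, protein_id: str, hpo_id: str) -> Prediction | None:
        return self._index.get((protein_id, hpo_id))


def predict_hpo(
    mappings: MappingTable,
    go_annot: AnnotationSet,
    score_floor: float = 0.01,
    dag: OntologyDAG | None = None,
    propagate: bool = False,
) -> PredictionSet:
    """Emit HPO predictions for every GO-annotated protein.

    For each protein and each HPO term reachable through at least one of its
    GO annotations, one prediction is emitted with score = max S over the
    contributing mappings (ties on S broken toward the lexicographically
    smallest supporting GO id, for determinism).  Predictions scoring below
    ``score_floor`` are dropped.  When a ``dag`` is supplied its roots are
    never emitted, and ``propagate=True`` additionally copies each predicted
    term's score onto its ancestors (max-aggregated).
    """
    if mappings.applied_thresholds is None:
        log.warning("mapping table carries no applied thresholds; predicting from a raw table")
    by_go: dict[str, list[tuple[str, float]]] = {}
    for rec in mappings:
        by_go.setdefault(rec.go_id, []).append((rec.hpo_id, rec.s))
    roots = dag.roots if dag is not None else frozenset()
    predictions: list[Prediction] = []
    for protein in sorted(go_annot.entities()):
        best: dict[str, tuple[float, str]] = {}
        for go_term in go_annot.by_entity[protein]:
            for hpo_id, s in by_go.get(go_term, ()):
                cur = best.get(hpo_id)
                if cur is None or s > cur[0] or (s == cur[0] and go_term < cur[1]):
                    best[hpo_id] = (s, go_term)
        if propagate and dag is not None:
            for hpo_id, (s, via) in list(best.items()):
                if hpo_id not in dag:
                    continue
                for anc in dag.ancestors(hpo_id):
                    cur = best.get(anc)
                    if cur is None or s > cur[0]:
                        best[anc] = (s, via)
        for hpo_id, (s, via) in best.items():
            if s < score_floor or hpo_id in roots:
                continue
            predictions.append(Prediction(protein, hpo_id, s, via))
    metadata = {
        "mapping_provenance": mappings.provenance,
        "applied_thresholds": mappings.applied_thresholds,
        "score_floor": score_floor,
        "propagated": propagate,
    }
    return PredictionSet(predictions, metadata)


def write_cafa_predictions(
    preds: PredictionSet,
    model_tag: str,
    stream: IO[str],
    author: str = "phenomap",
    keywords: str = "ontology mapping",
) -> int:
    """Write the CAFA exchange format; returns the number of data rows.

    Rows are ``target_id HP:nnnnnnn score`` with the score rounded to two
    decimals; a score rounding to 0.00 is clamped to 0.01 with a warning.
    """
    stream.write(f"AUTHOR {author}\nMODEL {model_tag}\nKEYWORDS {keywords}.\n")
    count = 0
    clamped = 0
    for p in preds:
        score = round(p.score, 2)
        if score < 0.01:
            score = 0.01
            clamped += 1
        stream.write(f"{p.protein_id} {p.hpo_id} {score:.2f}\n")
        count += 1
    stream.write("END\n")
    if clamped:
        log.warning("%d scores rounded to 0.00 were clamped to 0.01", clamped)
    return count


def read_cafa_predictions(stream: IO[str]) -> PredictionSet:
    """Read the CAFA exchange format back (via_go is not representable: empty)."""
    predictions = []
    for line in stream:
        line = line.strip()
        if not line or line == "END":
            continue
        if line.split(" ", 1)[0] in ("AUTHOR", "MODEL", "KEYWORDS"):
            continue
        protein, hpo_id, score = line.split()
        predictions.append(Prediction(protein, hpo_id, float(score), via_go=""))
    return PredictionSet(predictions)


def write_predictions_tsv(preds: PredictionSet, stream: IO[str]) -> int:
    """Plain TSV (protein, term, score, via_go), full precision, sorted."""
    stream.write("#protein_id\thpo_id\tscore\tvia_go\n")
    n = 0
    for p in preds:
        stream.write(f"{p.protein_id}\t{p.hpo_id}\t{p.score:.6f}\t{p.via_go}\n")
        n += 1
    return n


def read_predictions_tsv(stream: IO[str]) -> PredictionSet:
    predictions = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        protein, hpo_id, score, via = line.split("\t")
        predictions.append(Prediction(protein, hpo_id, float(score), via))
    return PredictionSet(predictions)
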