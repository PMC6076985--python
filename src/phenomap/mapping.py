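"""HPO-GO term mapping by annotation co-occurrence.

For every pair of an HPO term and a GO term annotated to at least one shared
gene, the co-occurrence similarity is the Dice-style ratio

    S = 2 * n / (N_hpo + N_go)

where ``n`` is the number of genes carrying both annotations and ``N_hpo``,
``N_go`` are the total gene counts of each term over its full corpus.  ``S``
lies in (0, 1] and reaches 1 exactly when the two gene sets coincide; ``n``
serves as a second reliability parameter, because a pair of rarely-annotated
terms can reach a high S on a single shared gene purely by chance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

from .annotations import AnnotationSet

log = logging.getLogger(__name__)


def cooccurrence_similarity(n: int, n_hpo: int, n_go: int) -> float:
    """Dice-style co-occurrence similarity 2n/(N_hpo+N_go)."""
    if n_hpo + n_go == 0:
        raise ValueError("similarity undefined for two unannotated terms")
    if n < 0 or n_hpo < n or n_go < n:
        raise ValueError(f"inconsistent counts n={n}, N_hpo={n_hpo}, N_go={n_go}")
    return 2.0 * n / (n_hpo + n_go)


@dataclass(frozen=True)
class MappingRecord:
    """One HPO-GO pair with its co-annotation statistics."""

    hpo_id: str
    go_id: str
    n: int
    n_hpo: int
    n_go: int

    @property
    def s(self) -> float:
        return cooccurrence_similarity(self.n, self.n_hpo, self.n_go)


class MappingTable:
    """Collection of mapping records, unique per (hpo_id, go_id).

    ``provenance`` distinguishes the observed table ("original") from the
    permutation-null table ("null"); ``applied_thresholds`` records the
    (s_min, n_min) filter a derived table satisfies.
    """

    def __init__(
        self,
        records: Iterable[MappingRecord],
        provenance: str = "original",
        applied_thresholds: tuple[float, int] | None = None,
    ):
        recs = sorted(records, key=lambda r: (r.hpo_id, r.go_id))
        self._index = {(r.hpo_id, r.go_id): r for r in recs}
        if len(self._index) != len(recs):
            raise ValueError("duplicate (hpo_id, go_id) keys in mapping table")
        self.records: tuple[MappingRecord, ...] = tuple(recs)
        self.provenance = provenance
        self.applied_thresholds = applied_thresholds

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MappingRecord]:
        return iter(self.records)

    def get(self, hpo_id: str, go_id: str) -> MappingRecord | None:
        return self._index.get((hpo_id, go_id))

    def s_values(self) -> list[float]:
        return [r.s for r in self.records]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MappingTable) and self.records == other.records


def build_raw_mapping(
    hpo_annot: AnnotationSet, go_annot: AnnotationSet, provenance: str = "original"
) -> MappingTable:
    """Build the full mapping table over the shared gene universe.

    One record per (HPO term, GO term) pair with ``n >= 1`` co-annotated
    genes; ``N_hpo``/``N_go`` are whole-corpus totals, not restricted to the
    shared genes.
    """
    shared = hpo_annot.entities() & go_annot.entities()
    counts: Counter[tuple[str, str]] = Counter()
    for gene in shared:
        hpo_terms = hpo_annot.by_entity[gene]
        go_terms = go_annot.by_entity[gene]
        for ht in hpo_terms:
            for gt in go_terms:
                counts[(ht, gt)] += 1
    if not counts:
        log.warning("no shared genes between the HPO and GO corpora; mapping table is empty")
    records = [
        MappingRecord(
            hpo_id=ht,
            go_id=gt,
            n=n,
            n_hpo=hpo_annot.term_count(ht),
            n_go=go_annot.term_count(gt),
        )
        for (ht, gt), n in counts.items()
    ]
    return MappingTable(records, provenance=provenance)


def filter_mapping(table: MappingTable, s_min: float, n_min: int) -> MappingTable:
    """Keep exactly the records with ``n >= n_min`` and ``S >= s_min``."""
    if s_min < 0 or n_min < 0:
        raise ValueError("thresholds must be non-negative")
    kept = [r for r in table if r.n >= n_min and r.s >= s_min]
    return MappingTable(kept, provenance=table.provenance, applied_thresholds=(s_min, n_min))


def summarize_mapping(table: MappingTable, s_thresholds: Sequence[float]) -> pd.DataFrame:
    """Cumulative mapping statistics per similarity threshold.

    One row per threshold with the number of records at ``S >= threshold``
    and the distinct HPO/GO term counts among them; counts are monotone
    non-increasing in the threshold.
    """
    rows = []
    for thr in s_thresholds:
        recs = [r for r in table if r.s >= thr]
        rows.append(
            {
                "s_threshold": thr,
                "n_mappings": len(recs),
                "n_hpo_terms": len({r.hpo_id for r in recs}),
                "n_go_terms": len({r.go_id for r in recs}),
            }
        )
    return pd.DataFrame(rows, columns=["s_threshold", "n_mappings", "n_hpo_terms", "n_go_terms"])


def write_mapping_table(table: MappingTable, stream: IO[str]) -> int:
    """Write the mapping TSV (hpo_id, go_id, n, N_hpo, N_go, S at 6 decimals)."""
    stream.write(f"#provenance={table.provenance}\n")
    if table.applied_thresholds is not None:
        s_min, n_min = table.applied_thresholds
        stream.write(f"#s_min={s_min}\n#n_min={n_min}\n")
    stream.write("#hpo_id\tgo_id\tn\tN_hpo\tN_go\tS\n")
    count = 0
    for r in table:
        stream.write(f"{r.hpo_id}\t{r.go_id}\t{r.n}\t{r.n_hpo}\t{r.n_go}\t{r.s:.6f}\n")
        count += 1
    return count


def read_mapping_table(stream: IO[str]) -> MappingTable:
    """Read the TSV written by :func:`write_mapping_table`."""
    provenance = "original"
    s_min: float | None = None
    n_min: int | None = None
    records = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:]
            if body.startswith("provenance="):
                provenance = body.split("=", 1)[1]
            elif body.startswith("s_min="):
                s_min = float(body.split("=", 1)[1])
            elif body.startswith("n_min="):
                n_min = int(float(body.split("=", 1)[1]))
            continue
        hpo_id, go_id, n, n_hpo, n_go, _s = line.split("\t")
        records.append(MappingRecord(hpo_id, go_id, int(n), int(n_hpo), int(n_go)))
    thresholds = (s_min, n_min) if s_min is not None and n_min is not None else None
    return MappingTable(records, provenance=provenance, applied_thresholds=thresholds)
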