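"""Protein-centric and term-centric evaluation of phenotype-term predictions.

Implements the CAFA2-style HPO-track metrics.  For each probabilistic score
threshold tau, a protein's predicted term set P_i(tau) is the true-path-rule
propagation of its predictions at score >= tau (ontology roots removed); the
truth set T_i is propagated likewise.  Then

    precision(tau) = mean over proteins with |P_i| >= 1 of |P_i & T_i| / |P_i|
    recall(tau)    = mean over benchmark proteins of |P_i & T_i| / |T_i|
    Fmax           = max over tau of the harmonic mean of precision and recall

In "full" evaluation mode the recall average runs over every benchmark
protein; "partial" mode restricts it to proteins with at least one
prediction.  Weighted variants replace set cardinalities with sums of
per-term information content.  Remaining uncertainty Ru(tau) and
misinformation Mi(tau) are the per-protein mean information content of
missed (T \\ P) and spurious (P \\ T) terms, and Smin is the minimum over
tau of sqrt(Ru^2 + Mi^2), always including the empty-prediction point.
Term-centric AUROC ranks benchmark proteins by predicted score per term
(missing prediction = score 0) with the rank-average tie convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .annotations import AnnotationSet
from .ontology import OntologyDAG, TermInformationContent, propagate_annotations
from .prediction import PredictionSet

log = logging.getLogger(__name__)

DEFAULT_TAU_GRID = tuple(round(0.01 * i, 2) for i in range(1, 101))


@dataclass(frozen=True)
class BenchmarkSet:
    """Ground-truth annotations for a benchmark protein list.

    ``truth`` must be ancestor-closed with roots removed; use
    :meth:`from_annotations` to build one from asserted annotations.
    """

    truth: AnnotationSet
    proteins: tuple[str, ...]
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "partial"):
            raise ValueError(f"mode must be 'full' or 'partial', got {self.mode!r}")
        missing = self.truth.entities() - set(self.proteins)
        if missing:
            raise ValueError(f"truth entities absent from the protein list: {sorted(missing)[:5]}")

    @classmethod
    def from_annotations(
        cls,
        annot: AnnotationSet,
        dag: OntologyDAG,
        proteins: Sequence[str] | None = None,
        mode: str = "full",
    ) -> "BenchmarkSet":
        propagated = propagate_annotations(annot, dag)
        no_roots = AnnotationSet(
            ((e, t) for e, t in propagated if t not in dag.roots),
            namespace=propagated.namespace,
        )
        if proteins is None:
            proteins = sorted(no_roots.entities())
        return cls(truth=no_roots, proteins=tuple(proteins), mode=mode)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Aggregated confusion counts and metric values at one threshold."""

    tau: float
    n_predicted_proteins: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    w_precision: float
    w_recall: float
    w_f_score: float
    ru: float
    mi: float

    @property
    def semantic_distance(self) -> float:
        return math.sqrt(self.ru**2 + self.mi**2)


@dataclass
class EvaluationSummary:
    fmax: float
    weighted_fmax: float
    smin: float
    coverage: float
    curve: list[ThresholdMetrics]
    term_auroc: dict[str, float]
    macro_auroc: float
    skipped_terms: list[str] = field(default_factory=list)


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def _propagated_scores(
    preds: PredictionSet, dag: OntologyDAG
) -> dict[str, dict[str, float]]:
    """Per protein: term -> max score over the term's predicted descendants/self.

    Thresholding this map at tau is equivalent to propagating the
    thresholded prediction set, for every tau at once.  Roots are removed.
    """
    out: dict[str, dict[str, float]] = {}
    for p in preds:
        if p.hpo_id not in dag:
            log.debug("predicted term %s absent from ontology; kept unpropagated", p.hpo_id)
            terms: Iterable[str] = (p.hpo_id,)
        else:
            tid = dag.resolve(p.hpo_id)
            terms = (tid, *dag.ancestors(tid))
        scores = out.setdefault(p.protein_id, {})
        for t in terms:
            if t in dag.roots:
                continue
            if scores.get(t, 0.0) < p.score:
                scores[t] = p.score
    return out


def threshold_metrics(
    preds: PredictionSet,
    bench: BenchmarkSet,
    dag: OntologyDAG,
    ic: TermInformationContent,
    tau: float,
    missing_ic: str = "drop",
) -> ThresholdMetrics:
    """Compute all per-threshold metrics at one tau (see module docstring)."""
    if not (0 < tau <= 1):
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    scores = _propagated_scores(preds, dag)
    return _metrics_at(scores, bench, ic, tau, missing_ic)


def _ic_sum(terms: Iterable[str], ic: TermInformationContent, missing_ic: str) -> float:
    total = 0.0
    for t in terms:
        if t in ic:
            total += ic[t]
        elif missing_ic == "error":
            raise KeyError(f"no information content for term {t}")
    return total


def _metrics_at(
    scores: Mapping[str, Mapping[str, float]],
    bench: BenchmarkSet,
    ic: TermInformationContent,
    tau: float,
    missing_ic: str = "drop",
) -> ThresholdMetrics:
    tp_sum = fp_sum = fn_sum = 0
    prec_terms: list[float] = []
    rec_terms: list[float] = []
    wprec_terms: list[float] = []
    wrec_terms: list[float] = []
    ru_terms: list[float] = []
    mi_terms: list[float] = []
    n_predicted = 0
    for protein in bench.proteins:
        truth = bench.truth.by_entity.get(protein, frozenset())
        predicted = {t for t, s in scores.get(protein, {}).items() if s >= tau}
        tp = predicted & truth
        fp = predicted - truth
        fn = truth - predicted
        tp_sum += len(tp)
        fp_sum += len(fp)
        fn_sum += len(fn)
        has_pred = len(predicted) >= 1
        if has_pred:
            n_predicted += 1
            prec_terms.append(len(tp) / len(predicted))
            w_pred = _ic_sum(predicted, ic, missing_ic)
            wprec_terms.append(_ic_sum(tp, ic, missing_ic) / w_pred if w_pred > 0 else 0.0)
        in_recall_pool = bench.mode == "full" or has_pred
        if in_recall_pool:
            if truth:
                rec_terms.append(len(tp) / len(truth))
                w_truth = _ic_sum(truth, ic, missing_ic)
                wrec_terms.append(_ic_sum(tp, ic, missing_ic) / w_truth if w_truth > 0 else 0.0)
            ru_terms.append(_ic_sum(fn, ic, missing_ic))
            mi_terms.append(_ic_sum(fp, ic, missing_ic))
    precision = float(np.mean(prec_terms)) if prec_terms else 0.0
    recall = float(np.mean(rec_terms)) if rec_terms else 0.0
    w_precision = float(np.mean(wprec_terms)) if wprec_terms else 0.0
    w_recall = float(np.mean(wrec_terms)) if wrec_terms else 0.0
    return ThresholdMetrics(
        tau=tau,
        n_predicted_proteins=n_predicted,
        tp=tp_sum,
        fp=fp_sum,
        fn=fn_sum,
        precision=precision,
        recall=recall,
        f_score=_harmonic(precision, recall),
        w_precision=w_precision,
        w_recall=w_recall,
        w_f_score=_harmonic(w_precision, w_recall),
        ru=float(np.mean(ru_terms)) if ru_terms else 0.0,
        mi=float(np.mean(mi_terms)) if mi_terms else 0.0,
    )


def fmax_curve(
    preds: PredictionSet,
    bench: BenchmarkSet,
    dag: OntologyDAG,
    ic: TermInformationContent,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    missing_ic: str = "drop",
) -> EvaluationSummary:
    """Sweep the tau grid; fill fmax, weighted fmax, smin, coverage and curve.

    Term-centric AUROC fields are left empty here; use :func:`evaluate` for
    the complete summary.
    """
    if not tau_grid:
        raise ValueError("tau_grid must be non-empty")
    scores = _propagated_scores(preds, dag)
    curve = [_metrics_at(scores, bench, ic, tau, missing_ic) for tau in tau_grid]
    fmax = max(m.f_score for m in curve)
    wfmax = max(m.w_f_score for m in curve)
    # the empty-prediction point always enters the Smin scan
    empty = _metrics_at(scores, bench, ic, _above_max_tau(scores), missing_ic)
    smin_val = min(m.semantic_distance for m in [*curve, empty])
    cov = coverage(preds, bench)
    return EvaluationSummary(
        fmax=fmax,
        weighted_fmax=wfmax,
        smin=smin_val,
        coverage=cov,
        curve=curve,
        term_auroc={},
        macro_auroc=math.nan,
    )


def _above_max_tau(scores: Mapping[str, Mapping[str, float]]) -> float:
    """A tau in (0, 1] strictly above every score, if one exists (else 1.0)."""
    top = max((s for per in scores.values() for s in per.values()), default=0.0)
    return 1.0 if top >= 1.0 else min(1.0, math.nextafter(top, 2.0))


def smin(
    preds: PredictionSet,
    bench: BenchmarkSet,
    dag: OntologyDAG,
    ic: TermInformationContent,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    missing_ic: str = "drop",
) -> float:
    """Minimum semantic distance sqrt(Ru^2 + Mi^2) over the tau scan."""
    summary = fmax_curve(preds, bench, dag, ic, tau_grid, missing_ic)
    return summary.smin


def term_centric_auroc(
    preds: PredictionSet,
    bench: BenchmarkSet,
    protein_universe: Sequence[str] | None = None,
    dag: OntologyDAG | None = None,
) -> tuple[dict[str, float], float, list[str]]:
    """Per-term AUROC over the protein universe, plus the macro average.

    For each truth term with at least one positive and one negative protein
    in the universe, proteins are scored by their (propagated, when a dag is
    given) predicted score for the term, 0 when absent.  Returns
    (term -> AUROC, macro AUROC, skipped terms).
    """
    if protein_universe is None:
        protein_universe = bench.proteins
    universe = list(dict.fromkeys(protein_universe))
    if not set(bench.proteins) <= set(universe):
        raise ValueError("protein_universe must contain every benchmark protein")
    if dag is not None:
        scores = _propagated_scores(preds, dag)
    else:
        scores = {}
        for p in preds:
            scores.setdefault(p.protein_id, {})[p.hpo_id] = max(
                p.score, scores.get(p.protein_id, {}).get(p.hpo_id, 0.0)
            )
    term_auroc: dict[str, float] = {}
    skipped: list[str] = []
    for term in sorted(bench.truth.terms()):
        positives = bench.truth.by_term[term]
        y_true = np.array([1 if prot in positives else 0 for prot in universe])
        if y_true.all() or not y_true.any():
            skipped.append(term)
            continue
        y_score = np.array([scores.get(prot, {}).get(term, 0.0) for prot in universe])
        term_auroc[term] = float(roc_auc_score(y_true, y_score))
    macro = float(np.mean(list(term_auroc.values()))) if term_auroc else math.nan
    return term_auroc, macro, skipped


def coverage(preds: PredictionSet, bench: BenchmarkSet) -> float:
    """Fraction of benchmark proteins with at least one prediction."""
    if not bench.proteins:
        raise ValueError("coverage undefined for an empty benchmark")
    predicted = preds.proteins()
    return sum(1 for p in bench.proteins if p in predicted) / len(bench.proteins)


def evaluate(
    preds: PredictionSet,
    bench: BenchmarkSet,
    dag: OntologyDAG,
    ic: TermInformationContent,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    protein_universe: Sequence[str] | None = None,
    missing_ic: str = "drop",
) -> EvaluationSummary:
    """Full evaluation: Fmax, weighted Fmax, Smin, coverage, term-centric AUROC."""
    summary = fmax_curve(preds, bench, dag, ic, tau_grid, missing_ic)
    term_auroc, macro, skipped = term_centric_auroc(preds, bench, protein_universe, dag)
    summary.term_auroc = term_auroc
    summary.macro_auroc = macro
    summary.skipped_terms = skipped
    return summary
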