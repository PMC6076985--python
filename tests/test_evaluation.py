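"""Protein-centric Fmax/Smin and term-centric AUROC evaluation."""

import math

import numpy as np
import pytest

from phenomap.annotations import AnnotationSet
from phenomap.evaluation import (
    BenchmarkSet,
    coverage,
    evaluate,
    fmax_curve,
    smin,
    term_centric_auroc,
    threshold_metrics,
)
from phenomap.ontology import OntologyDAG, Term, TermInformationContent
from phenomap.prediction import Prediction, PredictionSet
from phenomap.simulate import generate_benchmark_case

A, B, C, ROOT = "HP:0000002", "HP:0000003", "HP:0000004", "HP:0000001"


@pytest.fixture
def two_protein_case(flat_dag):
    """Truth P1:{a,b}, P2:{a}; preds P1:{a@0.9, c@0.4}, P2:{a@0.9, b@0.4}."""
    truth = AnnotationSet({("P1", A), ("P1", B), ("P2", A)})
    bench = BenchmarkSet.from_annotations(truth, flat_dag, proteins=["P1", "P2"])
    preds = PredictionSet(
        [
            Prediction("P1", A, 0.9, ""),
            Prediction("P1", C, 0.4, ""),
            Prediction("P2", A, 0.9, ""),
            Prediction("P2", B, 0.4, ""),
        ]
    )
    ic = TermInformationContent({A: 1.0, B: 1.0, C: 1.0, ROOT: 0.0}, source_count=2)
    return preds, bench, flat_dag, ic


class TestThresholdMetrics:
    def test_perfect_prediction_at_top_threshold(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P1", B)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag)
        preds = PredictionSet([Prediction("P1", A, 1.0, ""), Prediction("P1", B, 1.0, "")])
        ic = TermInformationContent({A: 1.0, B: 2.0}, source_count=1)
        m = threshold_metrics(preds, bench, flat_dag, ic, tau=1.0)
        assert (m.precision, m.recall) == (1.0, 1.0)
        assert (m.ru, m.mi) == (0.0, 0.0)

    def test_hand_enumerated_two_protein_example(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        m = threshold_metrics(preds, bench, dag, ic, tau=0.9)
        assert m.precision == pytest.approx(1.0)
        assert m.recall == pytest.approx(0.75)
        assert m.f_score == pytest.approx(6 / 7)

    def test_empty_predictions_in_full_mode(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        empty = PredictionSet([])
        m = threshold_metrics(empty, bench, dag, ic, tau=0.5)
        assert m.n_predicted_proteins == 0
        assert (m.precision, m.recall, m.f_score) == (0.0, 0.0, 0.0)
        assert m.ru == pytest.approx(1.5)  # mean total truth ic: (2 + 1) / 2
        assert m.mi == 0.0

    def test_truth_size_conservation_at_every_tau(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        truth_total = len(bench.truth)
        for tau in (0.1, 0.4, 0.9, 1.0):
            m = threshold_metrics(preds, bench, dag, ic, tau=tau)
            assert m.tp + m.fn == truth_total

    def test_tau_outside_unit_interval_rejected(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        with pytest.raises(ValueError):
            threshold_metrics(preds, bench, dag, ic, tau=0.0)


class TestFmax:
    def test_worked_example_fmax_is_six_sevenths(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        summary = fmax_curve(preds, bench, dag, ic, tau_grid=[0.4, 0.9])
        f_by_tau = {m.tau: m.f_score for m in summary.curve}
        assert f_by_tau[0.9] == pytest.approx(6 / 7)
        assert f_by_tau[0.4] == pytest.approx(0.6)
        assert summary.fmax == pytest.approx(6 / 7)

    def test_perfect_predictions_reach_fmax_one(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P2", B)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag)
        preds = PredictionSet([Prediction("P1", A, 0.8, ""), Prediction("P2", B, 0.8, "")])
        ic = TermInformationContent({A: 1.0, B: 1.0}, source_count=2)
        assert fmax_curve(preds, bench, flat_dag, ic).fmax == 1.0

    def test_equal_weights_collapse_weighted_to_unweighted(self, two_protein_case):
        preds, bench, dag, _ = two_protein_case
        ones = TermInformationContent({A: 1.0, B: 1.0, C: 1.0}, source_count=2)
        summary = fmax_curve(preds, bench, dag, ones)
        for m in summary.curve:
            assert m.w_precision == pytest.approx(m.precision)
            assert m.w_recall == pytest.approx(m.recall)
        assert summary.weighted_fmax == pytest.approx(summary.fmax)

    def test_recall_non_increasing_in_tau(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        summary = fmax_curve(preds, bench, dag, ic)
        recalls = [m.recall for m in summary.curve]
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_per_tau_recomputation(self, seed, flat_dag):
        rng = np.random.default_rng(seed)
        leaves = [A, B, C, "HP:0000005"]
        proteins = [f"P{i}" for i in range(8)]
        truth_pairs = {
            (p, t) for p in proteins for t in leaves if rng.random() < 0.5
        } or {(proteins[0], A)}
        bench = BenchmarkSet.from_annotations(
            AnnotationSet(truth_pairs), flat_dag, proteins=proteins
        )
        preds = PredictionSet(
            [
                Prediction(p, t, float(round(rng.uniform(0.05, 1.0), 2)), "")
                for p in proteins
                for t in leaves
                if rng.random() < 0.7
            ]
        )
        ic = TermInformationContent({t: 1.0 + i for i, t in enumerate(leaves)}, 8)
        tau_grid = [round(0.1 * i, 1) for i in range(1, 11)]
        summary = fmax_curve(preds, bench, flat_dag, ic, tau_grid)

        # oracle: naive set arithmetic per protein per tau (flat DAG: no propagation)
        def naive(tau):
            truths = {p: {t for q, t in truth_pairs if q == p} for p in proteins}
            pred_sets = {
                p: {pr.hpo_id for pr in preds if pr.protein_id == p and pr.score >= tau}
                for p in proteins
            }
            precs = [
                len(pred_sets[p] & truths[p]) / len(pred_sets[p])
                for p in proteins
                if pred_sets[p]
            ]
            recs = [
                len(pred_sets[p] & truths[p]) / len(truths[p])
                for p in proteins
                if truths[p]
            ]
            rus = [sum(ic[t] for t in truths[p] - pred_sets[p]) for p in proteins]
            mis = [sum(ic[t] for t in pred_sets[p] - truths[p]) for p in proteins]
            prec = float(np.mean(precs)) if precs else 0.0
            rec = float(np.mean(recs)) if recs else 0.0
            f = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            return f, math.hypot(float(np.mean(rus)), float(np.mean(mis)))

        naive_f = [naive(t)[0] for t in tau_grid]
        naive_s = [naive(t)[1] for t in tau_grid] + [naive(1.01)[1]]
        assert summary.fmax == pytest.approx(max(naive_f))
        for m, f in zip(summary.curve, naive_f):
            assert m.f_score == pytest.approx(f)
        assert summary.smin == pytest.approx(min(naive_s))


class TestSmin:
    def test_perfect_predictions_have_zero_smin(self, flat_dag):
        truth = AnnotationSet({("P1", A)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag)
        preds = PredictionSet([Prediction("P1", A, 0.9, "")])
        ic = TermInformationContent({A: 2.0}, source_count=1)
        assert smin(preds, bench, flat_dag, ic) == 0.0

    def test_empty_prediction_threshold_is_always_scanned(self, flat_dag):
        # truth {a(1), b(2)}, preds {a@0.9, c@0.9 (ic 3)}:
        # tau<=0.9 gives sqrt(2^2+3^2); dropping everything gives 3.0
        truth = AnnotationSet({("P1", A), ("P1", B)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag)
        preds = PredictionSet([Prediction("P1", A, 0.9, ""), Prediction("P1", C, 0.9, "")])
        ic = TermInformationContent({A: 1.0, B: 2.0, C: 3.0}, source_count=1)
        assert smin(preds, bench, flat_dag, ic, tau_grid=[0.5, 0.9]) == pytest.approx(3.0)
        # and the scanned grid point 0.9 itself gives sqrt(13)
        m = threshold_metrics(preds, bench, flat_dag, ic, tau=0.9)
        assert m.semantic_distance == pytest.approx(math.sqrt(13))

    def test_never_exceeds_empty_prediction_distance(self, two_protein_case):
        preds, bench, dag, ic = two_protein_case
        empty_distance = math.hypot(
            np.mean([sum(ic[t] for t in bench.truth.by_entity[p]) for p in bench.proteins]), 0
        )
        assert smin(preds, bench, dag, ic) <= empty_distance + 1e-12


class TestTermCentricAuroc:
    def test_separated_scores_give_unit_auroc(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P2", A)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag, proteins=["P1", "P2", "P3"])
        preds = PredictionSet([Prediction("P1", A, 0.9, ""), Prediction("P2", A, 0.8, "")])
        per_term, macro, skipped = term_centric_auroc(preds, bench)
        assert per_term[A] == 1.0
        assert macro == 1.0

    def test_identical_scores_give_half(self, flat_dag):
        truth = AnnotationSet({("P1", A)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag, proteins=["P1", "P2"])
        preds = PredictionSet(
            [Prediction("P1", A, 0.5, ""), Prediction("P2", A, 0.5, "")]
        )
        per_term, macro, _ = term_centric_auroc(preds, bench)
        assert per_term[A] == pytest.approx(0.5)

    def test_mann_whitney_pairwise_example(self, flat_dag):
        # positives {0.9, 0.4}, negative {0.6}: (1 win + 1 loss) / 2 pairs
        truth = AnnotationSet({("P1", A), ("P2", A)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag, proteins=["P1", "P2", "P3"])
        preds = PredictionSet(
            [
                Prediction("P1", A, 0.9, ""),
                Prediction("P2", A, 0.4, ""),
                Prediction("P3", A, 0.6, ""),
            ]
        )
        per_term, _, _ = term_centric_auroc(preds, bench)
        assert per_term[A] == pytest.approx(0.5)

    def test_all_positive_terms_are_skipped(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P2", A)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag, proteins=["P1", "P2"])
        per_term, macro, skipped = term_centric_auroc(PredictionSet([]), bench)
        assert per_term == {}
        assert skipped == [A]
        assert math.isnan(macro)


class TestCoverage:
    def test_extremes(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P2", B)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag)
        full = PredictionSet([Prediction("P1", A, 0.5, ""), Prediction("P2", C, 0.5, "")])
        assert coverage(full, bench) == 1.0
        assert coverage(PredictionSet([]), bench) == 0.0

    def test_fractional_count(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P2", B), ("P3", C)})
        bench = BenchmarkSet.from_annotations(truth, flat_dag)
        preds = PredictionSet([Prediction("P1", A, 0.5, "")])
        assert coverage(preds, bench) == pytest.approx(1 / 3)

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            coverage(PredictionSet([]), BenchmarkSet(AnnotationSet([]), (), "full"))


class TestModes:
    def test_partial_mode_restricts_recall_pool(self, flat_dag):
        truth = AnnotationSet({("P1", A), ("P2", B)})
        preds = PredictionSet([Prediction("P1", A, 0.9, "")])
        ic = TermInformationContent({A: 1.0, B: 1.0}, source_count=2)
        full = BenchmarkSet.from_annotations(truth, flat_dag, mode="full")
        partial = BenchmarkSet.from_annotations(truth, flat_dag, mode="partial")
        m_full = threshold_metrics(preds, full, flat_dag, ic, tau=0.5)
        m_partial = threshold_metrics(preds, partial, flat_dag, ic, tau=0.5)
        assert m_full.recall == pytest.approx(0.5)     # (1 + 0) / 2 proteins
        assert m_partial.recall == pytest.approx(1.0)  # predicted protein only
        assert m_full.precision == m_partial.precision


class TestSyntheticBenchmark:
    def test_perfect_separability_maxes_all_metrics(self):
        case = generate_benchmark_case(separability=1.0)
        summary = evaluate(case.predictions, case.benchmark, case.dag, case.ic)
        assert summary.fmax == 1.0
        assert summary.smin == 0.0
        assert summary.macro_auroc == 1.0
        assert summary.coverage == 1.0
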