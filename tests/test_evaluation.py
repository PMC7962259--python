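"""Metric formulas, single/multi-label scoring and path-length reports."""

import numpy as np
import pytest

from chemont.evaluation import (
    ConfusionCounts,
    f1,
    mean_parent_count,
    path_length_report,
    precision,
    recall,
    score_multi_label,
    score_single_label,
)

from conftest import build_graph


def brute_force_metrics(tp, fp, fn):
    """Independent re-derivation of P/R/F1 by explicit enumeration.

    Materialises the confusion table as individual outcomes and counts.
    """
    outcomes = ["tp"] * tp + ["fp"] * fp + ["fn"] * fn
    n_pred = sum(1 for o in outcomes if o in ("tp", "fp"))
    n_true = sum(1 for o in outcomes if o in ("tp", "fn"))
    n_hit = outcomes.count("tp")
    p = n_hit / n_pred if n_pred else 0.0
    r = n_hit / n_true if n_true else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


class TestMetricFormulas:
    def test_worked_example(self):
        counts = ConfusionCounts(tp=1, fp=1, fn=0)
        assert precision(counts) == 0.5
        assert recall(counts) == 1.0
        assert f1(counts) == pytest.approx(2 / 3)

    def test_zero_denominator_convention(self):
        counts = ConfusionCounts(0, 0, 0)
        assert precision(counts) == recall(counts) == f1(counts) == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 20, size=3)
            counts = ConfusionCounts(int(tp), int(fp), int(fn))
            ep, er, ef = brute_force_metrics(int(tp), int(fp), int(fn))
            assert precision(counts) == pytest.approx(ep)
            assert recall(counts) == pytest.approx(er)
            assert f1(counts) == pytest.approx(ef)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            tp, fp, fn = (int(x) for x in rng.integers(0, 15, size=3))
            counts = ConfusionCounts(tp, fp, fn)
            p, r = precision(counts), recall(counts)
            if p + r > 0:
                assert min(p, r) - 1e-12 <= f1(counts) <= max(p, r) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


class TestSingleLabel:
    def test_perfect_predictions(self):
        truth = {"m1": "A", "m2": "B"}
        rep = score_single_label(dict(truth), truth, ["A", "B"])
        assert all(r.f1 == 1.0 for r in rep.per_class)
        assert rep.macro_f1 == 1.0

    def test_constant_predictor_on_balanced_two_class_set(self):
        truth = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        preds = {m: "A" for m in truth}
        rep = score_single_label(preds, truth, ["A", "B"])
        by_id = {r.class_id: r for r in rep.per_class}
        assert by_id["A"].precision == 0.5 and by_id["A"].recall == 1.0
        assert by_id["B"].f1 == 0.0
        assert "precision" in by_id["B"].zero_division

    def test_macro_f1_is_mean_of_per_class(self):
        truth = {"m1": "A", "m2": "B", "m3": "B"}
        preds = {"m1": "A", "m2": "A", "m3": "B"}
        rep = score_single_label(preds, truth, ["A", "B"])
        assert rep.macro_f1 == pytest.approx(
            np.mean([r.f1 for r in rep.per_class])
        )

    def test_tp_sum_equals_correct_predictions(self):
        rng = np.random.default_rng(3)
        classes = ["A", "B", "C"]
        truth = {f"m{i}": classes[rng.integers(3)] for i in range(60)}
        preds = {m: classes[rng.integers(3)] for m in truth}
        rep = score_single_label(preds, truth, classes)
        correct = sum(1 for m in truth if preds[m] == truth[m])
        assert sum(r.counts.tp for r in rep.per_class) == correct

    def test_member_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            score_single_label({"m1": "A"}, {"m2": "A"}, ["A"])


class TestMultiLabel:
    def test_exact_sets_score_one(self):
        truth = {"m1": {"A", "B"}}
        rep = score_multi_label({"m1": {"A", "B"}}, truth, ["A", "B"])
        assert rep.per_molecule_f1["m1"] == 1.0
        assert rep.abstentions == set()

    def test_abstention_recorded_with_zero_f1(self):
        rep = score_multi_label({"m1": set()}, {"m1": {"A"}}, ["A"])
        assert rep.abstentions == {"m1"}
        assert rep.per_molecule_f1["m1"] == 0.0

    def test_overprediction_f1(self):
        rep = score_multi_label({"m1": {"a", "b"}}, {"m1": {"a"}}, ["a", "b"])
        assert rep.per_molecule_f1["m1"] == pytest.approx(2 / 3)

    def test_permutation_invariant_in_member_order(self):
        truth = {"m1": {"A"}, "m2": {"B"}, "m3": {"A", "B"}}
        preds = {"m1": {"B"}, "m2": {"B"}, "m3": {"A"}}
        rep1 = score_multi_label(preds, truth, ["A", "B"])
        flipped_t = dict(reversed(list(truth.items())))
        flipped_p = dict(reversed(list(preds.items())))
        rep2 = score_multi_label(flipped_p, flipped_t, ["A", "B"])
        assert rep1.macro_f1 == rep2.macro_f1
        assert rep1.per_molecule_f1 == rep2.per_molecule_f1


class TestPathLengthReport:
    def test_exact_match_means_zero(self, chain_graph):
        rep = path_length_report(
            chain_graph, {"m1": {"B"}}, {"m1": {"B"}}
        )
        assert rep.mean == 0.0 and rep.max == 0

    def test_chain_parent_distance_one(self, chain_graph):
        rep = path_length_report(chain_graph, {"m1": {"B"}}, {"m1": {"A"}})
        assert rep.pairwise["m1"] == [1]
        assert rep.per_molecule_min["m1"] == rep.per_molecule_max["m1"] == 1
        assert rep.mean == 1.0

    def test_pair_count_is_cartesian_product(self, diamond_graph):
        rep = path_length_report(
            diamond_graph,
            {"m1": {"B", "C"}},
            {"m1": {"A", "B", "D"}},
        )
        assert len(rep.pairwise["m1"]) == 6

    def test_no_path_pairs_excluded_from_mean(self):
        g = build_graph([("B", "A")], extra_nodes=["Z"])
        rep = path_length_report(g, {"m1": {"A"}}, {"m1": {"B", "Z"}})
        assert rep.n_no_path == 1
        assert rep.mean == 1.0

    def test_min_leq_mean_leq_max_per_molecule(self, diamond_graph):
        rep = path_length_report(
            diamond_graph, {"m1": {"B", "D"}}, {"m1": {"A", "C"}}
        )
        lengths = rep.pairwise["m1"]
        assert rep.per_molecule_min["m1"] <= np.mean(lengths) <= rep.per_molecule_max["m1"]


class TestMeanParentCount:
    def test_singletons(self, chain_graph):
        assert mean_parent_count({"m1": {"A"}, "m2": {"B"}}, chain_graph) == 1.0

    def test_class_plus_ancestor_counts_once(self, chain_graph):
        assert mean_parent_count({"m1": {"C", "A"}}, chain_graph) == 1.0

    def test_mixed_sizes_over_antichain(self):
        g = build_graph([(f"s{i}", "R") for i in range(1, 4)])
        preds = {
            "m1": {"s1"},
            "m2": {"s1", "s2"},
            "m3": {"s1", "s2", "s3"},
        }
        assert mean_parent_count(preds, g) == 2.0

    def test_mixed_sizes_with_condensation(self, diamond_graph):
        preds = {"m1": {"B"}, "m2": {"B", "C"}, "m3": {"B", "C", "D"}}
        # D subsumed by B and C? no: B and C are D's ancestors, so {B,C,D}
        # condenses to {D}
        assert mean_parent_count(preds, diamond_graph) == pytest.approx(
            (1 + 2 + 1) / 3
        )
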