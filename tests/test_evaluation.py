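"""Metric panels against brute-force oracles; bootstrap CIs; rank analysis."""

import numpy as np
import pandas as pd
import pytest

from ecgorigin.anatomy import CreditMatrix, partial_credit_matrix
from ecgorigin.evaluation import (accuracy_and_adjusted, bootstrap_ci,
                                  confusion, metric_report,
                                  one_vs_rest_metrics, topk_analysis,
                                  weighted_average)


def _brute_force_panel(y_true, y_pred, classes):
    """Independent tally straight from the label pairs."""
    rows = {}
    n = len(y_true)
    for c in classes:
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        tn = n - tp - fn - fp
        div = lambda a, b: a / b if b else np.nan
        se, sp = div(tp, tp + fn), div(tn, tn + fp)
        ppv, npv = div(tp, tp + fp), div(tn, tn + fn)
        f1 = (2 * ppv * se / (ppv + se)
              if not (np.isnan(ppv) or np.isnan(se)) and (ppv + se) > 0
              else np.nan)
        rows[c] = dict(SE=se, SP=sp, PPV=ppv, NPV=npv, F1=f1,
                       balanced_accuracy=(se + sp) / 2)
    return pd.DataFrame(rows).T


class TestConfusion:
    def test_hand_tally(self):
        cm = confusion(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_perfect_is_diagonal(self):
        cm = confusion(["A", "B", "B"], ["A", "B", "B"], ["A", "B"])
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_empty(self):
        cm = confusion([], [], ["A", "B"])
        assert cm.total == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="C"):
            confusion(["C"], ["A"], ["A", "B"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["A"], [], ["A"])


class TestOneVsRest:
    def test_two_class_hand_arithmetic(self):
        cm = confusion(
            ["1"] * 10 + ["2"] * 10,
            ["1"] * 8 + ["2"] * 2 + ["1"] * 1 + ["2"] * 9, ["1", "2"])
        np.testing.assert_array_equal(cm.counts, [[8, 2], [1, 9]])
        panel = one_vs_rest_metrics(cm)
        assert panel.loc["1", "SE"] == pytest.approx(0.8)
        assert panel.loc["1", "SP"] == pytest.approx(0.9)
        assert panel.loc["1", "PPV"] == pytest.approx(8 / 9)
        assert panel.loc["1", "F1"] == pytest.approx(
            2 * (8 / 9) * 0.8 / ((8 / 9) + 0.8))
        assert panel.loc["1", "balanced_accuracy"] == pytest.approx(0.85)

    def test_diagonal_all_ones(self):
        cm = confusion(["A", "B", "C"], ["A", "B", "C"], ["A", "B", "C"])
        panel = one_vs_rest_metrics(cm)
        for col in ("SE", "SP", "PPV", "NPV", "F1", "balanced_accuracy"):
            np.testing.assert_allclose(panel[col], 1.0)

    def test_zero_predicted_positives_undefined_ppv(self):
        cm = confusion(["A", "A", "B"], ["B", "B", "B"], ["A", "B"])
        panel = one_vs_rest_metrics(cm)
        assert np.isnan(panel.loc["A", "PPV"])
        assert np.isnan(panel.loc["A", "F1"])
        assert panel.loc["A", "SE"] == 0.0

    def test_brute_force_oracle_random_instances(self):
        """Panel equals an independent tally on 50 random instances."""
        classes = ["a", "b", "c", "d"]
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 200))
            y = rng.choice(classes, n)
            p = rng.choice(classes, n)
            cm = confusion(y, p, classes)
            panel = one_vs_rest_metrics(cm)[list(
                ("SE", "SP", "PPV", "NPV", "F1", "balanced_accuracy"))]
            oracle = _brute_force_panel(y, p, classes)
            pd.testing.assert_frame_equal(panel, oracle[panel.columns],
                                          check_names=False, atol=1e-12)

    def test_micro_identity_accuracy_equals_weighted_se(self, rng):
        y = rng.choice(["x", "y", "z"], 120)
        p = rng.choice(["x", "y", "z"], 120)
        cm = confusion(y, p, ["x", "y", "z"])
        panel = one_vs_rest_metrics(cm)
        avg = weighted_average(panel)
        acc, _ = accuracy_and_adjusted(cm)
        assert avg["SE"] == pytest.approx(acc)


class TestWeightedAverage:
    def test_equal_supports(self):
        panel = pd.DataFrame({"SE": [0.8, 1.0], "SP": [1, 1], "PPV": [1, 1],
                              "NPV": [1, 1], "F1": [1, 1],
                              "balanced_accuracy": [1, 1],
                              "support": [5, 5]}, index=["A", "B"])
        assert weighted_average(panel)["SE"] == pytest.approx(0.9)

    def test_unequal_supports(self):
        panel = pd.DataFrame({"SE": [1.0, 0.0], "SP": [1, 1], "PPV": [1, 1],
                              "NPV": [1, 1], "F1": [1, 1],
                              "balanced_accuracy": [1, 1],
                              "support": [3, 1]}, index=["A", "B"])
        assert weighted_average(panel)["SE"] == pytest.approx(0.75)

    def test_undefined_classes_renormalized(self):
        panel = pd.DataFrame({"SE": [0.5, np.nan], "SP": [1, 1],
                              "PPV": [1, 1], "NPV": [1, 1], "F1": [1, 1],
                              "balanced_accuracy": [1, 1],
                              "support": [2, 8]}, index=["A", "B"])
        assert weighted_average(panel)["SE"] == pytest.approx(0.5)

    def test_all_undefined_stays_undefined(self):
        panel = pd.DataFrame({"SE": [np.nan], "SP": [1], "PPV": [1],
                              "NPV": [1], "F1": [1],
                              "balanced_accuracy": [1], "support": [4]},
                             index=["A"])
        assert np.isnan(weighted_average(panel)["SE"])


class TestAdjustedAccuracy:
    def test_identity_credit_reduces_to_accuracy(self):
        cm = confusion(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
        credit = CreditMatrix(4, ("A", "B"), np.eye(2))
        acc, adj = accuracy_and_adjusted(cm, credit)
        assert adj == pytest.approx(acc)

    def test_hand_computation_with_half_credit(self):
        cm = confusion(["1", "1", "2", "2"], ["1", "2", "2", "2"], ["1", "2"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])
        credit = CreditMatrix(4, ("1", "2"),
                              np.array([[1.0, 0.5], [0.5, 1.0]]))
        acc, adj = accuracy_and_adjusted(cm, credit)
        assert acc == pytest.approx(0.75)
        assert adj == pytest.approx(0.875)

    def test_dominance_for_random_credit(self, rng):
        for _ in range(20):
            y = rng.choice(["a", "b", "c"], 60)
            p = rng.choice(["a", "b", "c"], 60)
            cm = confusion(y, p, ["a", "b", "c"])
            w = rng.random((3, 3))
            np.fill_diagonal(w, 1.0)
            credit = CreditMatrix(4, ("a", "b", "c"), w)
            acc, adj = accuracy_and_adjusted(cm, credit)
            assert adj >= acc - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_and_adjusted(confusion([], [], ["A"]))


def _acc(y, p):
    return float(np.mean(y == p))


class TestBootstrap:
    def test_degenerate_constant_metric(self):
        y = ["A"] * 20
        point, lo, hi = bootstrap_ci(_acc, y, y, B=200, seed=0)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_width_matches_binomial_closed_form(self):
        """n=1000, 90% correct: percentile-CI width within +-30% of the
        normal-approximation binomial width 2 * 1.96 * sqrt(pq/n)."""
        n = 1000
        y = np.array(["A"] * n)
        p = np.array(["A"] * 900 + ["B"] * 100)
        point, lo, hi = bootstrap_ci(_acc, y, p, B=2000, seed=1)
        width = hi - lo
        closed_form = 2 * 1.96 * np.sqrt(0.9 * 0.1 / n)
        assert point == pytest.approx(0.9)
        assert abs(width - closed_form) / closed_form < 0.30

    def test_ordering_over_random_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 80))
            y = rng.choice(["A", "B"], n)
            p = rng.choice(["A", "B"], n)
            point, lo, hi = bootstrap_ci(_acc, y, p, B=100, seed=seed)
            assert lo <= point + 1e-9
            assert point <= hi + 1e-9

    def test_deterministic_given_seed(self):
        y = np.array(["A", "B"] * 30)
        p = np.array(["A"] * 60)
        assert (bootstrap_ci(_acc, y, p, B=300, seed=5)
                == bootstrap_ci(_acc, y, p, B=300, seed=5))

    def test_width_shrinks_like_root_n(self):
        widths = []
        for n in (100, 400, 1600):
            y = np.array(["A"] * n)
            p = np.array(["A"] * int(0.9 * n) + ["B"] * (n - int(0.9 * n)))
            _, lo, hi = bootstrap_ci(_acc, y, p, B=500, seed=2)
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)


class TestTopK:
    def test_perfect_top1(self):
        ranked = [[("A", 0.9), ("B", 0.1)]] * 4
        hist = topk_analysis(ranked, ["A"] * 4)
        assert hist == {"1": 4, "2": 0, "3": 0, ">3": 0}

    def test_hand_ranking(self):
        ranked = [[("A", 0.6), ("B", 0.4)], [("A", 0.9), ("B", 0.1)]]
        hist = topk_analysis(ranked, ["B", "A"])
        assert hist == {"1": 1, "2": 1, "3": 0, ">3": 0}

    def test_counts_sum_and_monotone_cumulative(self, rng):
        classes = ["a", "b", "c", "d", "e"]
        ranked, truth = [], []
        for _ in range(50):
            probs = rng.dirichlet(np.ones(5))
            order = np.argsort(-probs)
            ranked.append([(classes[j], probs[j]) for j in order])
            truth.append(rng.choice(classes))
        hist = topk_analysis(ranked, truth)
        assert sum(hist.values()) == 50
        cum = np.cumsum([hist["1"], hist["2"], hist["3"]])
        assert all(np.diff(cum) >= 0)


class TestMetricReport:
    def test_report_assembles_and_serializes(self, tmp_path, rng):
        y = rng.choice(["LAF", "LPF", "MV"], 60)
        p = rng.choice(["LAF", "LPF", "MV"], 60)
        credit = partial_credit_matrix(4)
        # restrict credit to present classes via the full scheme-4 report
        report = metric_report(y, p, credit.classes, credit=credit,
                               B=100, seed=0)
        assert 0 <= report.accuracy <= 1
        assert report.adjusted_accuracy >= report.accuracy - 1e-12
        doc = report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()
        assert doc["accuracy"] == report.accuracy
        table = report.to_table()
        assert "Average" in table.index
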