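"""Unit tests for splits, confusion metrics, ROC/AUC and cvAUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tepimage import evaluate as ev


def make_strata(sizes: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    ids, strata = [], {}
    for name, n in sizes.items():
        for i in range(n):
            sid = f"{name}_{i:03d}"
            ids.append(sid)
            strata[sid] = name
    return ids, strata


class TestStratifiedHoldout:
    def test_forty_percent_of_ovarian_style_cohort(self):
        """28/30/204 strata at 40% must yield an 11/12/81 test set (floor rule)."""
        ids, strata = make_strata({"oc": 28, "benign": 30, "healthy": 204})
        plan = ev.stratified_holdout(ids, strata, test_frac=0.40, seed=3)
        counts = pd.Series([strata[s] for s in plan.test_ids]).value_counts()
        assert counts["oc"] == 11
        assert counts["benign"] == 12
        assert counts["healthy"] == 81

    def test_zero_fraction_gives_empty_test_set(self):
        ids, strata = make_strata({"a": 5, "b": 5})
        assert ev.stratified_holdout(ids, strata, test_frac=0.0).test_ids == []

    def test_same_seed_same_plan(self):
        ids, strata = make_strata({"a": 20, "b": 30})
        p1 = ev.stratified_holdout(ids, strata, seed=9)
        p2 = ev.stratified_holdout(ids, strata, seed=9)
        assert p1.test_ids == p2.test_ids

    def test_input_order_invariance(self):
        ids, strata = make_strata({"a": 20, "b": 30})
        p1 = ev.stratified_holdout(ids, strata, seed=9)
        p2 = ev.stratified_holdout(list(reversed(ids)), strata, seed=9)
        assert p1.test_ids == p2.test_ids

    def test_invalid_fraction_rejected(self):
        ids, strata = make_strata({"a": 5})
        with pytest.raises(ValueError, match="test_frac"):
            ev.stratified_holdout(ids, strata, test_frac=1.0)


class TestStratifiedKFold:
    def test_exact_divisibility_case(self):
        ids, strata = make_strata({"pos": 10, "neg": 40})
        plan = ev.stratified_kfold(ids, strata, k=5, seed=0)
        for _, val in plan.folds:
            vals = pd.Series([strata[s] for s in val]).value_counts()
            assert vals["pos"] == 2 and vals["neg"] == 8

    def test_validation_sets_partition_cohort(self):
        ids, strata = make_strata({"pos": 13, "neg": 29})
        plan = ev.stratified_kfold(ids, strata, k=5, seed=1)
        all_val = list(itertools.chain.from_iterable(v for _, v in plan.folds))
        assert sorted(all_val) == sorted(ids)
        assert len(set(all_val)) == len(all_val)
        for train, val in plan.folds:
            assert set(train) == set(ids) - set(val)

    def test_stratum_balance_within_one(self):
        ids, strata = make_strata({"pos": 13, "neg": 29})
        plan = ev.stratified_kfold(ids, strata, k=5, seed=1)
        for name, n in (("pos", 13), ("neg", 29)):
            per_fold = [
                sum(strata[s] == name for s in val) for _, val in plan.folds
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_same_seed_same_folds(self):
        ids, strata = make_strata({"pos": 10, "neg": 20})
        assert (
            ev.stratified_kfold(ids, strata, seed=4).folds
            == ev.stratified_kfold(ids, strata, seed=4).folds
        )

    def test_tiny_stratum_merged_with_warning(self, caplog):
        ids, strata = make_strata({"pos": 3, "neg": 30})
        with caplog.at_level("WARNING"):
            plan = ev.stratified_kfold(ids, strata, k=5, seed=0)
        assert "merging" in caplog.text
        assert len(plan.folds) == 5

    def test_k_below_two_rejected(self):
        ids, strata = make_strata({"a": 10})
        with pytest.raises(ValueError, match="k must be"):
            ev.stratified_kfold(ids, strata, k=1)


class TestConfusionMetrics:
    def test_hand_counted_confusion(self):
        # TP=3 FP=1 FN=1 TN=5
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.2, 0.3, 0.4, 0.45]
        m = ev.confusion_metrics(y, s)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 1, 5)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.8333, abs=1e-4)
        assert m["balanced_accuracy"] == pytest.approx(0.7917, abs=1e-4)
        assert m["precision"] == pytest.approx(0.75)

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        # sens 0.94, spec 0.79 reported as 87% after rounding
        y = [1] * 50 + [0] * 100
        s = [0.9] * 47 + [0.1] * 3 + [0.1] * 79 + [0.9] * 21
        m = ev.confusion_metrics(y, s)
        assert m["sensitivity"] == pytest.approx(0.94)
        assert m["specificity"] == pytest.approx(0.79)
        assert m["balanced_accuracy"] == pytest.approx(0.865)
        assert ev.round_percent(m["balanced_accuracy"]) == 87

    def test_perfect_classifier(self):
        m = ev.confusion_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        for name in ("sensitivity", "specificity", "balanced_accuracy",
                     "precision", "recall"):
            assert m[name] == 1.0

    def test_threshold_counts_as_positive(self):
        m = ev.confusion_metrics([1, 0], [0.5, 0.4], threshold=0.5)
        assert m["tp"] == 1 and m["fp"] == 0

    def test_recall_equals_sensitivity_and_precision_consistency(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        m = ev.confusion_metrics(y, s)
        assert m["recall"] == m["sensitivity"]
        n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
        implied = ev.implied_precision(
            m["sensitivity"], m["specificity"], n_pos, n_neg
        )
        assert m["precision"] == pytest.approx(implied)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ev.confusion_metrics([1, 0], [1.2, 0.1])


class TestSpecificityAtFullSensitivity:
    def test_perfect_separation(self):
        assert ev.specificity_at_full_sensitivity(
            [1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]
        ) == 1.0

    def test_brute_force_example(self):
        y = [1, 1, 0, 0, 0, 0]
        s = [0.6, 0.2, 0.1, 0.3, 0.5, 0.7]
        assert ev.specificity_at_full_sensitivity(y, s) == pytest.approx(0.25)

    def test_case_at_global_minimum_gives_zero(self):
        y = [1, 0, 0]
        s = [0.05, 0.5, 0.9]
        assert ev.specificity_at_full_sensitivity(y, s) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_threshold_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y.all():
            y[0] = 0
        s = rng.random(n).round(2)
        best = 0.0
        for t in np.unique(s):
            pred = s >= t
            if (pred[y == 1]).all():
                spec = float((~pred[y == 0]).mean())
                best = max(best, spec)
        assert ev.specificity_at_full_sensitivity(y, s) == pytest.approx(best)


def brute_force_auc(y, s):
    y, s = np.asarray(y), np.asarray(s)
    pairs = concordant = tied = 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            pairs += 1
            if s[i] > s[j]:
                concordant += 1
            elif s[i] == s[j]:
                tied += 1
    return (concordant + 0.5 * tied) / pairs


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert ev.roc_auc([1, 0], [0.9, 0.1]) == 1.0
        assert ev.roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_auc([1, 1], [0.5, 0.6])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y.all():
            y[0] = 0
        s = rng.random(n).round(1)  # coarse grid to generate ties
        assert ev.roc_auc(y, s) == pytest.approx(brute_force_auc(y, s))


class TestRocPoints:
    def test_staircase_and_area_consistency(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 8 + [0] * 12)
        s = rng.random(20)
        pts = ev.roc_points(y, s)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr, tpr = zip(*pts)
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))
        area = np.trapezoid(tpr, fpr)
        assert area == pytest.approx(ev.roc_auc(y, s), abs=1e-9)

    def test_perfect_scores_pass_through_corner(self):
        pts = ev.roc_points([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (0.0, 1.0) in pts

    def test_reversed_scores_mirror_area(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 5 + [0] * 5)
        s = rng.random(10)
        a = ev.roc_auc(y, s)
        pts = ev.roc_points(y, 1 - s)
        fpr, tpr = zip(*pts)
        assert np.trapezoid(tpr, fpr) == pytest.approx(1 - a, abs=1e-9)


class TestCvAuc:
    def _fold(self, case_score):
        y = np.array([1, 0, 0, 0, 0, 0])
        s = np.array([case_score, 0.1, 0.2, 0.3, 0.4, 0.5])
        return y, s

    def test_degenerate_perfect_folds(self):
        folds = [
            (np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
            for _ in range(3)
        ]
        out = ev.cv_auc(folds)
        assert out["cvauc"] == 1.0
        assert out["ci95"] == (1.0, 1.0)

    def test_mean_of_fold_aucs(self):
        folds = [self._fold(0.45), self._fold(0.5), self._fold(0.6)]
        out = ev.cv_auc(folds)
        assert out["fold_aucs"] == pytest.approx([0.8, 0.9, 1.0])
        assert out["cvauc"] == pytest.approx(0.9)

    def test_single_class_fold_dropped_with_warning(self, caplog):
        folds = [
            self._fold(0.45),
            self._fold(0.5),
            (np.array([0, 0, 0]), np.array([0.1, 0.2, 0.3])),
        ]
        with caplog.at_level("WARNING"):
            out = ev.cv_auc(folds)
        assert "dropped" in caplog.text
        assert len(out["fold_aucs"]) == 2

    def test_all_folds_dropped_is_error(self):
        folds = [(np.array([0, 0]), np.array([0.1, 0.2]))] * 3
        with pytest.raises(ValueError):
            ev.cv_auc(folds)

    def test_influence_curve_se_close_to_bootstrap(self):
        """IC-based SE should track a within-fold bootstrap SE on a toy set."""
        rng = np.random.default_rng(10)
        folds = []
        for _ in range(5):
            y = np.array([1] * 15 + [0] * 25)
            s = np.clip(
                np.where(y == 1, 0.62, 0.42) + rng.normal(0, 0.18, 40), 0, 1
            )
            folds.append((y, s))
        out = ev.cv_auc(folds)
        boot = []
        for _ in range(400):
            aucs = []
            for y, s in folds:
                idx = np.concatenate([
                    rng.choice(np.flatnonzero(y == 1), 15),
                    rng.choice(np.flatnonzero(y == 0), 25),
                ])
                aucs.append(ev.roc_auc(y[idx], s[idx]))
            boot.append(np.mean(aucs))
        boot_se = np.std(boot, ddof=1)
        assert out["se"] == pytest.approx(boot_se, rel=0.20)


class TestAggregateOverFolds:
    def test_identical_folds_have_zero_sd(self):
        y = pd.Series([1, 1, 0, 0], index=list("abcd"))
        scores = [np.array([0.9, 0.8, 0.2, 0.1])] * 3
        rep = ev.aggregate_over_folds(y, scores)
        assert all(v == 0.0 for v in rep.sd.values())
        assert all(lo == hi for lo, hi in rep.ci95.values())

    def test_two_point_aggregation(self):
        y = pd.Series([1] * 50 + [0] * 100)
        # Fold A: sens 0.94, spec 0.80 -> bal 0.87; fold B: sens 1.0, spec 0.92 -> 0.96
        s_a = np.array([0.9] * 47 + [0.1] * 3 + [0.1] * 80 + [0.9] * 20)
        s_b = np.array([0.9] * 50 + [0.1] * 92 + [0.9] * 8)
        rep = ev.aggregate_over_folds(y, [s_a, s_b])
        assert rep.per_fold[0]["balanced_accuracy"] == pytest.approx(0.87)
        assert rep.per_fold[1]["balanced_accuracy"] == pytest.approx(0.96)
        assert rep.mean["balanced_accuracy"] == pytest.approx(0.915)
        assert ev.round_percent(rep.mean["balanced_accuracy"]) == 92

    def test_tep_score_is_mean_of_fold_scores(self):
        y = pd.Series([1, 0], index=["a", "b"])
        scores = [np.array([v, 0.0]) for v in (0.2, 0.4, 0.6, 0.8, 1.0)]
        rep = ev.aggregate_over_folds(y, scores)
        assert rep.tep_scores["a"] == pytest.approx(0.6)

    def test_report_serializes_with_rounded_percents(self):
        y = pd.Series([1, 1, 0, 0])
        rep = ev.aggregate_over_folds(y, [np.array([0.9, 0.8, 0.2, 0.1])])
        payload = rep.to_json()
        assert '"mean_percent_rounded"' in payload
        assert '"sensitivity": 100' in payload


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.865, 87), (0.915, 92), (0.864, 86), (0.5, 50), (0.005, 1)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert ev.round_percent(value) == expected
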