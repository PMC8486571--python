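"""Validation design: stratified splits, confusion metrics, ROC and cvAUC.

The study design is a stratified 40% hold-out (the independent test set)
followed by stratified 5-fold cross-validation on the remainder; each fold
model is evaluated on its validation subgroup and on the fixed test set.
Strata carry both the class and the control subtype (healthy vs benign) so
class balance is preserved at that finer grain.

The metric suite reports sensitivity, specificity, balanced accuracy,
precision, recall, specificity at full sensitivity, and AUC, aggregated
over fold models as mean / sample SD / normal-approximation 95% CI.
Cross-validated AUC is the mean of per-fold AUCs with an influence-curve
standard error (the pooled per-observation projection of the Mann-Whitney
U statistic).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "stratified_holdout",
    "stratified_kfold",
    "confusion_metrics",
    "specificity_at_full_sensitivity",
    "implied_precision",
    "roc_auc",
    "roc_points",
    "cv_auc",
    "aggregate_over_folds",
    "round_percent",
]

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "precision",
    "recall",
    "specificity_at_full_sensitivity",
    "auc",
)


def round_percent(fraction: float) -> int:
    """Report a rate as an integer percentage, rounding half away from zero."""
    x = 100.0 * fraction
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SplitPlan:
    """Test-set ids plus per-fold (train, validation) id lists."""

    test_ids: list[str] = field(default_factory=list)
    folds: list[tuple[list[str], list[str]]] = field(default_factory=list)
    strata: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (sample_id, subset, fold) for TSV export."""
        rows = [(sid, "test", -1) for sid in self.test_ids]
        for k, (_, val) in enumerate(self.folds):
            rows.extend((sid, "validation", k) for sid in val)
        return pd.DataFrame(rows, columns=["sample_id", "subset", "fold"])


def _check_strata(ids, strata) -> pd.Series:
    s = pd.Series(strata).reindex(ids)
    if s.isna().any():
        missing = list(s.index[s.isna()])
        raise ValueError(f"samples missing a stratum label: {missing[:5]}")
    return s


def stratified_holdout(ids, strata, test_frac: float = 0.40, seed: int = 0) -> SplitPlan:
    """Draw ``floor(test_frac * n)`` samples per stratum into the test set.

    Ids are sorted before seeding, so the plan depends only on the id set,
    the strata and the seed — never on input order.
    """
    if not (0 <= test_frac < 1):
        raise ValueError("test_frac must lie in [0, 1)")
    ids = sorted(ids)
    s = _check_strata(ids, strata)
    rng = np.random.default_rng(seed)
    test: list[str] = []
    for stratum in sorted(s.unique()):
        members = [i for i in ids if s[i] == stratum]
        n_test = int(math.floor(test_frac * len(members)))
        picked = rng.choice(len(members), size=n_test, replace=False)
        test.extend(members[j] for j in sorted(picked))
    plan = SplitPlan(test_ids=sorted(test), strata=dict(s))
    logger.info(
        "stratified_holdout: %d of %d samples held out for testing",
        len(plan.test_ids), len(ids),
    )
    return plan


def stratified_kfold(ids, strata, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition ids into k stratified folds (proportions preserved +/-1).

    Strata smaller than k are merged with the next-smallest stratum (with a
    warning) until every stratum can appear in each fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = sorted(ids)
    s = _check_strata(ids, strata).astype(str)

    counts = s.value_counts()
    while (counts < k).any() and len(counts) > 1:
        small = counts.idxmin()
        rest = counts.drop(index=small)
        target = rest.idxmin()
        logger.warning(
            "stratified_kfold: stratum %r has %d < k=%d samples; merging into %r",
            small, int(counts[small]), k, target,
        )
        s = s.replace(small, target)
        counts = s.value_counts()
    if (counts < k).any():
        raise ValueError(f"cannot form {k} folds: only {len(ids)} samples")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    id_arr = np.array(ids)
    folds = [
        (sorted(id_arr[tr]), sorted(id_arr[va]))
        for tr, va in skf.split(id_arr, s.to_numpy())
    ]
    return SplitPlan(folds=folds, strata=dict(_check_strata(ids, strata)))


def _validate_scores(scores) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    return s


def _validate_labels(y_true) -> np.ndarray:
    y = np.asarray(y_true).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def confusion_metrics(y_true, scores, threshold: float = 0.5) -> dict[str, float]:
    """Threshold the scores and compute the confusion-matrix metric suite.

    A score equal to the threshold counts as a positive call.  Precision is
    reported as 0 (with a log note) when no positive calls are made.
    """
    y = _validate_labels(y_true)
    s = _validate_scores(scores)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        logger.info("confusion_metrics: no positive calls; precision set to 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "precision": prec,
        "recall": sens,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def specificity_at_full_sensitivity(y_true, scores) -> float:
    """Specificity at the most permissive threshold with sensitivity 1.

    The threshold is the minimum score over true cases; every sample at or
    above it is called positive.
    """
    y = _validate_labels(y_true)
    s = _validate_scores(scores)
    t_star = s[y == 1].min()
    controls = s[y == 0]
    tn = int((controls < t_star).sum())
    return tn / len(controls)


def implied_precision(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> float:
    """Precision implied by sensitivity, specificity and the class counts.

    TP = sensitivity * n_pos and FP = (1 - specificity) * n_neg, so
    precision = TP / (TP + FP).  Useful for checking that a reported
    metric set is internally consistent.
    """
    tp = sensitivity * n_pos
    fp = (1.0 - specificity) * n_neg
    if tp + fp == 0:
        return 0.0
    return tp / (tp + fp)


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied pairs) / (n1 * n0)."""
    y = _validate_labels(y_true)
    s = _validate_scores(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(y_true, scores) -> list[tuple[float, float]]:
    """Monotone ROC staircase from (0,0) to (1,1) as (FPR, TPR) pairs."""
    y = _validate_labels(y_true)
    s = _validate_scores(scores)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def _auc_influence(y: np.ndarray, s: np.ndarray, auc: float) -> np.ndarray:
    """Per-observation influence-curve values for the empirical AUC."""
    n = len(y)
    cases = s[y == 1]
    controls = s[y == 0]
    p1 = len(cases) / n
    p0 = 1.0 - p1
    ic = np.empty(n, dtype=float)
    for i in range(n):
        if y[i] == 1:
            f0 = ((controls < s[i]).mean() + 0.5 * (controls == s[i]).mean())
            ic[i] = (f0 - auc) / p1
        else:
            g1 = ((cases > s[i]).mean() + 0.5 * (cases == s[i]).mean())
            ic[i] = (g1 - auc) / p0
    return ic


def cv_auc(per_fold: list[tuple[np.ndarray, np.ndarray]]) -> dict[str, float]:
    """Cross-validated AUC with an influence-curve 95% confidence interval.

    ``per_fold`` is a list of (y_true, scores) pairs, one per fold.  Folds
    with a single class are dropped with a warning.  The variance estimate
    pools per-observation influence curves: ``SE^2 = K^-2 * sum_k
    var(IC_k)/n_k``.
    """
    kept = []
    for i, (y, s) in enumerate(per_fold):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            logger.warning("cv_auc: fold %d has one class; dropped", i)
            continue
        kept.append((y, _validate_scores(s)))
    if len(kept) < 2:
        raise ValueError("cv_auc requires >= 2 folds with both classes")
    fold_aucs = [roc_auc(y, s) for y, s in kept]
    k = len(kept)
    cvauc = float(np.mean(fold_aucs))
    var_sum = 0.0
    for (y, s), auc in zip(kept, fold_aucs):
        ic = _auc_influence(y, s, auc)
        var_sum += ic.var(ddof=1) / len(ic)
    se = math.sqrt(var_sum) / k
    lo = max(0.0, cvauc - 1.96 * se)
    hi = min(1.0, cvauc + 1.96 * se)
    return {
        "cvauc": cvauc,
        "se": se,
        "sd": float(np.std(fold_aucs, ddof=1)),
        "ci95": (lo, hi),
        "fold_aucs": fold_aucs,
    }


@dataclass
class MetricsReport:
    """Per-fold metrics on the fixed test set plus mean/SD/CI aggregates."""

    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    tep_scores: pd.Series  # per test sample: mean of fold-model scores

    def to_json(self, **extra) -> str:
        payload = {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "mean_percent_rounded": {
                k: round_percent(v)
                for k, v in self.mean.items()
                if k in METRIC_NAMES
            },
            "tep_scores": self.tep_scores.round(6).to_dict(),
        }
        payload.update(extra)
        return json.dumps(payload, indent=2)


def aggregate_over_folds(
    y_test, fold_scores: list[np.ndarray], threshold: float = 0.5
) -> MetricsReport:
    """Evaluate each fold model's test-set scores and aggregate.

    ``fold_scores`` holds one score vector per fold model, all on the same
    fixed test set.  Aggregates are mean, sample SD, and a normal
    approximation CI (mean +/- 1.96 * SD / sqrt(K)) clipped to [0, 1]; the
    per-sample TEP score is the mean of the fold-model scores.
    """
    if not fold_scores:
        raise ValueError("need at least one fold report")
    y = _validate_labels(y_test)
    per_fold = []
    for s in fold_scores:
        m = confusion_metrics(y, s, threshold=threshold)
        m["specificity_at_full_sensitivity"] = specificity_at_full_sensitivity(y, s)
        m["auc"] = roc_auc(y, s)
        per_fold.append(m)
    k = len(per_fold)
    mean, sd, ci = {}, {}, {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in per_fold])
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if k > 1 else 0.0
        half = 1.96 * sd[name] / math.sqrt(k)
        ci[name] = (max(0.0, mean[name] - half), min(1.0, mean[name] + half))
    stack = np.vstack([np.asarray(s, dtype=float) for s in fold_scores])
    index = (
        y_test.index if isinstance(y_test, pd.Series) else pd.RangeIndex(len(y))
    )
    tep = pd.Series(stack.mean(axis=0), index=index, name="tep_score")
    return MetricsReport(per_fold=per_fold, mean=mean, sd=sd, ci95=ci, tep_scores=tep)
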