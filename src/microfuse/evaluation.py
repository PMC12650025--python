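"""Subject-independent cross-validation plans, classification metrics and
microstate group comparison.

Fold plans partition *subjects* (never samples), stratified by group, so no
subject contributes to both the training and test side of any fold; within
each fold's non-test subjects an 80/20 train/validation split is drawn, also
by subject.  Metrics are computed from the confusion counts by their
definitional formulas; ratios with zero denominators are returned as NaN
with a flag rather than silently coerced to 0.  Group differences in the
microstate features use a two-sided Mann-Whitney U test per feature (the
direction is the sign of the case-minus-control mean difference), with an
optional Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "Fold",
    "FoldPlan",
    "make_subject_folds",
    "confusion_from_predictions",
    "classification_metrics",
    "rmse",
    "group_compare",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class Fold:
    train_subjects: list[str]
    val_subjects: list[str]
    test_subjects: list[str]


@dataclass
class FoldPlan:
    folds: list[Fold]

    def validate(self) -> None:
        """Assert the no-leakage partition laws."""
        all_test: list[str] = []
        for f in self.folds:
            tr, va, te = map(set, (f.train_subjects, f.val_subjects, f.test_subjects))
            if tr & te or va & te or tr & va:
                raise AssertionError("subject leakage across splits")
            all_test.extend(f.test_subjects)
        if len(all_test) != len(set(all_test)):
            raise AssertionError("subject in more than one test fold")


def make_subject_folds(
    subject_ids: list[str],
    labels: list | np.ndarray,
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> FoldPlan:
    """Stratified-by-group subject partition into k test folds, with an
    80/20 train/validation subject split inside each fold's remainder."""
    subject_ids = list(subject_ids)
    labels = np.asarray(labels)
    if len(subject_ids) != len(labels):
        raise ValueError("subject_ids and labels length mismatch")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    if len(subject_ids) < k:
        raise ValueError(f"fewer subjects ({len(subject_ids)}) than folds ({k})")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    subjects = np.asarray(subject_ids)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    folds = []
    for rest_idx, test_idx in skf.split(subjects, labels):
        rest, rest_y = subjects[rest_idx], labels[rest_idx]
        # stratified 80/20 subject split for validation
        val_sel = np.zeros(len(rest), dtype=bool)
        for cls in np.unique(rest_y):
            cls_idx = np.nonzero(rest_y == cls)[0]
            n_val = max(1, int(round(val_fraction * len(cls_idx))))
            val_sel[rng.choice(cls_idx, size=n_val, replace=False)] = True
        folds.append(Fold(
            train_subjects=list(rest[~val_sel]),
            val_subjects=list(rest[val_sel]),
            test_subjects=list(subjects[test_idx]),
        ))
    plan = FoldPlan(folds)
    plan.validate()
    return plan


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and Cohen's kappa from a confusion
    table.  Undefined ratios are NaN and listed in ``"undefined"``."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (tp + tn) / n
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n ** 2
    if p_e == 1.0:
        undefined.append("kappa")
        kappa = float("nan")
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "kappa": kappa, "undefined": undefined}


def rmse(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Root-mean-square deviation of predicted probabilities from labels."""
    y_true = np.asarray(y_true, dtype=float)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("empty input")
    if np.any((y_prob < 0) | (y_prob > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    return float(np.sqrt(((y_true - y_prob) ** 2).mean()))


def group_compare(
    feature_table: pd.DataFrame,
    group_labels: np.ndarray | list,
    alpha: float = 0.05,
    case_label: str = "case",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided rank test between case and control subjects.

    Returns a table with the effect direction (sign of case-minus-control
    mean difference, printed ``up``/``down``), the Mann-Whitney p-value and
    a significance flag at ``alpha`` (optionally BH-FDR adjusted).
    """
    groups = np.asarray(group_labels)
    case = feature_table.loc[groups == case_label]
    ctrl = feature_table.loc[groups != case_label]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for col in feature_table.columns:
        a, b = case[col].to_numpy(dtype=float), ctrl[col].to_numpy(dtype=float)
        diff = a.mean() - b.mean()
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": col, "direction": "up" if diff > 0 else "down",
                     "mean_diff": diff, "p": p})
    out = pd.DataFrame(rows)
    if fdr:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(order[::-1]):
            i = m - rank
            prev = min(prev, out["p"].iloc[idx] * m / i)
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out
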