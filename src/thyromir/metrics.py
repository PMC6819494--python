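"""Diagnostic-accuracy metrics, cross-validation, ROC/AUC and rank tests.

Conventions: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN); an undefined ratio (zero denominator)
is reported as None, never as 0.  AUC is computed by the rank (Mann-Whitney)
identity with ties counted one half, and its standard error by the
Hanley-McNeil formula.  Cross-validation is stratified k-fold at the sample
level by default, with optional patient-level grouping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k count table; rows = truth, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("counts must be a square non-negative matrix")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_labels(cls, truth, predicted, classes=None) -> "ConfusionMatrix":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        if len(truth) != len(predicted):
            raise ValueError("truth and predicted differ in length")
        if classes is None:
            classes = tuple(sorted(set(truth) | set(predicted)))
        idx = {c: i for i, c in enumerate(classes)}
        k = len(classes)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(truth, predicted):
            counts[idx[t], idx[p]] += 1
        return cls(counts=counts, classes=tuple(classes))

    @classmethod
    def from_binary_counts(cls, tp: int, fn: int, fp: int, tn: int,
                           positive: str = "malignant",
                           negative: str = "benign") -> "ConfusionMatrix":
        return cls(counts=np.array([[tp, fn], [fp, tn]]),
                   classes=(positive, negative))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.classes, name="truth"),
                            columns=pd.Index(self.classes, name="predicted"))

    def collapse(self, positive_class: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against the rest."""
        if positive_class not in self.classes:
            raise ValueError(f"{positive_class!r} not among {self.classes}")
        i = self.classes.index(positive_class)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = int(self.total - tp - fn - fp)
        return tp, fn, fp, tn


def _ratio(num: int, den: int):
    return None if den == 0 else num / den


def confusion_metrics(cm: ConfusionMatrix, positive_class: str) -> dict:
    """Sensitivity, specificity, PPV, NPV and total error for one class
    versus the rest."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, fp, tn = cm.collapse(positive_class)
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "total_error": (fp + fn) / cm.total,
    }


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Sensitivity and PPV per class (one-vs-rest), as in the study's
    classifier-characteristics tables."""
    rows = {}
    for c in cm.classes:
        m = confusion_metrics(cm, c)
        rows[c] = {"sensitivity": m["sensitivity"], "ppv": m["ppv"]}
    return pd.DataFrame.from_dict(rows, orient="index")


def total_error(cm: ConfusionMatrix) -> float:
    """Fraction of off-diagonal (misclassified) samples."""
    return 1.0 - np.trace(cm.counts) / cm.total


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores, labels, positive=1) -> tuple[float, float]:
    """AUC by the rank identity U/(n1*n2) with ties counted 1/2, plus the
    Hanley-McNeil standard error."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n1, n2 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)  # midranks
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    return float(auc), float(math.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for sample ``a``) and two-sided p-value.

    Exact by enumeration when n1+n2 <= 12 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= 12 and not has_ties:
        # exact null distribution of U by enumerating rank assignments
        all_ranks = range(1, n1 + n2 + 1)
        us = [
            sum(c) - n1 * (n1 + 1) / 2.0
            for c in itertools.combinations(all_ranks, n1)
        ]
        us = np.asarray(us)
        mid = n1 * n2 / 2.0
        # two-sided: symmetric tail around the null mean
        p = float(np.mean(np.abs(us - mid) >= abs(u1 - mid) - 1e-12))
        return float(u1), min(p, 1.0)

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u == 0:
        return float(u1), 1.0
    z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return float(u1), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# discordance between the molecular and histological calls

def discordance_report(molecular, histology) -> dict:
    """Disagreements on malignancy between molecular and histological labels.

    False positive: molecular malignant / histology benign.  False negative:
    molecular benign / histology malignant.  Percentages are of all samples,
    rounded half away from zero to 2 decimals.
    """
    m = np.asarray(molecular)
    h = np.asarray(histology)
    if len(m) != len(h):
        raise ValueError("label vectors differ in length")
    n = len(m)
    fp = int(((m == "malignant") & (h == "benign")).sum())
    fn = int(((m == "benign") & (h == "malignant")).sum())

    def pct(x):
        return round_half_away(100.0 * x / n, 2) if n else None

    return {
        "n": n,
        "n_discordant": fp + fn,
        "n_false_pos": fp,
        "n_false_neg": fn,
        "pct_discordant": pct(fp + fn),
        "pct_false_pos": pct(fp),
        "pct_false_neg": pct(fn),
    }


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention behind the published
    whole-number percentages)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    classes: tuple[str, ...]
    per_class: pd.DataFrame       # sensitivity/ppv, training and CV columns
    total_error: float
    cv_total_error: float
    folds: pd.Series              # sample_id -> fold index
    training_confusion: ConfusionMatrix
    cv_confusion: ConfusionMatrix


def assign_folds(sample_ids, labels, k: int, seed: int,
                 groups=None) -> pd.Series:
    """Deterministic stratified fold assignment.

    Depends only on (sample ids, k, seed): ids are sorted within each class
    before a seeded shuffle and round-robin assignment.  With ``groups``
    (e.g. patient ids) all samples of a group land in one fold.
    """
    ids = pd.Series(np.asarray(sample_ids))
    labels = pd.Series(np.asarray(labels), index=ids.index)
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=ids.values, dtype=int)
    if groups is not None:
        groups = pd.Series(np.asarray(groups), index=ids.index)
        gframe = pd.DataFrame({"g": groups.values, "y": labels.values},
                              index=ids.values)
        # stratify groups by their majority label
        glabel = gframe.groupby("g")["y"].agg(lambda s: s.value_counts().idxmax())
        for cls in sorted(glabel.unique()):
            members = sorted(glabel.index[glabel == cls])
            order = rng.permutation(len(members))
            for pos, gi in enumerate(order):
                fold[gframe.index[gframe["g"] == members[gi]]] = pos % k
        return fold
    for cls in sorted(pd.unique(labels)):
        members = sorted(ids[labels.values == cls])
        order = rng.permutation(len(members))
        for pos, mi in enumerate(order):
            fold[members[mi]] = pos % k
    return fold


def kfold_cv(table: pd.DataFrame, target: str, features, params=None,
             k: int = 5, seed: int = 0, group_by: str = "sample") -> CVResult:
    """Stratified k-fold cross-validation of the C4.5-style trainer.

    Training metrics come from a tree fitted on the full table; CV metrics
    pool the held-out predictions over all folds.  ``group_by="patient"``
    keeps all samples of a patient in one fold.
    """
    from .tree import C45Params, c45_train

    params = params or C45Params()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the number of samples ({len(table)})")
    counts = table[target].value_counts()
    if (counts < k).any():
        import warnings

        small = counts[counts < k]
        warnings.warn(
            f"classes with fewer than k={k} members degrade stratification: "
            f"{dict(small)}", stacklevel=2,
        )

    groups = table["patient_id"].values if group_by == "patient" else None
    folds = assign_folds(table["sample_id"].values, table[target].values, k,
                         seed, groups=groups)
    fold_of_row = table["sample_id"].map(folds).to_numpy()

    full_tree = c45_train(table, target, features, params)
    train_pred = full_tree.predict(table)
    classes = tuple(sorted(pd.unique(table[target])))
    cm_train = ConfusionMatrix.from_labels(table[target], train_pred, classes)

    cv_truth, cv_pred = [], []
    for f in range(k):
        test = table.loc[fold_of_row == f]
        train = table.loc[fold_of_row != f]
        if len(test) == 0:
            continue
        tree_f = c45_train(train, target, features, params)
        cv_pred.extend(tree_f.predict(test).tolist())
        cv_truth.extend(test[target].tolist())
    cm_cv = ConfusionMatrix.from_labels(cv_truth, cv_pred, classes)

    per_train = per_class_metrics(cm_train)
    per_cv = per_class_metrics(cm_cv)
    per = per_train.join(per_cv, lsuffix="_train", rsuffix="_cv")
    return CVResult(
        classes=classes,
        per_class=per,
        total_error=total_error(cm_train),
        cv_total_error=total_error(cm_cv),
        folds=folds,
        training_confusion=cm_train,
        cv_confusion=cm_cv,
    )
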