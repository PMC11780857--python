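"""Linear-SVM group classification and DeLong ROC comparisons.

Two feature sets are compared head to head: the eight task metrics plus
age, gender and education ("OMT"), against the ACE screening score plus the
same demographics ("ACE"). Classifiers are linear support vector machines
evaluated by stratified k-fold cross-validation; per-class ROC AUCs come
from one-vs-rest decision scores, and the two models are compared on the
same held-out cases with DeLong's test for paired ROC curves.

Features are standardized inside each training fold only, so no test-fold
statistics leak into scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import BASIC_METRICS
from .mixture import MIXTURE_METRICS

#: The eight task metrics entering the "OMT" feature set.
OMT_FEATURES = tuple(BASIC_METRICS) + tuple(MIXTURE_METRICS)
DEMOGRAPHICS = ("age", "gender", "education")


@dataclass(frozen=True)
class ClassifierResult:
    feature_set: str
    classes: tuple[str, ...]
    auc_per_class: dict[str, float]
    accuracy: float
    #: out-of-fold decision scores, one column per class (binary: one column)
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ROCComparison:
    auc_a: float
    auc_b: float
    Z: float
    p: float
    paired: bool


# ------------------------------------------------------------- DeLong

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mid-rank placement values V10 (per positive), V01 (per negative)."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_s)
    pos_ranks = ranks[:m]
    auc = (pos_ranks.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (pos_ranks - sps.rankdata(pos)) / n
    v01 = 1.0 - (ranks[m:] - sps.rankdata(neg)) / m
    return v10, v01, float(auc)


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, variance of AUC) by DeLong's placement-value method."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("labels must contain both classes")
    v10, v01, auc = _placements(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    return auc, float(var)


def delong_compare(
    scores_a,
    scores_b,
    labels,
    paired: bool = True,
) -> ROCComparison:
    """DeLong test for the difference between two ROC AUCs.

    With paired=True the two score vectors must be over the same cases in
    the same order; the placement-value covariance then enters the variance
    of the difference.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    if len(scores_a) != len(labels) or len(scores_b) != len(labels):
        raise ValueError("scores and labels must have equal length")

    pos_a, neg_a = scores_a[labels], scores_a[~labels]
    pos_b, neg_b = scores_b[labels], scores_b[~labels]
    v10_a, v01_a, auc_a = _placements(pos_a, neg_a)
    v10_b, v01_b, auc_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    var_a = v10_a.var(ddof=1) / m + v01_a.var(ddof=1) / n
    var_b = v10_b.var(ddof=1) / m + v01_b.var(ddof=1) / n
    if paired:
        cov = (
            np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
            + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
        )
    else:
        cov = 0.0
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0:
        z = 0.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return ROCComparison(float(auc_a), float(auc_b), float(z), float(p), paired)


# --------------------------------------------------------------- SVM

def _feature_matrix(table: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    if feature_set == "OMT":
        cols = list(OMT_FEATURES) + list(DEMOGRAPHICS)
    elif feature_set == "ACE":
        cols = ["ace"] + list(DEMOGRAPHICS)
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    X = table[cols].copy()
    if X["gender"].dtype.kind not in "ifb":
        X["gender"] = X["gender"].map({"M": 0.0, "F": 1.0})
    return X.astype(float)


def fit_eval_classifier(
    table: pd.DataFrame,
    feature_set: str = "OMT",
    classes: tuple[str, ...] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierResult:
    """Cross-validated linear SVM over the requested classes.

    `table` holds one row per participant with the metric columns, ACE and
    demographics, plus a `group` column. Returns out-of-fold one-vs-rest
    decision scores (the inputs to DeLong comparisons), per-class AUC and
    out-of-fold multiclass accuracy.
    """
    if classes is None:
        classes = tuple(sorted(table["group"].unique()))
    sub = table[table["group"].isin(classes)].dropna(
        subset=_feature_matrix(table.head(1), feature_set).columns.tolist()
    )
    y = sub["group"].to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes present")
    if counts.min() < cv_folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} members < {cv_folds} "
            "folds; use a smaller cv_folds"
        )
    X = _feature_matrix(sub, feature_set).to_numpy()

    class_order = list(classes)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    n_cols = 1 if len(class_order) == 2 else len(class_order)
    scores = np.zeros((len(y), n_cols))
    pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        clf = make_pipeline(
            StandardScaler(),
            SVC(
                kernel="linear", C=C, class_weight="balanced",
                decision_function_shape="ovr",
            ),
        )
        clf.fit(X[train], y[train])
        df_scores = clf.decision_function(X[test])
        if df_scores.ndim == 1:
            df_scores = df_scores[:, None]
            svc_classes = clf[-1].classes_
            pred[test] = np.where(
                df_scores[:, 0] > 0, svc_classes[1], svc_classes[0]
            )
            scores[test] = df_scores
        else:
            svc_classes = list(clf[-1].classes_)
            order = [svc_classes.index(c) for c in class_order]
            scores[test] = df_scores[:, order]
            pred[test] = np.asarray(class_order)[np.argmax(scores[test], axis=1)]

    auc = {}
    if n_cols == 1:
        pos_class = sorted(class_order)[1] if len(class_order) == 2 else None
        svc_pos = pos_class
        # decision_function is positive for classes_[1] (sorted order)
        svc_pos = sorted(class_order)[1]
        auc[svc_pos] = float(roc_auc_score((y == svc_pos).astype(int), scores[:, 0]))
        auc[sorted(class_order)[0]] = auc[svc_pos]  # symmetric in binary case
    else:
        for j, c in enumerate(class_order):
            auc[c] = float(roc_auc_score((y == c).astype(int), scores[:, j]))
    return ClassifierResult(
        feature_set=feature_set,
        classes=tuple(class_order),
        auc_per_class=auc,
        accuracy=float(np.mean(pred == y)),
        scores=scores,
        labels=y,
    )


def compare_feature_sets_per_class(
    res_a: ClassifierResult, res_b: ClassifierResult
) -> dict[str, ROCComparison]:
    """Paired DeLong comparison of two models' per-class out-of-fold scores."""
    if res_a.classes != res_b.classes or not np.array_equal(res_a.labels, res_b.labels):
        raise ValueError("paired comparison needs identical classes and cases")
    out = {}
    if res_a.scores.shape[1] == 1:
        pos = sorted(res_a.classes)[1]
        out[pos] = delong_compare(
            res_a.scores[:, 0], res_b.scores[:, 0], res_a.labels == pos
        )
        return out
    for j, c in enumerate(res_a.classes):
        out[c] = delong_compare(
            res_a.scores[:, j], res_b.scores[:, j], res_a.labels == c
        )
    return out


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    auc_omt: float
    auc_ace: float
    Z: float  # positive: ACE better
    p: float


def pairwise_suite(
    table: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = (("EHC", "SCD"), ("SCD", "MCI"), ("MCI", "AD")),
    cv_folds: int = 5,
    seed: int = 0,
) -> list[PairwiseComparison]:
    """Binary OMT-vs-ACE classifier comparisons for clinically adjacent pairs."""
    out = []
    for a, b in pairs:
        res_omt = fit_eval_classifier(
            table, "OMT", classes=(a, b), cv_folds=cv_folds, seed=seed
        )
        res_ace = fit_eval_classifier(
            table, "ACE", classes=(a, b), cv_folds=cv_folds, seed=seed
        )
        pos = sorted((a, b))[1]
        cmp = delong_compare(
            res_ace.scores[:, 0], res_omt.scores[:, 0], res_ace.labels == pos
        )
        out.append(
            PairwiseComparison(
                a, b,
                auc_omt=res_omt.auc_per_class[pos],
                auc_ace=res_ace.auc_per_class[pos],
                Z=cmp.Z, p=cmp.p,
            )
        )
    return out
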