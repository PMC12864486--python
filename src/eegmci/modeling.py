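"""Fold-internal feature selection, repeated cross-validated classification,
metrics, and per-feature group comparisons.

Every training phase standardizes on the training rows, ranks all candidate
features by the one-way ANOVA F-statistic computed on the training rows only,
keeps the top k (default 100), fits the classifier on those, and scores the
held-out fold — so no statistic ever sees test rows (leakage-safe).  The
scheme is stratified 5-fold CV repeated 10 times with per-repeat seeds, i.e.
50 evaluation folds; metrics are aggregated as mean ± SD over those folds.

The eight classifiers approximate common "default" configurations: linear SVM
(C = 1), CART decision tree (Gini, unlimited depth), Gaussian naive Bayes,
pooled-covariance LDA, AdaBoost with 100 depth-1 rounds, 1-nearest-neighbour
(Euclidean), random forest with 100 trees and √P features per split, and
unpenalized logistic regression.

The progressive group (PMCI) is the positive class throughout.  AUC uses the
rank-sum formula with average ranks for ties, which equals the fraction of
positive–negative score pairs correctly ordered (ties counting ½).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SEN", "SPE", "PPV", "F1", "AUC")

#: Classifiers whose decision boundary is nonlinear in the inputs (the linear
#: SVM earns its place through the margin on standardized selected features).
NONLINEAR_CLASSIFIERS = ("SVM", "DT", "NB", "ADA", "KNN", "RF")

CLASSIFIER_NAMES = ("SVM", "DT", "NB", "LDA", "ADA", "KNN", "RF", "LogReg")


def make_classifier(name: str, seed: int | None = None):
    """Instantiate one of the eight pinned classifier configurations."""
    rs = seed
    if name == "SVM":
        return SVC(kernel="linear", C=1.0, random_state=rs)
    if name == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=rs)
    if name == "NB":
        return GaussianNB()
    if name == "LDA":
        return LinearDiscriminantAnalysis(solver="svd")
    if name == "ADA":
        return AdaBoostClassifier(n_estimators=100, random_state=rs)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, max_features="sqrt",
                                      random_state=rs)
    if name == "LogReg":
        # C = inf realizes an unpenalized fit without the deprecated penalty kwarg
        return LogisticRegression(C=np.inf, max_iter=2000, random_state=rs)
    raise InvalidConfigError(f"unknown classifier {name!r}")


def _scores(model, x: np.ndarray) -> np.ndarray:
    """Continuous scores for AUC: probabilities where natural, otherwise the
    signed decision value."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


# ---------------------------------------------------------------------------
# F-statistic selection
# ---------------------------------------------------------------------------

def f_statistic(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way two-group ANOVA F per feature column.

    F = (between-group mean square) / (within-group mean square).  Features
    with zero within-group variance get F = 0 when the group means coincide
    and +inf otherwise (perfectly separating feature ranks first).
    """
    x = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if x.ndim == 2 and x.shape[0] == 1 and np.asarray(labels).size != 1:
        x = x.T
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidInputError("need exactly two classes")
    n = x.shape[0]
    masks = [y == c for c in classes]
    ns = np.array([m.sum() for m in masks])
    if np.any(ns < 2):
        raise InvalidInputError("need at least 2 samples per class")
    grand = x.mean(axis=0)
    means = np.vstack([x[m].mean(axis=0) for m in masks])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = np.vstack(
        [((x[m] - means[i]) ** 2).sum(axis=0) for i, m in enumerate(masks)]
    ).sum(axis=0)
    ms_between = ss_between / (classes.size - 1)
    ms_within = ss_within / (n - classes.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f = np.where(ms_within == 0, np.where(ms_between == 0, 0.0, np.inf), f)
    return f


@dataclass
class SelectionResult:
    f_values: np.ndarray
    ranking: np.ndarray   # feature indices, descending F (stable ties)
    retained: np.ndarray  # top-k indices in canonical column order


def select_top_k(values: np.ndarray, labels: np.ndarray, k: int = 100) -> SelectionResult:
    """Rank features by descending F on the given (training) rows, retain the
    top min(k, P); ties break by canonical column order."""
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    f = f_statistic(values, labels)
    order = np.argsort(-f, kind="stable")  # stable => ties keep column order
    retained = np.sort(order[: min(k, f.size)])
    return SelectionResult(f_values=f, ranking=order, retained=retained)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """ACC, SEN, SPE, PPV and F1 from confusion counts (PMCI positive).

    A metric whose denominator is empty is reported as NaN ("undefined") and
    later excluded from fold averaging.
    """
    if counts.total == 0:
        raise InvalidInputError("empty confusion table")
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "ACC": (tp + tn) / counts.total,
        "SEN": _ratio(tp, tp + fn),
        "SPE": _ratio(tn, fp + tn),
        "PPV": _ratio(tp, tp + fp),
        "F1": _ratio(2 * tp, 2 * tp + fp + fn),
    }


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-sum AUC: (Σ ranks of positives − M(M+1)/2) / (M·N), average ranks
    for tied scores."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if not np.all(np.isfinite(s)):
        raise InvalidInputError("scores must be finite")
    pos = y == 1
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise InvalidInputError("need both classes to compute AUC")
    ranks = rankdata(s)  # average ranks on ties
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    repeat: int
    fold: int
    counts: ConfusionCounts
    metrics: dict[str, float]
    retained: np.ndarray
    test_indices: np.ndarray


@dataclass
class CvReport:
    classifier: str
    folds: list[FoldResult]
    scheme: dict = field(default_factory=dict)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([f.metrics[name] for f in self.folds], dtype=np.float64)

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean ± SD per metric over all evaluation folds, NaN folds excluded
        (their count is reported)."""
        out = {}
        for name in METRIC_NAMES:
            vals = self.metric_values(name)
            defined = vals[~np.isnan(vals)]
            out[name] = {
                "mean": float(defined.mean()) if defined.size else float("nan"),
                "sd": float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
                "n_undefined": int(np.isnan(vals).sum()),
            }
        return out


def _fit_fold(x_train: np.ndarray, y_train: np.ndarray, estimator, k: int):
    """Training-rows-only pipeline: standardize → F-select top k → fit."""
    scaler = StandardScaler().fit(x_train)
    xs = scaler.transform(x_train)
    sel = select_top_k(xs, y_train, k=k)
    model = clone(estimator).fit(xs[:, sel.retained], y_train)
    return scaler, sel, model


def _eval_fold(scaler, sel, model, x_test: np.ndarray, y_test: np.ndarray):
    xs = scaler.transform(x_test)[:, sel.retained]
    pred = model.predict(xs)
    score = _scores(model, xs)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y_test == 1)).sum()),
        fn=int(((pred == 0) & (y_test == 1)).sum()),
        fp=int(((pred == 1) & (y_test == 0)).sum()),
        tn=int(((pred == 0) & (y_test == 0)).sum()),
    )
    metrics = compute_metrics(counts)
    try:
        metrics["AUC"] = auc_rank(score, y_test)
    except InvalidInputError:
        metrics["AUC"] = float("nan")  # single-class test fold
    return counts, metrics


def repeated_cv(
    table: pd.DataFrame,
    classifier: str = "SVM",
    folds: int = 5,
    repeats: int = 10,
    k: int = 100,
    seed: int = 0,
) -> CvReport:
    """Stratified ``repeats`` × ``folds`` cross-validation of one classifier
    on a longitudinal feature table (``label`` column + feature columns).

    Standardization and F-selection are refit inside every training phase.
    Fold partitions use per-repeat seeds ``seed + repeat``; the whole report
    is reproducible from ``seed``.
    """
    y = table["label"].to_numpy(dtype=int)
    x = table.drop(columns=["label"]).to_numpy(dtype=np.float64)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < folds:
        raise InvalidConfigError(
            f"smallest class has {class_counts.min()} subjects; cannot stratify "
            f"into {folds} folds"
        )
    estimator = make_classifier(classifier, seed=seed)
    results: list[FoldResult] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for fold_i, (tr, te) in enumerate(skf.split(x, y)):
            scaler, sel, model = _fit_fold(x[tr], y[tr], estimator, k)
            counts, metrics = _eval_fold(scaler, sel, model, x[te], y[te])
            results.append(FoldResult(repeat=rep, fold=fold_i, counts=counts,
                                      metrics=metrics, retained=sel.retained,
                                      test_indices=te))
    return CvReport(
        classifier=classifier,
        folds=results,
        scheme={"folds": folds, "repeats": repeats, "k": k, "seed": seed,
                "stratified": True, "aggregation": "over all evaluation folds"},
    )


def evaluate_classifiers(
    table: pd.DataFrame,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    folds: int = 5,
    repeats: int = 10,
    k: int = 100,
    seed: int = 0,
) -> dict[str, CvReport]:
    """Repeated CV for a set of classifiers on the same table."""
    return {
        name: repeated_cv(table, classifier=name, folds=folds, repeats=repeats,
                          k=k, seed=seed)
        for name in classifiers
    }


def summary_grid(reports: Mapping[str, CvReport]) -> pd.DataFrame:
    """Classifier × metric grid of fold means (and SDs) as a tidy frame."""
    rows = []
    for name, report in reports.items():
        summ = report.summary()
        row: dict[str, float | str] = {"classifier": name}
        for metric in METRIC_NAMES:
            row[f"{metric}_mean"] = summ[metric]["mean"]
            row[f"{metric}_sd"] = summ[metric]["sd"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("classifier")


# ---------------------------------------------------------------------------
# Per-feature group comparisons
# ---------------------------------------------------------------------------

def mann_whitney_map(
    features: pd.DataFrame,
    labels: np.ndarray,
    correction: str | None = None,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per feature column between the two groups.

    Returns a frame with U, p, and (when the name follows the canonical
    ``{kind}__{channel}`` convention) the feature kind and channel for
    topographic grouping.  ``correction="bh"`` adds Benjamini–Hochberg
    adjusted p-values; the primary analysis is uncorrected (α = 0.05).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise InvalidInputError("need both groups for comparisons")
    records = []
    for col in features.columns:
        a = features.loc[y == 1, col].to_numpy(dtype=np.float64)
        b = features.loc[y == 0, col].to_numpy(dtype=np.float64)
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            u, p = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        kind, _, channel = col.partition("__")
        records.append({"feature": col, "kind": kind, "channel": channel,
                        "U": float(u), "p": float(p)})
    out = pd.DataFrame.from_records(records).set_index("feature")
    if correction == "bh":
        from scipy.stats import false_discovery_control
        out["p_bh"] = false_discovery_control(out["p"].to_numpy())
    elif correction is not None:
        raise InvalidConfigError(f"unknown correction {correction!r}")
    return out
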