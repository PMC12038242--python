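"""Dual-rank feature selection and SVM classification with ROC/AUC.

Candidate features (differentially expressed circRNAs) are ranked in
parallel by a single-threshold information-gain filter and by random
forest mean-decrease-in-impurity importance; the two ranks are combined
by rank sum.  An SVM with grid-tuned hyperparameters (cost, gamma,
kernel, degree) is trained on z-scored expression and evaluated either on
an independent cohort or by stratified 10-fold cross-validation, pooling
out-of-fold prediction probabilities into a single ROC/AUC.

All scaling and selection statistics are computed on training data only;
``kfold_cv_classify`` takes a learner factory so the whole selection +
scaling + tuning stack refits inside every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

_C = [0.1, 1.0, 10.0, 100.0]
_GAMMA = [0.001, 0.01, 0.1, 1.0]
DEFAULT_GRID = [
    {"svm__estimator__kernel": ["linear"], "svm__estimator__C": _C},
    {
        "svm__estimator__kernel": ["rbf"],
        "svm__estimator__C": _C,
        "svm__estimator__gamma": _GAMMA,
    },
    {
        "svm__estimator__kernel": ["poly"],
        "svm__estimator__C": _C,
        "svm__estimator__gamma": _GAMMA,
        "svm__estimator__degree": [2, 3],
    },
]


@dataclass
class RocResult:
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def select_de_features(
    de_results: pd.DataFrame, lfc_cut: float = 1.0, padj_cut: float = 0.05
) -> list[str]:
    """Features passing both |log2FC| and adjusted-P cuts."""
    lfc = de_results["log2FoldChange"]
    padj = de_results["padj"]
    keep = (lfc.abs() > lfc_cut) & (padj < padj_cut)
    selected = list(de_results.index[keep.fillna(False)])
    if not selected:
        import warnings

        warnings.warn("no feature passes the DE cuts; classifier has nothing to train on",
                      stacklevel=2)
    return selected


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(values, labels) -> float:
    """Best single-threshold information gain of a continuous feature (bits).

    IG = H(labels) - min over thresholds of the weighted conditional
    entropy of the two sides of the split.  Constant features score 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.size != y.size or x.size == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    uniq = np.unique(x)
    if uniq.size < 2:
        return 0.0
    h = _entropy(y)
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    best = h
    n = x.size
    for t in thresholds:
        left = y[x <= t]
        right = y[x > t]
        cond = (left.size / n) * _entropy(left) + (right.size / n) * _entropy(right)
        best = min(best, cond)
    return h - best


def forest_importance(
    matrix: pd.DataFrame, labels, n_trees: int = 500, seed: int = 0
) -> pd.Series:
    """Mean-decrease-in-impurity importances from a seeded random forest.

    Samples are the matrix columns; ``matrix`` is features x samples as
    everywhere else in the package.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need two classes for forest importance")
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100 for stable importances")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True, random_state=seed
    )
    forest.fit(matrix.to_numpy().T, y)
    return pd.Series(forest.feature_importances_, index=matrix.index, name="imp_score")


def rank_features(
    matrix: pd.DataFrame, labels, n_trees: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Dual ranking: information gain and forest importance per feature.

    Returns ig_score/ig_rank, imp_score/imp_rank and the combined_rank
    (rank of the rank sum; ties broken by ig_rank, then feature id).
    """
    y = np.asarray(labels)
    ig = pd.Series(
        {f: information_gain(matrix.loc[f].to_numpy(), y) for f in matrix.index},
        name="ig_score",
    )
    imp = forest_importance(matrix, y, n_trees=n_trees, seed=seed)
    return combine_ranks(ig, imp)


def combine_ranks(ig_scores: pd.Series, imp_scores: pd.Series) -> pd.DataFrame:
    """Rank-sum combination of the two filters; total deterministic order."""
    if set(ig_scores.index) != set(imp_scores.index):
        raise ValueError("rankings must cover the same feature set")
    df = pd.DataFrame({"ig_score": ig_scores, "imp_score": imp_scores.reindex(ig_scores.index)})
    df = df.sort_index()
    # higher score = better = rank 1; ties by feature id for determinism
    order_ig = df.sort_values(["ig_score"], ascending=False, kind="stable")
    df["ig_rank"] = pd.Series(range(1, len(df) + 1), index=order_ig.index)
    order_imp = df.sort_values(["imp_score"], ascending=False, kind="stable")
    df["imp_rank"] = pd.Series(range(1, len(df) + 1), index=order_imp.index)
    df["rank_sum"] = df["ig_rank"] + df["imp_rank"]
    order = df.sort_values(["rank_sum", "ig_rank"], kind="stable")
    df["combined_rank"] = pd.Series(range(1, len(df) + 1), index=order.index)
    return df.sort_values("combined_rank")


def tune_and_train_svm(
    train_matrix: pd.DataFrame,
    labels,
    grid: list[dict] | None = None,
    inner_cv_folds: int = 3,
    seed: int = 0,
) -> GridSearchCV:
    """Grid-tuned SVM with z-scoring and Platt-calibrated probabilities.

    The scaler is part of the pipeline so training statistics never see
    evaluation data.  Model selection maximizes inner-CV AUC.
    """
    y = np.asarray(labels)
    X = train_matrix.to_numpy().T
    n_min = np.unique(y, return_counts=True)[1].min()
    folds = min(inner_cv_folds, int(n_min))
    if folds < inner_cv_folds:
        import warnings

        warnings.warn(f"reducing inner CV folds to {folds} (smallest class)", stacklevel=2)
    # sigmoid (Platt) calibration on inner-CV decision values; calibration
    # folds sized so each grid-search training fold still has both classes
    cal_cv = int(max(2, min(3, n_min * (folds - 1) // folds)))
    calibrated = CalibratedClassifierCV(
        SVC(random_state=seed), method="sigmoid", cv=cal_cv, ensemble=False
    )
    pipe = Pipeline([("scale", StandardScaler()), ("svm", calibrated)])
    search = GridSearchCV(
        pipe,
        grid if grid is not None else DEFAULT_GRID,
        scoring="roc_auc",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        refit=True,
    )
    search.fit(X, y)
    search.feature_ids_ = list(train_matrix.index)
    return search


def auc(scores, labels) -> float:
    """AUC as the pairwise concordance probability.

    Mean over all (positive, negative) pairs of 1[score_pos > score_neg]
    with ties counted 1/2; identical to the Mann-Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute an AUC")
    # rank-based form of the pairwise count
    from scipy.stats import rankdata

    ranks = rankdata(s)
    u = ranks[y].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_result(scores, labels) -> RocResult:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(scores=s, labels=y, fpr=fpr, tpr=tpr, auc=auc(s, y))


def evaluate_on_cohort(model, test_matrix: pd.DataFrame, test_labels) -> RocResult:
    """Score an independent cohort with a trained model.

    The matrix must contain every training feature; scaling uses the
    training statistics stored in the fitted pipeline.
    """
    feats = getattr(model, "feature_ids_", None)
    if feats is not None:
        missing = [f for f in feats if f not in test_matrix.index]
        if missing:
            raise KeyError(f"test matrix lacks trained features: {missing}")
        test_matrix = test_matrix.loc[feats]
    proba = model.predict_proba(test_matrix.to_numpy().T)
    classes = model.classes_ if hasattr(model, "classes_") else model.best_estimator_.classes_
    scores = proba[:, list(classes).index(classes.max())]
    y = (np.asarray(test_labels) == classes.max()).astype(int)
    return roc_result(scores, y)


def kfold_cv_classify(
    matrix: pd.DataFrame,
    labels,
    k: int = 10,
    learner=None,
    seed: int = 0,
) -> RocResult:
    """Stratified k-fold CV pooling out-of-fold probabilities.

    ``learner(train_matrix, train_labels, seed)`` must return a fitted
    object with ``predict_proba``; it is called fresh inside every fold,
    so any feature selection or scaling it performs sees training folds
    only.  Defaults to the tuned SVM.
    """
    y = np.asarray(labels)
    if k > y.size:
        raise ValueError(f"k={k} exceeds the number of samples {y.size}")
    if learner is None:
        learner = lambda m, yy, s: tune_and_train_svm(m, yy, seed=s)  # noqa: E731
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pos_label = np.unique(y).max()
    scores = np.empty(y.size, dtype=float)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        model = learner(matrix.iloc[:, tr], y[tr], seed + fold)
        feats = getattr(model, "feature_ids_", None)
        test = matrix.iloc[:, te]
        if feats is not None:
            test = test.loc[feats]
        proba = model.predict_proba(test.to_numpy().T)
        classes = model.classes_ if hasattr(model, "classes_") else model.best_estimator_.classes_
        scores[te] = proba[:, list(classes).index(pos_label)]
    return roc_result(scores, (y == pos_label).astype(int))


@dataclass
class DualRankSvmLearner:
    """Feature selection (top-n combined rank) + tuned SVM, as one learner.

    Suitable for ``kfold_cv_classify``: everything refits per fold.
    """

    n_features: int = 10
    n_trees: int = 200
    grid: list[dict] | None = None
    selected_: list[str] = field(default_factory=list, repr=False)

    def __call__(self, train_matrix: pd.DataFrame, labels, seed: int):
        ranks = rank_features(train_matrix, labels, n_trees=self.n_trees, seed=seed)
        top = list(ranks.index[: self.n_features])
        self.selected_ = top
        return tune_and_train_svm(train_matrix.loc[top], labels, grid=self.grid, seed=seed)
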