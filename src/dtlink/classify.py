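"""Link classification and evaluation.

The link classifier is a gradient-boosted tree ensemble (XGBoost) over the
2n-dimensional concatenated embedding features.  The evaluation protocol:
hold out an external test fraction once, then run repeated stratified
k-fold CV on the remaining internal pool; within each repeat a grid search
scores every candidate hyperparameter setting by mean internal-test
f-beta, the winner is refit on the whole internal pool and applied once to
the external test.  The final model is refit on all labelled pairs.

With validated negatives precision is trustworthy and f1 is the selection
metric; with negatives sampled from unknown pairs false positives are
unreliable, so f2 (recall-weighted) is used instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from xgboost import XGBClassifier

from .config import child_seed
from .dataset import CVSplit, LinkFeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "TrainedLinkModel",
    "CVReport",
    "train_classifier",
    "grid_search",
    "precision_recall",
    "f_beta",
    "ranking_metrics",
    "run_cv",
]


@dataclass
class ClassifierSpec:
    """Boosted-tree hyperparameters.

    The fixed defaults (depth 4, subsample 1, min_child_weight 2, gamma 0.8)
    are the method's stated winning values; the number of boosting rounds is
    capped at ``n_estimators`` with early stopping (patience
    ``early_stopping_rounds``) whenever a validation set is available.
    ``grid`` maps hyperparameter names to candidate values for grid search.
    """

    max_depth: int = 4
    subsample: float = 1.0
    min_child_weight: float = 2.0
    gamma: float = 0.8
    n_estimators: int = 200
    learning_rate: float = 0.1
    early_stopping_rounds: int = 20
    seed: int = 0
    grid: dict[str, list[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def candidates(self) -> list["ClassifierSpec"]:
        """Expand the grid into concrete specs (base spec when grid empty).

        Candidates are generated in a canonical order — parameter names
        sorted, then value order as given — so the selected spec does not
        depend on grid dict ordering.
        """
        if not self.grid:
            return [replace(self, grid={})]
        names = sorted(self.grid)
        out = []
        for combo in itertools.product(*(self.grid[k] for k in names)):
            out.append(replace(self, grid={}, **dict(zip(names, combo))))
        return out

    def sort_key(self) -> tuple:
        return (
            self.max_depth, self.learning_rate, self.n_estimators,
            self.min_child_weight, self.gamma, self.subsample,
        )


@dataclass
class TrainedLinkModel:
    """A fitted boosted-tree link classifier plus its training metadata."""

    booster: XGBClassifier
    n_features: int
    spec: ClassifierSpec
    data_hash: str

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features}-column features, got {features.shape}"
            )
        return self.booster.predict_proba(features)[:, 1]


@dataclass
class CVReport:
    """Per-fold internal and per-repeat external metrics plus summaries."""

    internal: pd.DataFrame  # repeat, fold, precision, recall, fbeta, aupr, auc
    external: pd.DataFrame  # repeat, precision, recall, fbeta, aupr, auc
    beta: float
    selected_specs: list[ClassifierSpec]

    def summary(self) -> pd.DataFrame:
        metrics = ["precision", "recall", "fbeta", "aupr", "auc"]
        rows = []
        for name, df in (("internal", self.internal), ("external", self.external)):
            for m in metrics:
                rows.append(
                    {"split": name, "metric": m,
                     "mean": df[m].mean(), "std": df[m].std(ddof=0)}
                )
        return pd.DataFrame(rows)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedLinkModel:
    """Fit the boosted-tree classifier.

    ``eval_set`` (features, labels) enables early stopping on validation
    log-loss; without it the full ``n_estimators`` rounds are used.
    Deterministic under ``spec.seed`` (single-threaded histogram trees).
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    kwargs: dict[str, Any] = dict(
        max_depth=spec.max_depth,
        subsample=spec.subsample,
        min_child_weight=spec.min_child_weight,
        gamma=spec.gamma,
        n_estimators=spec.n_estimators,
        learning_rate=spec.learning_rate,
        random_state=spec.seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    if eval_set is not None:
        kwargs["early_stopping_rounds"] = spec.early_stopping_rounds
    clf = XGBClassifier(**kwargs)
    if eval_set is not None:
        clf.fit(X, y, eval_set=[(np.asarray(eval_set[0], float), np.asarray(eval_set[1], int))],
                verbose=False)
    else:
        clf.fit(X, y, verbose=False)
    return TrainedLinkModel(
        booster=clf, n_features=X.shape[1], spec=spec, data_hash=_data_hash(X, y)
    )


def precision_recall(y_true, y_score, threshold: float = 0.5) -> tuple[float, float]:
    """Confusion-matrix precision and recall at a score threshold.

    Precision is 0 by convention (logged) when nothing is predicted
    positive; recall is 0 when there are no true positives.
    """
    y_true = np.asarray(y_true, int)
    y_score = np.asarray(y_score, float)
    if y_true.shape != y_score.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_score.shape}")
    pred = y_score >= threshold
    tp = int(np.sum(pred & (y_true == 1)))
    fp = int(np.sum(pred & (y_true == 0)))
    fn = int(np.sum(~pred & (y_true == 1)))
    if tp + fp == 0:
        logger.info("no positive predictions at threshold %.3f; precision set to 0", threshold)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall


def f_beta(precision: float, recall: float, beta: float) -> float:
    """(1 + b^2) P R / (b^2 P + R); 0 when both P and R are 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def ranking_metrics(y_true, y_score) -> tuple[float, float]:
    """Threshold-free metrics: (AUC, AUPR).

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative (ties count half); AUPR is the step-wise
    average-precision construction of the area under the precision-recall
    curve.
    """
    y_true = np.asarray(y_true, int)
    y_score = np.asarray(y_score, float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present for ranking metrics")
    return float(roc_auc_score(y_true, y_score)), float(average_precision_score(y_true, y_score))


def _fold_metrics(y_true, y_score, beta: float) -> dict[str, float]:
    p, r = precision_recall(y_true, y_score)
    auc, aupr = ranking_metrics(y_true, y_score)
    return {"precision": p, "recall": r, "fbeta": f_beta(p, r, beta), "aupr": aupr, "auc": auc}


def grid_search(
    feature_set: LinkFeatureSet,
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
    beta: float,
    seed: int,
) -> tuple[ClassifierSpec, pd.DataFrame, list[list[dict[str, float]]]]:
    """Score every grid candidate by mean internal-test f-beta over folds.

    Returns the winning spec, a per-candidate score table, and the winning
    candidate's per-fold metric dicts.  Ties break toward smaller max_depth,
    then lexicographic parameter order.
    """
    candidates = spec.candidates()
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    X, y = feature_set.features, feature_set.labels
    rows = []
    fold_metrics: list[list[list[dict[str, float]]]] = []
    for cand in candidates:
        cand = replace(cand, seed=seed)
        per_fold = []
        for train_idx, test_idx in folds:
            model = train_classifier(
                X[train_idx], y[train_idx], cand,
                eval_set=(X[test_idx], y[test_idx]),
            )
            scores = model.predict_proba(X[test_idx])
            per_fold.append(_fold_metrics(y[test_idx], scores, beta))
        fold_metrics.append(per_fold)
        rows.append({**{k: getattr(cand, k) for k in
                        ("max_depth", "learning_rate", "n_estimators",
                         "min_child_weight", "gamma", "subsample")},
                     "mean_fbeta": float(np.mean([m["fbeta"] for m in per_fold]))})
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-table["mean_fbeta"][i], candidates[i].sort_key()),
    )
    best = order[0]
    return replace(candidates[best], seed=seed), table, fold_metrics[best]


def run_cv(
    feature_set: LinkFeatureSet,
    split: CVSplit,
    spec: ClassifierSpec,
    beta: float | None = None,
    seed: int = 0,
) -> tuple[CVReport, TrainedLinkModel]:
    """The full evaluation protocol; returns the report and the final model.

    Per repeat: grid search over the repeat's folds, refit of the winner on
    the internal pool, one application to the external test.  External pairs
    never enter grid search or model selection.  The final model is refit on
    every labelled pair with the most-often-selected spec.
    """
    if beta is None:
        beta = 2.0 if feature_set.provenance == "sampled-unknown-negative" else 1.0
    X, y = feature_set.features, feature_set.labels
    split.validate(len(y))
    ext = split.external
    internal_pool = np.sort(
        np.array(sorted(set(range(len(y))) - set(ext.tolist())), dtype=int)
    )

    internal_rows, external_rows, selected = [], [], []
    for r, folds in enumerate(split.internal):
        rep_seed = child_seed(seed, f"cv-repeat-{r}")
        best_spec, _, best_fold_metrics = grid_search(
            feature_set, spec, folds, beta, rep_seed
        )
        selected.append(best_spec)
        for f, metrics in enumerate(best_fold_metrics):
            internal_rows.append({"repeat": r, "fold": f, **metrics})
        # refit the repeat's winner on the whole internal pool, score external once
        model = train_classifier(X[internal_pool], y[internal_pool], best_spec)
        ext_scores = model.predict_proba(X[ext])
        external_rows.append({"repeat": r, **_fold_metrics(y[ext], ext_scores, beta)})

    report = CVReport(
        internal=pd.DataFrame(internal_rows),
        external=pd.DataFrame(external_rows),
        beta=beta,
        selected_specs=selected,
    )
    # most frequently selected spec wins the final refit; ties -> sort_key
    keys = [s.sort_key() for s in selected]
    winner = selected[
        min(range(len(selected)), key=lambda i: (-keys.count(keys[i]), keys[i]))
    ]
    final = train_classifier(X, y, replace(winner, seed=child_seed(seed, "final-model")))
    return report, final
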