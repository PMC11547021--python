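"""Classifier benchmarking: split, train, confusion metrics, ROC, importance.

Three classifier families predict the secondary-decline label from the
feature table: an L2-regularized logistic regression (with standardized
inputs), a random forest, and gradient-boosted trees.  Evaluation follows a
single stratified 4:1 train/validation split, a fixed 0.5 posterior decision
threshold for the confusion matrix, and threshold-free ranking quality via
the area under the ROC curve, which equals the probability that a random
positive outscores a random negative with ties half-credited.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

MODEL_KINDS = ("logistic_regression", "random_forest", "gradient_boosted_trees")
TREE_KINDS = ("random_forest", "gradient_boosted_trees")

#: unstated-by-convention defaults; override per call via ``hyperparams``
DEFAULT_HYPERPARAMS: Dict[str, Dict] = {
    "logistic_regression": {"C": 1.0, "max_iter": 5000},
    "random_forest": {"n_estimators": 500},
    "gradient_boosted_trees": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
}


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """A single train/validation split (default 4:1, stratified)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_cohort(
    X: pd.DataFrame, y: pd.Series, spec: Optional[SplitSpec] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Deterministic exact partition into train and validation folds."""
    spec = spec or SplitSpec()
    if pd.Series(y).nunique() < 2:
        raise ValueError("both outcome classes must be present before splitting")
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=spec.train_fraction,
            random_state=spec.seed,
            stratify=y if spec.stratified else None,
            shuffle=True,
        )
    except ValueError as err:
        raise ValueError(f"stratified split impossible: {err}") from err
    return X_tr, X_te, y_tr, y_te


@dataclasses.dataclass
class FittedModel:
    """A trained classifier with its feature bookkeeping."""

    kind: str
    estimator: object
    feature_names: List[str]
    dropped_features: List[str]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior probability of the positive (decline) class."""
        Xk = X[self.feature_names]
        return self.estimator.predict_proba(Xk)[:, 1]


def train_classifier(
    X: pd.DataFrame,
    y: pd.Series,
    kind: str,
    hyperparams: Optional[Dict] = None,
    seed: int = 0,
) -> FittedModel:
    """Fit one of the three classifier kinds; reproducible under ``seed``.

    Zero-variance features carry no information and destabilize the scaled
    logistic fit, so they are dropped with a warning rather than failing.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    if pd.Series(y).nunique() < 2:
        raise ValueError("training requires both outcome classes")
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    hp.update(hyperparams or {})

    variances = X.var(axis=0, ddof=0)
    dropped = list(variances.index[variances == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    kept = [c for c in X.columns if c not in dropped]
    Xk = X[kept]
    y_arr = np.asarray(y, dtype=int)

    if kind == "logistic_regression":
        est = make_pipeline(
            StandardScaler(), LogisticRegression(random_state=seed, **hp)
        )
    elif kind == "random_forest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    else:
        from xgboost import XGBClassifier

        est = XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **hp
        )
    est.fit(Xk, y_arr)
    return FittedModel(kind=kind, estimator=est, feature_names=kept, dropped_features=dropped)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> Dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, PPV and NPV from a confusion matrix.

    Metrics whose denominator is empty are reported as ``None`` (absent),
    never coerced to 0.
    """
    for name, val in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[float, List[Tuple[float, float]]]:
    """AUROC (Mann-Whitney probability, ties half-credited) and ROC points.

    The trapezoidal area under the empirical ROC curve equals the rank
    statistic ``P(score+ > score-) + 0.5 * P(tie)`` exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes are required to compute an ROC curve")
    auroc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return auroc, list(zip(fpr.tolist(), tpr.tolist()))


def feature_importance(model: FittedModel) -> pd.Series:
    """Normalized, descending feature importances of a tree-based model."""
    if model.kind not in TREE_KINDS:
        raise ValueError(
            "feature importances are defined for tree models only; for "
            "logistic regression inspect the standardized coefficient "
            "magnitudes instead"
        )
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = raw.sum()
    weights = raw / total if total > 0 else raw
    imp = pd.Series(weights, index=model.feature_names)
    full = imp.reindex(model.feature_names + model.dropped_features, fill_value=0.0)
    return full.sort_values(ascending=False)


@dataclasses.dataclass
class ModelEvaluation:
    """Held-out evaluation: confusion matrix, metric panel, ROC, importances."""

    kind: str
    tp: int
    fn: int
    tn: int
    fp: int
    metrics: Dict[str, Optional[float]]
    auroc: float
    roc_points: List[Tuple[float, float]]
    importances: Optional[pd.Series]

    def to_dict(self) -> Dict:
        return {
            "model": self.kind,
            "confusion": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "metrics": self.metrics,
            "auroc": self.auroc,
            "roc_points": self.roc_points,
            "importances": None
            if self.importances is None
            else self.importances.to_dict(),
        }


def evaluate_model(
    model: FittedModel,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    threshold: float = 0.5,
) -> ModelEvaluation:
    """Score a fitted model on held-out data at a posterior threshold."""
    scores = model.predict_proba(X_test)
    y = np.asarray(y_test, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    auroc, points = roc_auc(scores, y)
    importances = feature_importance(model) if model.kind in TREE_KINDS else None
    return ModelEvaluation(
        kind=model.kind,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        metrics=confusion_metrics(tp, fn, tn, fp),
        auroc=auroc,
        roc_points=points,
        importances=importances,
    )


def plot_roc(evaluation: ModelEvaluation, path) -> None:
    """Save the ROC curve of an evaluation as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in evaluation.roc_points]
    tpr = [p[1] for p in evaluation.roc_points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"{evaluation.kind} (AUC={evaluation.auroc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cohort-description utilities
# ---------------------------------------------------------------------------


def compare_groups(
    groups: Dict[str, Sequence[float]], test: str = "anova", paired: bool = False
) -> Tuple[float, float]:
    """One-way ANOVA across groups, or a t-test between two of them.

    Used descriptively (e.g. epoch durations by surgery type), not for
    inference claims.  Returns ``(statistic, p_value)``.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    if test == "anova":
        if len(arrays) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        res = stats.f_oneway(*arrays)
    elif test == "t_test":
        if len(arrays) != 2:
            raise ValueError("t-test compares exactly 2 groups")
        if paired:
            res = stats.ttest_rel(arrays[0], arrays[1])
        else:
            res = stats.ttest_ind(arrays[0], arrays[1])
    else:
        raise ValueError("test must be 'anova' or 't_test'")
    return float(res.statistic), float(res.pvalue)
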