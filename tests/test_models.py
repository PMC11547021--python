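"""Splitting, training, confusion metrics, ROC/AUC and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perimob.models import (
    MODEL_KINDS,
    SplitSpec,
    compare_groups,
    confusion_metrics,
    evaluate_model,
    feature_importance,
    roc_auc,
    split_cohort,
    train_classifier,
)


def toy_table(n=75, n_pos=26, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)],
                  index=[f"P{i:03d}" for i in range(n)])
    X = pd.DataFrame(
        {
            "signal": rng.normal(0, 1, n) + (2.5 * y.to_numpy() if informative else 0),
            "noise_a": rng.normal(0, 1, n),
            "noise_b": rng.normal(0, 1, n),
        },
        index=y.index,
    )
    return X, y


# ------------------------------------------------------------------- split


def test_four_to_one_split_sizes():
    X, y = toy_table(75)
    X_tr, X_te, y_tr, y_te = split_cohort(X, y, SplitSpec(seed=1))
    assert len(X_tr) == 60 and len(X_te) == 15
    assert set(X_tr.index).isdisjoint(X_te.index)
    assert set(X_tr.index) | set(X_te.index) == set(X.index)


def test_stratified_split_preserves_class_counts():
    X, y = toy_table(10, n_pos=5)
    _, X_te, _, y_te = split_cohort(X, y, SplitSpec(seed=3))
    assert len(X_te) == 2 and y_te.sum() == 1


def test_split_is_deterministic_under_seed():
    X, y = toy_table(50, n_pos=20)
    a = split_cohort(X, y, SplitSpec(seed=9))
    b = split_cohort(X, y, SplitSpec(seed=9))
    assert list(a[0].index) == list(b[0].index)
    assert list(a[1].index) == list(b[1].index)


# ---------------------------------------------------------------- training


@pytest.mark.parametrize("kind", ["random_forest", "gradient_boosted_trees"])
def test_tree_models_fit_separable_data_perfectly(kind):
    X, y = toy_table(60, n_pos=25, seed=2)
    X["signal"] = y * 10.0  # linearly separable
    model = train_classifier(X, y, kind, seed=0)
    pred = (model.predict_proba(X) >= 0.5).astype(int)
    assert (pred == y.to_numpy()).all()


def test_zero_variance_features_dropped_with_warning():
    X, y = toy_table(40, n_pos=15)
    X["flat"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        model = train_classifier(X, y, "logistic_regression")
    assert "flat" in model.dropped_features
    assert "flat" not in model.feature_names


def test_training_requires_both_classes():
    X, y = toy_table(20, n_pos=0)
    y[:] = 0
    with pytest.raises(ValueError, match="both outcome classes"):
        train_classifier(X, y, "random_forest")


# -------------------------------------------------------- confusion metrics


@pytest.mark.parametrize(
    "matrix, acc, sens, spec",
    [
        ((4, 1, 9, 1), 86.7, 80.0, 90.0),
        ((3, 2, 9, 1), 80.0, 60.0, 90.0),
        ((3, 3, 8, 1), 73.3, 50.0, 88.9),
    ],
)
def test_confusion_metric_worked_examples(matrix, acc, sens, spec):
    tp, fn, tn, fp = matrix
    m = confusion_metrics(tp, fn, tn, fp)
    assert round(100 * m["accuracy"], 1) == acc
    assert round(100 * m["sensitivity"], 1) == sens
    assert round(100 * m["specificity"], 1) == spec


def test_undefined_denominators_reported_absent():
    m = confusion_metrics(0, 0, 5, 0)
    assert m["sensitivity"] is None
    assert m["specificity"] == 1.0
    assert m["ppv"] is None


def test_empty_confusion_matrix_raises():
    with pytest.raises(ValueError, match="empty"):
        confusion_metrics(0, 0, 0, 0)


@given(
    tp=st.integers(0, 50), fn=st.integers(0, 50),
    tn=st.integers(0, 50), fp=st.integers(0, 50),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_accuracy_identity_holds_for_every_matrix(tp, fn, tn, fp):
    """accuracy == (sens * P + spec * N) / (P + N) whenever defined."""
    if tp + fn + tn + fp == 0:
        return
    m = confusion_metrics(tp, fn, tn, fp)
    P, N = tp + fn, tn + fp
    if m["sensitivity"] is None or m["specificity"] is None:
        return
    assert m["accuracy"] == pytest.approx(
        (m["sensitivity"] * P + m["specificity"] * N) / (P + N)
    )


# ----------------------------------------------------------------- ROC/AUC


def brute_force_auc(scores, labels):
    """Exhaustive positive-negative pair comparison with half tie credit."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_perfectly_separated_scores_have_auc_one():
    auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)


def test_ties_get_half_credit_exactly():
    scores = [0.5, 0.5, 0.2, 0.8]
    labels = [1, 0, 0, 1]
    auc, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=80)
    labels = (rng.random(80) < 0.4).astype(int)
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(np.exp(3 * scores), labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_roc_points_are_monotone():
    rng = np.random.default_rng(12)
    scores = rng.random(60).round(1)  # force ties
    labels = (rng.random(60) < 0.5).astype(int)
    _, points = roc_auc(scores, labels)
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    assert fpr == sorted(fpr) and tpr == sorted(tpr)


def test_single_class_labels_raise():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.2], [1, 1])


# ------------------------------------------------------- feature importance


def test_planted_signal_ranks_first_and_weights_sum_to_one():
    X, y = toy_table(200, n_pos=70, seed=3)
    for kind in ("random_forest", "gradient_boosted_trees"):
        model = train_classifier(X, y, kind, seed=0)
        imp = feature_importance(model)
        assert imp.index[0] == "signal"
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)


def test_importance_refused_for_logistic_regression():
    X, y = toy_table(40, n_pos=15)
    model = train_classifier(X, y, "logistic_regression")
    with pytest.raises(ValueError, match="coefficient"):
        feature_importance(model)


def test_evaluation_confusion_sums_to_test_n():
    X, y = toy_table(100, n_pos=40, seed=5)
    X_tr, X_te, y_tr, y_te = split_cohort(X, y, SplitSpec(seed=2))
    model = train_classifier(X_tr, y_tr, "random_forest", seed=2)
    ev = evaluate_model(model, X_te, y_te)
    assert ev.tp + ev.fn + ev.tn + ev.fp == len(X_te)
    assert 0.0 <= ev.auroc <= 1.0


# --------------------------------------------------------- group comparison


def test_identical_groups_give_f_zero_p_one():
    g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
    f, p = compare_groups(g, test="anova")
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_two_sample_t_matches_closed_form():
    rng = np.random.default_rng(7)
    a = rng.normal(10.0, 2.0, 30)
    b = rng.normal(11.0, 2.0, 30)
    t, p = compare_groups({"a": a, "b": b}, test="t_test")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    assert t == pytest.approx(t_hand, abs=1e-9)


def test_anova_type_one_error_is_calibrated():
    """Equal-mean groups reject at about the nominal 5% rate."""
    rng = np.random.default_rng(15)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        groups = {k: rng.normal(0, 1, 30) for k in "abc"}
        _, p = compare_groups(groups, test="anova")
        rejections += p < 0.05
    rate = rejections / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


def test_tiny_group_raises():
    with pytest.raises(ValueError, match="at least 2"):
        compare_groups({"a": [1.0], "b": [1.0, 2.0]})
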