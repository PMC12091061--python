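"""Splitting, rebalancing, training, scoring and evaluation of the risk model."""

import math

import numpy as np
import pandas as pd
import pytest

from iit_triage.model import (
    ModelConfig,
    bootstrap_stability,
    evaluate,
    feature_importance,
    metrics_from_scores,
    rebalance,
    score_visits,
    select_top_k,
    split_train_test,
    train_classifier,
)


def synthetic_feature_table(n=2000, signal="current_age", strength=2.0, seed=0):
    """A feature table where only one column carries outcome signal."""
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.3
    df = pd.DataFrame({
        "client_id": [f"C{i}" for i in range(n)],
        "scheduled_date": pd.Timestamp("2020-01-01") + pd.to_timedelta(rng.integers(0, 300, n), "D"),
        "current_age": rng.normal(35, 8, n),
        "time_on_art": rng.normal(6, 2, n),
        "travel_time_min": rng.normal(25, 10, n),
        "n_times_gt28d_late": rng.integers(0, 3, n).astype(float),
        "sex": rng.choice(["F", "M"], n),
        "iit_next_visit": y,
    })
    df[signal] = df[signal] + strength * df[signal].std() * y
    return df


@pytest.fixture(scope="module")
def toy_features():
    return synthetic_feature_table()


def test_visit_split_sizes(toy_features):
    cfg = ModelConfig(test_fraction=0.2, seed=1)
    train, test = split_train_test(toy_features.head(100), cfg)
    assert len(train) == 80 and len(test) == 20


def test_client_split_keeps_clients_apart(toy_features):
    df = toy_features.copy()
    df["client_id"] = [f"C{i % 50}" for i in range(len(df))]
    cfg = ModelConfig(split_unit="client", seed=1)
    train, test = split_train_test(df, cfg)
    assert not set(train["client_id"]) & set(test["client_id"])


def test_split_deterministic(toy_features):
    cfg = ModelConfig(seed=7)
    t1, _ = split_train_test(toy_features, cfg)
    t2, _ = split_train_test(toy_features, cfg)
    assert list(t1.index) == list(t2.index)


@pytest.mark.parametrize(
    "mode, expected",
    [("downsample", (100, 100)), ("upsample", (900, 900)), ("none", (900, 100))],
)
def test_rebalance_class_counts(mode, expected):
    df = synthetic_feature_table(1000, seed=3)
    df["iit_next_visit"] = np.arange(1000) < 100  # 100 positives, 900 negatives
    out = rebalance(df, mode, seed=0)
    counts = out["iit_next_visit"].value_counts()
    assert (counts[False], counts[True]) == expected


def test_rebalance_single_class_error():
    df = synthetic_feature_table(50, seed=3)
    df["iit_next_visit"] = False
    with pytest.raises(ValueError, match="both outcome classes"):
        rebalance(df, "downsample")


def test_separable_data_scores_perfectly():
    df = synthetic_feature_table(400, strength=50.0, seed=5)
    cfg = ModelConfig(n_estimators=50, seed=2)
    train, test = split_train_test(df, cfg)
    scorer = train_classifier(rebalance(train, "downsample", 0), cfg)
    m = evaluate(scorer, test)
    assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.auc == 1.0


def test_shuffled_labels_give_null_auc():
    """With randomly permuted labels the AUC sits in the permutation-null band."""
    df = synthetic_feature_table(2000, strength=1.5, seed=8)
    rng = np.random.default_rng(0)
    df["iit_next_visit"] = rng.permutation(df["iit_next_visit"].to_numpy())
    cfg = ModelConfig(n_estimators=50, seed=3)
    train, test = split_train_test(df, cfg)
    scorer = train_classifier(rebalance(train, "downsample", 0), cfg)
    m = evaluate(scorer, test)
    n1 = int(test["iit_next_visit"].sum())
    n0 = len(test) - n1
    null_sd = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # Mann-Whitney null
    assert abs(m.auc - 0.5) < 4 * null_sd


def test_hand_computed_confusion_metrics():
    """TP=3, FP=1, FN=2, TN=4 worked through the confusion arithmetic."""
    y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
    scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.3, 0.2, 0.1])
    m = metrics_from_scores(y, scores, threshold=0.5)
    assert m.sensitivity == pytest.approx(0.6)
    assert m.specificity == pytest.approx(0.8)
    assert m.ppv == pytest.approx(0.75)
    assert m.npv == pytest.approx(2 / 3)
    assert m.accuracy == pytest.approx(0.7)
    assert m.n_positive_predictions + m.n_negative_predictions == m.n_test


def test_all_negative_predictor_metrics():
    y = np.concatenate([np.ones(10, bool), np.zeros(90, bool)])
    scores = np.full(100, 0.1)
    scores[:5] = 0.2  # avoid a constant scorer only for AUC definedness
    m = metrics_from_scores(y, scores, threshold=0.5)
    assert m.sensitivity == 0.0
    assert m.npv == pytest.approx(0.9)
    assert math.isnan(m.ppv)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    y = rng.random(500) < 0.3
    s = rng.random(500) + 0.3 * y
    a1 = metrics_from_scores(y, s).auc
    a2 = metrics_from_scores(y, np.exp(3 * s)).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_scoring_deterministic_and_column_checked(toy_features):
    cfg = ModelConfig(n_estimators=30, seed=1)
    train, test = split_train_test(toy_features, cfg)
    scorer = train_classifier(train, cfg)
    s1, s2 = score_visits(scorer, test), score_visits(scorer, test)
    assert np.array_equal(s1, s2)
    assert ((0 <= s1) & (s1 <= 1)).all()
    with pytest.raises(ValueError, match="missing at encode"):
        score_visits(scorer, test.drop(columns=["current_age"]))


def test_single_signal_feature_ranks_first():
    df = synthetic_feature_table(2000, signal="travel_time_min", strength=1.5, seed=6)
    cfg = ModelConfig(n_estimators=60, seed=2)
    scorer = train_classifier(df, cfg)
    imp = feature_importance(scorer)
    assert imp.index[0] == "travel_time_min"


def test_select_top_k_and_retrain(toy_features):
    cfg = ModelConfig(n_estimators=30, seed=1)
    scorer = train_classifier(toy_features, cfg)
    imp = feature_importance(scorer)
    assert select_top_k(imp, len(imp)) == list(imp.index)
    with pytest.raises(ValueError, match="exceeds"):
        select_top_k(imp, len(imp) + 1)
    cfg2 = ModelConfig(n_estimators=30, seed=1, top_k_features=2)
    reduced = train_classifier(toy_features, cfg2)
    assert len(feature_importance(reduced)) <= 2


def test_rebalancing_leaves_test_set_alone(toy_features):
    cfg = ModelConfig(seed=9)
    _, test1 = split_train_test(toy_features, cfg)
    rebalance(toy_features, "downsample", seed=1)
    _, test2 = split_train_test(toy_features, cfg)
    assert list(test1.index) == list(test2.index)


def test_bootstrap_stability_recovers_strong_signal():
    df = synthetic_feature_table(1200, signal="n_times_gt28d_late", strength=2.5, seed=10)
    cfg = ModelConfig(n_estimators=25, seed=4)
    out = bootstrap_stability(df, cfg, B=10, top_k=2)
    freq = out["selection_frequency"]
    assert ((0.0 <= freq) & (freq <= 1.0)).all()
    assert freq.loc["n_times_gt28d_late"] == 1.0
    q = out["metric_quantiles"]
    assert (q.loc[0.05] <= q.loc[0.5]).all() and (q.loc[0.5] <= q.loc[0.95]).all()
    with pytest.raises(ValueError, match="B must be"):
        bootstrap_stability(df, cfg, B=1)
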