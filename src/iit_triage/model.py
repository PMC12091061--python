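"""Imbalance-corrected boosted classifier for next-visit IIT risk.

The scorer is an AdaBoost ensemble of depth-1 trees (gradient boosting is
available as an alternative) trained on a class-rebalanced sample: the IIT
class is rare (~11-14% of visits), so the majority class is randomly
down-sampled — or the minority up-sampled — to parity before fitting.
Each scored visit receives a probability-like risk score in [0, 1] for the
outcome "the next scheduled visit is interrupted".

Evaluation reports the standard confusion-matrix metrics at a fixed 0.5
threshold plus the threshold-free AUC, and bootstrap refitting measures how
stable the top-ranked features are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, encode_for_model

__all__ = [
    "ModelConfig",
    "ModelMetrics",
    "RiskScorer",
    "split_train_test",
    "rebalance",
    "train_classifier",
    "score_visits",
    "metrics_from_scores",
    "evaluate",
    "feature_importance",
    "select_top_k",
    "bootstrap_stability",
]

LABEL = "iit_next_visit"


@dataclass
class ModelConfig:
    algorithm: str = "adaboost"  # or "gradient_boost"
    n_estimators: int = 200
    learning_rate: float = 1.0
    rebalance: str = "downsample"  # "downsample" | "upsample" | "none"
    test_fraction: float = 0.2
    split_unit: str = "visit"  # "visit" | "client"
    top_k_features: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.algorithm not in ("adaboost", "gradient_boost"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.rebalance not in ("downsample", "upsample", "none"):
            raise ValueError(f"unknown rebalance mode {self.rebalance!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.split_unit not in ("visit", "client"):
            raise ValueError(f"unknown split_unit {self.split_unit!r}")


@dataclass(frozen=True)
class ModelMetrics:
    """Confusion-matrix metrics at a fixed threshold, plus AUC."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    n_test: int
    n_positive_predictions: int
    n_negative_predictions: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RiskScorer:
    """A fitted classifier bound to its feature-encoding metadata."""

    estimator: object
    metadata: dict
    feature_columns: list[str] = field(default_factory=list)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        return score_visits(self, features)


def _labeled_rows(features: pd.DataFrame) -> pd.DataFrame:
    if LABEL not in features.columns:
        raise ValueError(f"feature table lacks the {LABEL!r} target column")
    return features.loc[features[LABEL].notna()]


def split_train_test(
    features: pd.DataFrame, config: ModelConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split scored visits into train and test sets.

    ``split_unit="visit"`` splits individual visits (clients may straddle the
    two sets, mirroring the headline analysis); ``split_unit="client"`` keeps
    each client's visits together as the leakage-safe alternative.
    Deterministic given the config seed.
    """
    config.validate()
    df = _labeled_rows(features)
    y = df[LABEL].astype(bool)
    if config.split_unit == "visit":
        if y.value_counts().min() < 2:
            raise ValueError("too few observations in a class to stratify the split")
        train, test = train_test_split(
            df,
            test_size=config.test_fraction,
            random_state=config.seed,
            stratify=y,
        )
    else:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=config.seed
        )
        idx_train, idx_test = next(splitter.split(df, groups=df["client_id"]))
        train, test = df.iloc[idx_train], df.iloc[idx_test]
    return train, test


def split_time_holdout(
    features: pd.DataFrame, holdout_months: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out the most recent months of visits as a deployment-style test set."""
    df = _labeled_rows(features)
    cutoff = df["scheduled_date"].max() - pd.Timedelta(days=holdout_months * 30.4375)
    return df.loc[df["scheduled_date"] <= cutoff], df.loc[df["scheduled_date"] > cutoff]


def rebalance(train: pd.DataFrame, mode: str, seed: int = 0) -> pd.DataFrame:
    """Equalize class sizes by random down- or up-sampling.

    ``downsample`` reduces the majority class to the minority size without
    replacement; ``upsample`` resamples the minority with replacement up to
    the majority size; ``none`` returns the input unchanged.
    """
    if mode == "none":
        return train
    y = train[LABEL].astype(bool)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("rebalancing requires both outcome classes present")
    rng = np.random.default_rng(seed)
    minority, majority = counts.idxmin(), counts.idxmax()
    minority_df = train.loc[y == minority]
    majority_df = train.loc[y == majority]
    if mode == "downsample":
        take = rng.choice(len(majority_df), size=len(minority_df), replace=False)
        majority_df = majority_df.iloc[np.sort(take)]
    elif mode == "upsample":
        take = rng.choice(len(minority_df), size=len(majority_df), replace=True)
        minority_df = minority_df.iloc[np.sort(take)]
    else:
        raise ValueError(f"unknown rebalance mode {mode!r}")
    return pd.concat([majority_df, minority_df]).sort_index()


def _make_estimator(config: ModelConfig):
    if config.algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=config.n_estimators,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        )
    return GradientBoostingClassifier(
        n_estimators=config.n_estimators,
        learning_rate=min(config.learning_rate, 0.5),
        random_state=config.seed,
    )


def _encode_checked(features: pd.DataFrame, metadata: dict | None):
    X, metadata = encode_for_model(features, metadata)
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite feature values after encoding")
    return X, values, metadata


def train_classifier(
    train: pd.DataFrame, config: ModelConfig, feature_columns: list[str] | None = None
) -> RiskScorer:
    """Fit the boosted scorer on (already rebalanced) training visits."""
    config.validate()
    df = _labeled_rows(train)
    if feature_columns is not None:
        keep = [c for c in df.columns if c not in FEATURE_COLUMNS or c in feature_columns]
        df = df[keep]
    X, values, metadata = _encode_checked(df, None)
    y = df[LABEL].astype(bool).to_numpy()
    est = _make_estimator(config)
    est.fit(values, y)
    scorer = RiskScorer(est, metadata, feature_columns=list(X.columns))
    if config.top_k_features is not None and feature_columns is None:
        top = select_top_k(feature_importance(scorer), config.top_k_features)
        scorer = train_classifier(train, replace(config, top_k_features=None), top)
    return scorer


def score_visits(scorer: RiskScorer, features: pd.DataFrame) -> np.ndarray:
    """Probability-like risk score in [0, 1] for each visit row."""
    X, values, _ = _encode_checked(features, scorer.metadata)
    if list(X.columns) != scorer.feature_columns:
        raise ValueError("encoded columns do not match the fitted scorer")
    return scorer.estimator.predict_proba(values)[:, 1]


def metrics_from_scores(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ModelMetrics:
    """Confusion-matrix metrics of scores against known outcomes."""
    y = np.asarray(y_true, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("outcomes contain a single class; AUC undefined")
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    n = len(y)

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return ModelMetrics(
        accuracy=(tp + tn) / n,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        auc=float(roc_auc_score(y, scores)),
        n_test=n,
        n_positive_predictions=tp + fp,
        n_negative_predictions=tn + fn,
    )


def evaluate(scorer: RiskScorer, test: pd.DataFrame, threshold: float = 0.5) -> ModelMetrics:
    """Score a held-out set and compute metrics at the given threshold."""
    df = _labeled_rows(test)
    y = df[LABEL].astype(bool).to_numpy()
    return metrics_from_scores(y, score_visits(scorer, df), threshold)


def feature_importance(scorer: RiskScorer) -> pd.Series:
    """Importance per base feature, summed over derived encoded columns.

    One-hot levels and missingness indicators are attributed back to their
    source feature; the result is sorted descending with a deterministic
    alphabetical tie-break.
    """
    imp = getattr(scorer.estimator, "feature_importances_", None)
    if imp is None:
        raise ValueError("fitted estimator exposes no feature importances")
    base = [c.split("=")[0].removesuffix("__missing") for c in scorer.feature_columns]
    s = pd.Series(imp, index=base).groupby(level=0).sum()
    return s.sort_index().sort_values(ascending=False, kind="stable")


def select_top_k(importances: pd.Series, k: int) -> list[str]:
    """The ``k`` highest-importance base features."""
    if k > len(importances):
        raise ValueError(f"k={k} exceeds the {len(importances)} available features")
    return list(importances.index[:k])


def bootstrap_stability(
    features: pd.DataFrame, config: ModelConfig, B: int, top_k: int = 11
) -> dict:
    """Refit on B bootstrap resamples of the training data.

    Returns the fraction of refits in which each feature ranks in the top
    ``top_k`` by importance, and the 5/50/95% quantiles of each test metric
    across refits. The test set is fixed across resamples.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    config.validate()
    train, test = split_train_test(features, config)
    rng = np.random.default_rng(config.seed)
    selected: list[list[str]] = []
    metric_rows = []
    for _ in range(B):
        idx = rng.choice(len(train), size=len(train), replace=True)
        boot = rebalance(train.iloc[np.sort(idx)], config.rebalance,
                         seed=int(rng.integers(2**31)))
        scorer = train_classifier(boot, config)
        imp = feature_importance(scorer)
        selected.append(select_top_k(imp, min(top_k, len(imp))))
        metric_rows.append(evaluate(scorer, test).to_dict())
    all_feats = sorted({f for sel in selected for f in sel})
    freq = pd.Series(
        {f: sum(f in sel for sel in selected) / B for f in all_feats}
    ).sort_values(ascending=False, kind="stable")
    metrics = pd.DataFrame(metric_rows)[
        ["accuracy", "sensitivity", "specificity", "ppv", "npv", "auc"]
    ]
    return {
        "selection_frequency": freq,
        "metric_quantiles": metrics.quantile([0.05, 0.5, 0.95]),
    }
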