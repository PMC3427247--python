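"""Random-forest classifiers: the first-stage model on selected features and
the two-stage model that stacks the first-stage disease probability with six
external predictor scores.

Forests default to 500 trees with sqrt(p) features per split and unlimited
depth.  Training rows are median-imputed (medians stored with the model).
The second stage always consumes out-of-fold first-stage scores during
training — never in-fold ones, which leak the training labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluation import MetricsReport, metrics_from_scores
from .io_formats import TOOL_COLUMNS

DEFAULT_FOREST_PARAMS = {"n_estimators": 500, "max_features": "sqrt"}

LABEL_COLUMN = "label"


class ModelError(ValueError):
    pass


def _check_features(df: pd.DataFrame, features: list[str]) -> None:
    unknown = [f for f in features if f not in df.columns]
    if unknown:
        raise ModelError(f"unknown feature names: {unknown}")


def _labels(df: pd.DataFrame) -> np.ndarray:
    if LABEL_COLUMN not in df.columns:
        raise ModelError("matrix has no label column")
    y = df[LABEL_COLUMN].to_numpy()
    if set(np.unique(y)) - {1, -1}:
        raise ModelError("labels must be 1 (disease) or -1 (neutral)")
    if len(np.unique(y)) < 2:
        raise ModelError("training requires both classes")
    return y


@dataclass
class FittedForest:
    estimator: RandomForestClassifier
    feature_names: list[str]
    medians: pd.Series
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def importances(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_, index=self.feature_names)

    def _impute(self, df: pd.DataFrame) -> pd.DataFrame:
        _check_features(df, self.feature_names)
        x = df[self.feature_names].astype(float)
        return x.fillna(self.medians)

    def predict_scores(self, df: pd.DataFrame) -> np.ndarray:
        """P(disease) per row."""
        x = self._impute(df)
        classes = list(self.estimator.classes_)
        return self.estimator.predict_proba(x.to_numpy())[:, classes.index(1)]


def _fit_forest(x: pd.DataFrame, y: np.ndarray, params: dict | None,
                seed: int) -> RandomForestClassifier:
    p = dict(DEFAULT_FOREST_PARAMS)
    p.update(params or {})
    forest = RandomForestClassifier(random_state=seed, **p)
    forest.fit(x.to_numpy(), y)
    return forest


def train_first_stage(df: pd.DataFrame, features: list[str],
                      params: dict | None = None, seed: int = 0) -> FittedForest:
    """Fit the first-stage forest on the selected features (median-imputed)."""
    _check_features(df, features)
    y = _labels(df)
    x = df[list(features)].astype(float)
    medians = x.median()
    x = x.fillna(medians).fillna(0.0)
    forest = _fit_forest(x, y, params, seed)
    return FittedForest(estimator=forest, feature_names=list(features),
                        medians=medians.fillna(0.0), seed=seed, params=params or {})


@dataclass
class CVResult:
    scores: pd.Series            # per-row disease probability, averaged over repeats
    metrics: MetricsReport
    k: int
    repeats: int
    seed: int


def cross_validate(df: pd.DataFrame, features: list[str], k: int = 5,
                   repeats: int = 100, seed: int = 0,
                   params: dict | None = None,
                   threshold: float = 0.5) -> CVResult:
    """Repeated stratified k-fold CV of the first-stage forest.

    Per-row scores are averaged across repeats before thresholding; metrics
    are computed once on the averaged scores.
    """
    if k < 2:
        raise ModelError("k must be >= 2")
    _check_features(df, features)
    y = _labels(df)
    counts = pd.Series(y).value_counts()
    if k > counts.min():
        raise ModelError(f"k={k} exceeds smallest class count {counts.min()}")
    score_sum = np.zeros(len(df))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(np.zeros(len(df)), y):
            fitted = train_first_stage(df.iloc[train_idx], features, params=params,
                                       seed=seed + rep)
            score_sum[test_idx] += fitted.predict_scores(df.iloc[test_idx])
    scores = pd.Series(score_sum / repeats, index=df.index, name="score")
    metrics = metrics_from_scores(scores.to_numpy(), y, threshold)
    return CVResult(scores=scores, metrics=metrics, k=k, repeats=repeats, seed=seed)


def out_of_fold_scores(df: pd.DataFrame, features: list[str], k: int = 5,
                       seed: int = 0, params: dict | None = None) -> pd.Series:
    """First-stage scores for training rows produced strictly out-of-fold."""
    y = _labels(df)
    scores = np.zeros(len(df))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(df)), y):
        fitted = train_first_stage(df.iloc[train_idx], features, params=params, seed=seed)
        scores[test_idx] = fitted.predict_scores(df.iloc[test_idx])
    return pd.Series(scores, index=df.index, name="first_stage")


@dataclass
class StackedModel:
    """Two-stage model: first-stage forest plus a second forest over the
    first-stage probability and the six external tool scores (7 columns)."""

    first_stage: FittedForest
    second_stage: FittedForest
    policy: str
    tool_columns: tuple = TOOL_COLUMNS

    def predict_scores(self, df: pd.DataFrame, tools: pd.DataFrame) -> pd.Series:
        first = self.first_stage.predict_scores(df)
        stacked = tools.reindex(df.index)[list(self.tool_columns)].astype(float).copy()
        stacked.insert(0, "first_stage", first)
        return pd.Series(self.second_stage.predict_scores(stacked), index=df.index,
                         name="score")


def _apply_tool_policy(tools: pd.DataFrame, policy: str) -> pd.DataFrame:
    tools = tools[list(TOOL_COLUMNS)].astype(float)
    if policy == "drop-incomplete":
        return tools.dropna()
    if policy == "impute":
        return tools.fillna(tools.median())
    raise ModelError(f"unknown missing-score policy {policy!r}")


def train_two_stage(df: pd.DataFrame, features: list[str], tools: pd.DataFrame,
                    k_inner: int = 5, policy: str = "drop-incomplete",
                    params: dict | None = None, seed: int = 0) -> StackedModel:
    """Fit the stacked model.

    Tool rows are joined to the matrix by index; rows failing the
    missing-score policy are excluded (drop-incomplete) or median-imputed
    (impute).  First-stage inputs to the second stage come from ``k_inner``-
    fold out-of-fold prediction on the retained rows.
    """
    tools = _apply_tool_policy(tools.reindex(df.index), policy)
    retained = df.loc[df.index.intersection(tools.index)]
    if retained.empty:
        raise ModelError("all rows dropped by the missing-score policy")
    first_full = train_first_stage(retained, features, params=params, seed=seed)
    oof = out_of_fold_scores(retained, features, k=k_inner, seed=seed, params=params)
    stacked = tools.loc[retained.index].copy()
    stacked.insert(0, "first_stage", oof)
    stacked[LABEL_COLUMN] = retained[LABEL_COLUMN]
    second = train_first_stage(stacked, ["first_stage", *TOOL_COLUMNS],
                               params=params, seed=seed + 1)
    return StackedModel(first_stage=first_full, second_stage=second, policy=policy)


def cross_validate_stacked(df: pd.DataFrame, features: list[str], tools: pd.DataFrame,
                           k: int = 5, k_inner: int = 5,
                           policy: str = "drop-incomplete",
                           params: dict | None = None, seed: int = 0,
                           threshold: float = 0.5) -> tuple[CVResult, CVResult]:
    """Paired outer CV of the first-stage and two-stage models.

    Returns (first_stage_result, two_stage_result) on the same outer folds
    and row subset, so AUC/MCC comparisons are paired.
    """
    tools_ok = _apply_tool_policy(tools.reindex(df.index), policy)
    data = df.loc[df.index.intersection(tools_ok.index)]
    if data.empty:
        raise ModelError("all rows dropped by the missing-score policy")
    y = _labels(data)
    first_scores = np.zeros(len(data))
    stacked_scores = np.zeros(len(data))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(data)), y):
        train, test = data.iloc[train_idx], data.iloc[test_idx]
        stacked_model = train_two_stage(train, features, tools_ok, k_inner=k_inner,
                                        policy=policy, params=params, seed=seed)
        first_scores[test_idx] = stacked_model.first_stage.predict_scores(test)
        stacked_scores[test_idx] = stacked_model.predict_scores(test, tools_ok)
    first = CVResult(scores=pd.Series(first_scores, index=data.index),
                     metrics=metrics_from_scores(first_scores, y, threshold),
                     k=k, repeats=1, seed=seed)
    second = CVResult(scores=pd.Series(stacked_scores, index=data.index),
                      metrics=metrics_from_scores(stacked_scores, y, threshold),
                      k=k, repeats=1, seed=seed)
    return first, second


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: FittedForest | StackedModel, path) -> None:
    """Persist a model as a joblib archive plus JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    if isinstance(model, StackedModel):
        meta = {"kind": "two-stage", "features": model.first_stage.feature_names,
                "tool_columns": list(model.tool_columns), "policy": model.policy,
                "seed": model.first_stage.seed}
    else:
        meta = {"kind": "first-stage", "features": model.feature_names,
                "seed": model.seed, "params": model.params}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path):
    return joblib.load(path)
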