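"""Two-step feature selection.

Step one scores every feature by its mean decrease in Gini impurity (MDGI)
averaged over repeated forest fits, standardizes the means to Z-scores
z_i = (x_i − x̄)/σ, and keeps features with Z > 1.0 as optimal feature
candidates.  Step two is backward stepwise elimination: each round tries
removing every surviving feature, evaluates the remainder by repeated
stratified 5-fold cross-validated MCC (scores averaged over repeats before
thresholding), accepts the best removal if it improves the incumbent MCC,
and stops when no removal improves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .model import LABEL_COLUMN, DEFAULT_FOREST_PARAMS, ModelError, _labels, cross_validate


class EmptySelectionError(ValueError):
    """Raised when no feature clears the Z-score threshold."""


@dataclass
class ZScoreReport:
    """Per-feature MDGI summary: mean importance x_i, Z = (x_i − x̄)/σ."""

    table: pd.DataFrame  # columns: mean_mdgi, zscore, candidate
    mean: float          # x̄
    sd: float            # σ
    threshold: float
    repeats: int
    seed: int

    def candidates(self) -> list[str]:
        cand = self.table[self.table["candidate"]]
        return cand.sort_values("zscore", ascending=False).index.tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def compute_mdgi_zscores(df: pd.DataFrame, repeats: int = 100,
                         forest_params: dict | None = None, seed: int = 0,
                         threshold: float = 1.0) -> ZScoreReport:
    """Average Gini importances over ``repeats`` forests (seeds seed…seed+R−1)
    and standardize across features."""
    y = _labels(df)
    features = [c for c in df.columns if c != LABEL_COLUMN]
    x = df[features].astype(float)
    x = x.fillna(x.median()).fillna(0.0)
    params = dict(DEFAULT_FOREST_PARAMS)
    params.update(forest_params or {})
    total = np.zeros(len(features))
    for r in range(repeats):
        forest = RandomForestClassifier(random_state=seed + r, **params)
        forest.fit(x.to_numpy(), y)
        total += forest.feature_importances_
    mean_mdgi = total / repeats
    x_bar = float(mean_mdgi.mean())
    sigma = float(mean_mdgi.std(ddof=0))
    if sigma == 0:
        raise ModelError("degenerate importances: zero variance across features")
    z = (mean_mdgi - x_bar) / sigma
    table = pd.DataFrame(
        {"mean_mdgi": mean_mdgi, "zscore": z, "candidate": z > threshold},
        index=pd.Index(features, name="feature"),
    )
    return ZScoreReport(table=table, mean=x_bar, sd=sigma, threshold=threshold,
                        repeats=repeats, seed=seed)


def select_candidates(report: ZScoreReport, threshold: float | None = None) -> list[str]:
    """Features with Z strictly above the threshold, ordered by descending Z."""
    thr = report.threshold if threshold is None else threshold
    tab = report.table
    selected = tab[tab["zscore"] > thr].sort_values("zscore", ascending=False)
    if selected.empty:
        raise EmptySelectionError(
            f"no feature has Z-score > {thr} (max is {tab['zscore'].max():.3f})")
    return selected.index.tolist()


@dataclass
class SelectionRound:
    round: int
    removed: str | None
    mcc_before: float
    mcc_after: float
    surviving: list[str]


@dataclass
class SelectionTrace:
    initial_features: list[str]
    initial_mcc: float
    rounds: list[SelectionRound] = field(default_factory=list)

    @property
    def final_features(self) -> list[str]:
        return self.rounds[-1].surviving if self.rounds else list(self.initial_features)

    @property
    def final_mcc(self) -> float:
        return self.rounds[-1].mcc_after if self.rounds else self.initial_mcc

    def to_json(self, path) -> None:
        payload = {
            "initial_features": self.initial_features,
            "initial_mcc": self.initial_mcc,
            "rounds": [
                {"round": r.round, "removed": r.removed, "mcc_before": r.mcc_before,
                 "mcc_after": r.mcc_after, "surviving": r.surviving}
                for r in self.rounds
            ],
            "final_features": self.final_features,
            "final_mcc": self.final_mcc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("round\tremoved\tmcc\tn_features\n")
            fh.write(f"0\t-\t{self.initial_mcc:.6f}\t{len(self.initial_features)}\n")
            for r in self.rounds:
                fh.write(f"{r.round}\t{r.removed}\t{r.mcc_after:.6f}\t{len(r.surviving)}\n")


def stepwise_select(df: pd.DataFrame, candidates: list[str], cv_k: int = 5,
                    cv_repeats: int = 10, epsilon: float = 1e-4, seed: int = 0,
                    forest_params: dict | None = None,
                    zscores: pd.Series | None = None,
                    max_rounds: int | None = None) -> SelectionTrace:
    """Backward stepwise elimination maximizing repeated-CV MCC.

    Each round evaluates removing every surviving feature on the same CV
    folds (seeded by round), accepts the removal with maximal MCC if it
    beats the incumbent by more than ``epsilon``, breaking ties by removing
    the feature with the lowest Z-score, and terminates when no removal
    improves (or after ``max_rounds`` accepted removals).
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate feature")

    def cv_mcc(feats: list[str], round_seed: int) -> float:
        res = cross_validate(df, feats, k=cv_k, repeats=cv_repeats, seed=round_seed,
                             params=forest_params)
        return res.metrics.mcc

    surviving = list(candidates)
    incumbent = cv_mcc(surviving, seed)
    trace = SelectionTrace(initial_features=list(candidates), initial_mcc=incumbent)
    if len(surviving) < 2:
        return trace

    round_no = 0
    while len(surviving) > 1:
        round_no += 1
        round_seed = seed + round_no
        results = []
        for feat in surviving:
            trial = [f for f in surviving if f != feat]
            results.append((feat, cv_mcc(trial, round_seed)))
        best_mcc = max(m for _, m in results)
        if best_mcc <= incumbent + epsilon:
            break
        tied = [f for f, m in results if m == best_mcc]
        if len(tied) > 1 and zscores is not None:
            removed = min(tied, key=lambda f: zscores.get(f, np.inf))
        else:
            removed = tied[0]
        surviving = [f for f in surviving if f != removed]
        trace.rounds.append(SelectionRound(
            round=round_no, removed=removed, mcc_before=incumbent,
            mcc_after=best_mcc, surviving=list(surviving)))
        incumbent = best_mcc
        if max_rounds is not None and round_no >= max_rounds:
            break
    return trace
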