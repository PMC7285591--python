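"""Boosted random-forest classifier.

A discrete AdaBoost loop whose weak learners are small random forests.
Each round t resamples the training set proportionally to the current
boosting weights (weighted bootstrap), fits a forest h_t, computes the
weighted training error eps_t, and assigns the learner weight

    alpha_t = learning_rate * 1/2 * ln((1 - eps_t) / eps_t)

Misclassified samples are up-weighted by exp(alpha_t), correctly
classified samples down-weighted by exp(-alpha_t), and weights are
renormalized.  The loop stops early when eps_t = 0 (perfect round; alpha
capped at a finite maximum) or eps_t >= 0.5 (no-better-than-chance round).

Scoring aggregates the forests' positive-class probabilities as the
alpha-weighted mean, giving a score in [0, 1]; the classical hard-vote
sign rule over alpha-weighted {-1,+1} votes is also exposed.  A score is
called "yes" when it is greater than or equal to the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from aptapred.imbalance import LabeledDataset

#: finite cap used in place of an infinite learner weight when eps_t = 0
ALPHA_MAX = float(np.log(1e10))

#: default decision thresholds: pair-interaction mode and aptamer mode
PAIR_THRESHOLD = 0.44
APTAMER_THRESHOLD = 0.48


@dataclass(frozen=True)
class BoostParams:
    """Ensemble hyperparameters (defaults: 10-tree depth-150 forests,
    300 boosting rounds, learning rate 0.75)."""

    n_trees: int = 10
    max_depth: int = 150
    n_rounds: int = 300
    learning_rate: float = 0.75

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


def learner_weight(eps: float, learning_rate: float = 1.0) -> float:
    """alpha = learning_rate * 1/2 * ln((1-eps)/eps), capped at ALPHA_MAX.

    eps = 1/2 gives alpha = 0; eps = 0 gives the cap.
    """
    if eps <= 0.0:
        return learning_rate * ALPHA_MAX
    if eps >= 1.0:
        return -learning_rate * ALPHA_MAX
    raw = 0.5 * np.log((1.0 - eps) / eps)
    return float(learning_rate * np.clip(raw, -ALPHA_MAX, ALPHA_MAX))


@dataclass
class BoostedForestModel:
    """Ordered base forests with their weights and a decision threshold."""

    learners: list[RandomForestClassifier]
    alphas: np.ndarray
    params: BoostParams
    feature_names: tuple[str, ...]
    threshold: float = PAIR_THRESHOLD
    errors: np.ndarray = field(default_factory=lambda: np.array([]))
    stopped_early_at: int | None = None

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.learners) < 1:
            raise ValueError("model must have at least one learner")
        if len(self.learners) != len(self.alphas):
            raise ValueError("learners/alphas length mismatch")
        if not np.all(np.isfinite(self.alphas)):
            raise ValueError("non-finite learner weights")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def n_rounds(self) -> int:
        return len(self.learners)

    def _check_features(self, features: pd.DataFrame) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            if tuple(features.columns) != self.feature_names:
                raise ValueError(
                    "feature signature mismatch: model was trained on "
                    f"{len(self.feature_names)} named columns; input columns "
                    "differ in names or order"
                )
            return features.to_numpy(dtype=float)
        arr = np.asarray(features, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.feature_names):
            raise ValueError("feature signature mismatch: wrong column count")
        return arr

    def _positive_probas(self, X: np.ndarray) -> np.ndarray:
        """(n_rounds, n_samples) positive-class probabilities per learner."""
        out = np.empty((len(self.learners), X.shape[0]))
        for t, forest in enumerate(self.learners):
            proba = forest.predict_proba(X)
            classes = list(forest.classes_)
            if 1 in classes:
                out[t] = proba[:, classes.index(1)]
            else:
                out[t] = 0.0
        return out

    def predict_score(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Alpha-weighted mean of base-forest positive probabilities, in [0,1]."""
        X = self._check_features(features)
        P = self._positive_probas(X)
        total = self.alphas.sum()
        if total <= 0:
            return P.mean(axis=0)
        return (self.alphas[:, None] * P).sum(axis=0) / total

    def predict_vote(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Hard-vote rule: sign of the alpha-weighted sum of {-1,+1} votes.

        Returns labels in {0, 1}; a zero aggregate falls on the positive side.
        """
        X = self._check_features(features)
        votes = np.empty((len(self.learners), X.shape[0]))
        for t, forest in enumerate(self.learners):
            votes[t] = 2.0 * (forest.predict(X) == 1) - 1.0
        agg = (self.alphas[:, None] * votes).sum(axis=0)
        return (agg >= 0).astype(int)

    def save(self, path) -> None:
        joblib.dump({"format": "aptapred-model-v1", "model": self}, path)

    @staticmethod
    def load(path) -> "BoostedForestModel":
        payload = joblib.load(path)
        if not (isinstance(payload, dict) and payload.get("format") == "aptapred-model-v1"):
            raise ValueError("not an aptapred model archive")
        return payload["model"]


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary decision: 1 ("yes") iff score >= threshold (boundary inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    scores = np.asarray(scores, dtype=float)
    return (scores >= threshold).astype(int)


def fit_boosted_forest(
    train: LabeledDataset,
    params: BoostParams | None = None,
    seed: int = 0,
    threshold: float = PAIR_THRESHOLD,
) -> BoostedForestModel:
    """Fit the AdaBoost-over-random-forest ensemble on a labeled dataset."""
    params = params or BoostParams()
    X = train.features.to_numpy(dtype=float)
    y = train.labels
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training data")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    n = X.shape[0]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    weights = np.full(n, 1.0 / n)
    learners: list[RandomForestClassifier] = []
    alphas: list[float] = []
    errors: list[float] = []
    stopped_at: int | None = None

    for t in range(params.n_rounds):
        idx = rng.choice(n, size=n, replace=True, p=weights)
        # guarantee both classes in the weighted bootstrap
        if len(np.unique(y[idx])) < 2:
            for c in classes:
                if not np.any(y[idx] == c):
                    pool = np.flatnonzero(y == c)
                    idx[rng.integers(0, n) % len(idx)] = pool[
                        np.argmax(weights[pool])
                    ]
        forest = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_depth=params.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X[idx], y[idx])
        pred = forest.predict(X)
        miss = pred != y
        eps = float(weights[miss].sum())
        alpha = learner_weight(eps, params.learning_rate)

        if eps >= 0.5 and t > 0:
            # no-better-than-chance round: stop, keep previously fitted rounds
            stopped_at = t
            break
        learners.append(forest)
        alphas.append(max(alpha, 0.0) if eps >= 0.5 else alpha)
        errors.append(eps)
        if eps == 0.0 or eps >= 0.5:
            stopped_at = t + 1 if t + 1 < params.n_rounds else None
            break
        weights = weights * np.exp(np.where(miss, alpha, -alpha))
        weights /= weights.sum()

    return BoostedForestModel(
        learners=learners,
        alphas=np.array(alphas),
        params=params,
        feature_names=tuple(train.features.columns),
        threshold=threshold,
        errors=np.array(errors),
        stopped_early_at=stopped_at,
    )


def prediction_table(
    names: Sequence[str],
    scores: np.ndarray,
    threshold: float,
    name_column: str = "name",
) -> pd.DataFrame:
    """Standard output table: name, result ("yes"/"no"), score."""
    labels = classify(scores, threshold)
    return pd.DataFrame(
        {
            name_column: list(names),
            "result": ["yes" if v else "no" for v in labels],
            "score": np.asarray(scores, dtype=float),
        }
    )
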