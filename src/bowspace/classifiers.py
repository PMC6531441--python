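"""The five interaction classifiers behind one train/predict surface.

All models consume the same feature matrix (any subspace mask of the
439-column bow descriptor) and emit an interaction probability per pair:

* ``bart``          -- probit sum-of-trees with backfitting MCMC (the
                       probabilistic reference model; also yields a central
                       posterior interval per pair);
* ``logistic``      -- logistic regression, regularisation constant C = 1e5;
* ``svm``           -- RBF support vector machine, gamma = 1e-4, C = 100,
                       Platt-scaled probabilities;
* ``decision_tree`` -- a single CART tree;
* ``random_forest`` -- a bagged forest of CART trees.

Tree-based models consume raw features; logistic and SVM are fitted on
per-column standardized features (scaler fitted on the training set only).
Hard labels follow the 0.5 rule: probability strictly above the threshold
means "interaction", equal or below means "non-interaction".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from bowspace.bart import BartClassifier
from bowspace.exceptions import DegenerateTrainingError, InvalidInputError, SignatureError

CLASSIFIER_NAMES = ("bart", "logistic", "svm", "decision_tree", "random_forest")

#: Stated defaults for the classical baselines.
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "logistic": {"C": 1e5, "max_iter": 2000},
    "svm": {"gamma": 1e-4, "C": 100.0},
    "decision_tree": {},
    "random_forest": {"n_estimators": 100},
    "bart": {"n_trees": 50, "n_burn": 200, "n_keep": 800},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train, with hyperparameter overrides and a seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise InvalidInputError(
                f"unknown classifier {self.name!r}; expected one of {CLASSIFIER_NAMES}"
            )

    def resolved_params(self) -> dict:
        params = dict(DEFAULT_PARAMS[self.name])
        params.update(self.params)
        return params


@dataclass
class FittedModel:
    """A trained classifier plus the spec and feature-column signature."""

    spec: ClassifierSpec
    columns: tuple[str, ...] | int
    estimator: Any

    @property
    def supports_interval(self) -> bool:
        return self.spec.name == "bart"


@dataclass
class PredictionResult:
    """Probabilities (and, for BART, central posterior intervals) per pair."""

    ids: list[str]
    proba: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    threshold: float = 0.5

    @property
    def labels(self) -> np.ndarray:
        return classify(self.proba, self.threshold)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pair": self.ids, "probability": self.proba})
        if self.lo is not None:
            df["lo"] = self.lo
            df["hi"] = self.hi
        df["label"] = self.labels
        return df


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | int]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, arr.shape[1]


def _build_estimator(spec: ClassifierSpec):
    params = spec.resolved_params()
    if spec.name == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(random_state=spec.seed, **params)
        )
    if spec.name == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=spec.seed, **params),
        )
    if spec.name == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    if spec.name == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    return BartClassifier(random_state=spec.seed, **params)


def train(spec: ClassifierSpec, X, y) -> FittedModel:
    """Fit the requested classifier; deterministic given the spec's seed.

    Raises DegenerateTrainingError when y has a single class and
    InvalidInputError on shape problems or missing values.
    """
    mat, columns = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if mat.ndim != 2 or mat.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(mat)):
        raise InvalidInputError("feature matrix contains non-finite values")
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    estimator = _build_estimator(spec)
    estimator.fit(mat, y)
    return FittedModel(spec=spec, columns=columns, estimator=estimator)


def _check_signature(model: FittedModel, X) -> np.ndarray:
    mat, columns = _as_matrix(X)
    if isinstance(model.columns, tuple) and isinstance(columns, tuple):
        if columns != model.columns:
            raise SignatureError(
                "feature columns do not match the training signature "
                f"(got {len(columns)} columns, trained on {len(model.columns)})"
            )
    else:
        n_train = model.columns if isinstance(model.columns, int) else len(model.columns)
        if mat.shape[1] != n_train:
            raise SignatureError(
                f"expected {n_train} feature columns, got {mat.shape[1]}"
            )
    return mat


def predict_proba(model: FittedModel, X, ids=None, threshold: float = 0.5,
                  interval_level: float = 0.95) -> PredictionResult:
    """Interaction probabilities for new pairs (+ posterior intervals for BART)."""
    mat = _check_signature(model, X)
    if ids is None:
        ids = list(X.index.astype(str)) if isinstance(X, pd.DataFrame) else [
            str(i) for i in range(mat.shape[0])
        ]
    proba = model.estimator.predict_proba(mat)[:, 1]
    lo = hi = None
    if model.supports_interval:
        bounds = model.estimator.predict_interval(mat, level=interval_level)
        lo, hi = bounds[:, 0], bounds[:, 1]
    return PredictionResult(ids=list(ids), proba=proba, lo=lo, hi=hi,
                            threshold=threshold)


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff p > threshold (p equal to the threshold maps to 0)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    return (p > threshold).astype(int)
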