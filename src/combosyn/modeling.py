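"""Classifier training, grid search and greedy forward feature selection.

Model families are classical classifiers behind a single :class:`ModelSpec`
contract: random forest, extremely randomized trees, gradient boosting,
k-nearest neighbors, extreme gradient boosting (XGBoost), an additive
logistic glass-box, and (when the optional ``interpret`` backend is
installed) the Explainable Boosting Machine.  Feature selection is the
bottom-up greedy procedure: start empty, at each round score every
unselected feature by mean k-fold cross-validated Matthews correlation
coefficient of the learner on the selected set plus that feature, append
the best, and stop at a feature budget or when no feature improves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

FAMILIES = (
    "random_forest",
    "extremely_randomized_trees",
    "gradient_boosting",
    "knn",
    "extreme_gradient_boosting",
    "additive_logistic",
    "ebm",
)

#: Default hyperparameter grids per family (config-overridable; these make
#: no claim of matching any published tuned values).
DEFAULT_GRIDS = {
    "random_forest": {"n_estimators": [100, 300, 600], "max_depth": [None, 8, 16]},
    "extremely_randomized_trees": {
        "n_estimators": [100, 300, 600],
        "max_depth": [None, 8, 16],
    },
    "gradient_boosting": {"n_estimators": [100, 300], "max_depth": [2, 3]},
    "knn": {"n_neighbors": [3, 5, 11, 21]},
    "extreme_gradient_boosting": {"n_estimators": [100, 300], "max_depth": [3, 6]},
    "additive_logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "ebm": {},
}


class ModelFamilyUnavailable(ImportError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {FAMILIES}"
            )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn-compatible estimator for a spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "extremely_randomized_trees":
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    if spec.family == "extreme_gradient_boosting":
        from xgboost import XGBClassifier

        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "additive_logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, **hp)
        )
    if spec.family == "ebm":
        try:
            from interpret.glassbox import ExplainableBoostingClassifier
        except ImportError as e:  # pragma: no cover - optional backend
            raise ModelFamilyUnavailable(
                "the 'ebm' family delegates to the optional 'interpret' "
                "package, which is not installed"
            ) from e
        return ExplainableBoostingClassifier(random_state=spec.seed, **hp)
    raise ValueError(spec.family)


@dataclass
class TrainedModel:
    """A fitted estimator plus the provenance needed to reuse it safely."""

    estimator: object
    spec: ModelSpec
    feature_names: list
    config_hash: str = None

    def predict_proba(self, X, config_hash: str = None) -> np.ndarray:
        """P(synergistic) per row; refuses a mismatched feature config."""
        if (
            config_hash is not None
            and self.config_hash is not None
            and config_hash != self.config_hash
        ):
            raise ValueError(
                f"feature-config hash mismatch: model {self.config_hash}, "
                f"input {config_hash}"
            )
        X = np.asarray(X, dtype=float)
        proba = self.estimator.predict_proba(X)
        classes = list(getattr(self.estimator, "classes_", [0, 1]))
        return proba[:, classes.index(1)]

    def predict(self, X, threshold: float = 0.5, config_hash: str = None):
        return (self.predict_proba(X, config_hash) >= threshold).astype(int)

    def save(self, path):
        joblib.dump(
            {
                "estimator": self.estimator,
                "spec": self.spec.to_dict(),
                "feature_names": self.feature_names,
                "config_hash": self.config_hash,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        return cls(
            estimator=blob["estimator"],
            spec=ModelSpec(**blob["spec"]),
            feature_names=blob["feature_names"],
            config_hash=blob["config_hash"],
        )


def train_classifier(
    X, y, spec: ModelSpec, feature_names=None, config_hash: str = None
) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    est = build_estimator(spec)
    est.fit(X, y)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return TrainedModel(
        estimator=est,
        spec=spec,
        feature_names=list(feature_names),
        config_hash=config_hash,
    )


# ---------------------------------------------------------------------------
# Cross-validated MCC and grid search


def _cv_mcc(X, y, spec: ModelSpec, k: int, seed: int) -> float:
    """Mean out-of-fold MCC of the spec under stratified k-fold CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        est = build_estimator(spec)
        est.fit(X[tr], y[tr])
        scores.append(matthews_corrcoef(y[te], est.predict(X[te])))
    return float(np.mean(scores))


def _complexity(hp: dict) -> tuple:
    """Tie-break key: fewer estimators / smaller numeric settings first."""
    n_est = hp.get("n_estimators", 0)
    numeric = sum(v for v in hp.values() if isinstance(v, (int, float)) and v is not None)
    return (n_est, numeric, json.dumps(hp, sort_keys=True, default=str))


@dataclass
class GridSearchResult:
    best: ModelSpec
    scores: list  # (hyperparameter dict, mean CV MCC) per grid point


def grid_search(
    X, y, family: str, grid: dict = None, k: int = 5, seed: int = 0
) -> GridSearchResult:
    """Exhaustive grid search scored by stratified k-fold CV MCC.

    Ties go to the lowest-complexity point (fewest estimators, then the
    smallest numeric settings, then lexicographic).
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if k < 2:
        raise ValueError("need at least 2 CV folds")
    names = sorted(grid)
    if names and any(len(grid[n]) == 0 for n in names):
        raise ValueError("empty hyperparameter value list")
    points = [{}]
    for n in names:
        points = [dict(p, **{n: v}) for p in points for v in grid[n]]
    scored = []
    for hp in points:
        spec = ModelSpec(family=family, hyperparameters=hp, seed=seed)
        scored.append((hp, _cv_mcc(X, y, spec, k, seed)))
    best_hp = min(scored, key=lambda t: (-t[1],) + _complexity(t[0]))[0]
    return GridSearchResult(
        best=ModelSpec(family=family, hyperparameters=best_hp, seed=seed),
        scores=scored,
    )


# ---------------------------------------------------------------------------
# Greedy forward feature selection


@dataclass
class FeatureSelectionTrace:
    steps: list  # (feature name, CV MCC after inclusion)
    stopping_reason: str  # "max_features" | "no_improvement"

    @property
    def selected(self) -> list:
        return [name for name, _ in self.steps]


def greedy_forward_selection(
    X,
    y,
    spec: ModelSpec,
    feature_names=None,
    k: int = 10,
    max_features: int = 10,
    seed: int = 0,
) -> FeatureSelectionTrace:
    """Bottom-up greedy feature selection scored by k-fold CV MCC.

    Every round evaluates each unselected feature joined to the selected
    set and appends the highest-scoring one (ties -> lowest column index).
    Stops at ``max_features`` or at the first round where no candidate
    improves the incumbent MCC, whichever comes first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    selected: list = []
    steps = []
    incumbent = -np.inf
    while len(selected) < max_features:
        best_j, best_score = None, -np.inf
        for j in range(X.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            score = _cv_mcc(X[:, cols], y, spec, k, seed)
            if score > best_score:
                best_j, best_score = j, score
        if best_j is None or best_score <= incumbent:
            return FeatureSelectionTrace(steps=steps, stopping_reason="no_improvement")
        selected.append(best_j)
        steps.append((feature_names[best_j], best_score))
        incumbent = best_score
    return FeatureSelectionTrace(steps=steps, stopping_reason="max_features")
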