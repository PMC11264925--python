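"""Feature attribution: permutation importance, glass-box contributions,
per-feature risk profiles.

The always-available path is seeded permutation importance (drop in MCC
when a column is shuffled).  Models exposing additive per-feature
contributions — the ``additive_logistic`` glass-box here, or an EBM when
its optional backend is installed — additionally support exact global
importances (mean absolute contribution over a reference matrix) and
risk-profile curves; for other families the risk profile falls back to
centered partial dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.inspection import partial_dependence
from sklearn.metrics import matthews_corrcoef
from sklearn.pipeline import Pipeline

from .modeling import TrainedModel


@dataclass
class ImportanceReport:
    features: list
    importances: np.ndarray
    method: str  # glassbox_contribution | shapley_summary | permutation

    def ranking(self) -> list:
        order = np.argsort(-self.importances, kind="mergesort")
        return [self.features[i] for i in order]

    def to_frame(self):
        import pandas as pd

        out = pd.DataFrame(
            {"feature": self.features, "importance": self.importances}
        ).sort_values("importance", ascending=False, kind="mergesort")
        return out.reset_index(drop=True)


def permutation_importance(
    model: TrainedModel, X, y, n_repeats: int = 5, seed: int = 0
) -> ImportanceReport:
    """Mean MCC drop over ``n_repeats`` column shuffles, per feature."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to score MCC")
    rng = np.random.default_rng(seed)
    baseline = matthews_corrcoef(y, model.predict(X))
    imps = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - matthews_corrcoef(y, model.predict(Xp)))
        imps[j] = np.mean(drops)
    return ImportanceReport(
        features=list(model.feature_names), importances=imps, method="permutation"
    )


def _linear_parts(model: TrainedModel):
    """(coef, scaler) when the estimator is an additive linear glass-box."""
    est = model.estimator
    if isinstance(est, Pipeline):
        final = est.steps[-1][1]
        scaler = est.steps[0][1] if len(est.steps) > 1 else None
        if hasattr(final, "coef_"):
            return final, scaler
    elif hasattr(est, "coef_"):
        return est, None
    return None, None


def global_importance(model: TrainedModel, X, y=None, seed: int = 0) -> ImportanceReport:
    """Mean absolute per-feature contribution over ``X``.

    Exact for additive models (contribution of feature j on a row is its
    weight times the standardized value).  Non-additive families fall
    back to permutation importance, which needs ``y``; the method tag in
    the report records which path produced it.
    """
    X = np.asarray(X, dtype=float)
    linear, scaler = _linear_parts(model)
    if linear is not None:
        Z = scaler.transform(X) if scaler is not None else X
        contrib = Z * linear.coef_.ravel()
        return ImportanceReport(
            features=list(model.feature_names),
            importances=np.abs(contrib).mean(axis=0),
            method="glassbox_contribution",
        )
    if hasattr(model.estimator, "term_importances"):  # EBM backend
        return ImportanceReport(
            features=list(model.feature_names),
            importances=np.asarray(model.estimator.term_importances()),
            method="glassbox_contribution",
        )
    if y is None:
        raise ValueError(
            "model is not additive; permutation fallback requires labels y"
        )
    return permutation_importance(model, X, y, seed=seed)


@dataclass
class RiskProfile:
    feature: str
    grid: np.ndarray
    contribution: np.ndarray  # centered score contribution along the grid
    histogram: tuple  # (counts, bin edges) of observed values
    method: str


def risk_profile(
    model: TrainedModel, feature: str, X, grid_size: int = 25
) -> RiskProfile:
    """Per-feature contribution curve over the observed value range.

    Positive values push toward the synergistic class, negative toward
    antagonistic.  Additive models give the exact (centered) weight-times-
    value line; other families use centered partial dependence of
    P(synergistic).  Grid bounds equal the observed min/max.
    """
    if feature not in model.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = model.feature_names.index(feature)
    X = np.asarray(X, dtype=float)
    lo, hi = X[:, j].min(), X[:, j].max()
    grid = np.linspace(lo, hi, grid_size) if hi > lo else np.array([lo])
    counts, edges = np.histogram(X[:, j], bins=min(20, max(5, grid_size // 2)))

    linear, scaler = _linear_parts(model)
    if linear is not None:
        w = linear.coef_.ravel()[j]
        if scaler is not None:
            z = (grid - scaler.mean_[j]) / scaler.scale_[j]
        else:
            z = grid
        contrib = w * z
        contrib = contrib - contrib.mean()
        method = "glassbox_contribution"
    else:
        pd_res = partial_dependence(
            model.estimator, X, [j], grid_resolution=len(grid),
            custom_values={j: grid} if len(grid) > 1 else None,
        )
        contrib = np.asarray(pd_res["average"][0], dtype=float)
        grid = np.asarray(pd_res["grid_values"][0], dtype=float)
        contrib = contrib - contrib.mean()
        method = "partial_dependence"
    return RiskProfile(
        feature=feature,
        grid=np.asarray(grid, dtype=float),
        contribution=np.asarray(contrib, dtype=float),
        histogram=(counts, edges),
        method=method,
    )
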