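"""Evaluation: the seven-metric suite, CV-scheme runs, KS feature analysis.

The metric suite mirrors the standard binary-classification bundle for
synergy prediction: accuracy, balanced accuracy, Matthews correlation
coefficient (MCC), area under the ROC curve, precision, recall and F1,
with class 1 (synergistic) as the positive class.  Scheme evaluation
fits a fresh model per fold and reports both per-fold metrics and the
pooled out-of-fold metrics (the literature is not always explicit about
which it reports, so both are emitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, wilcoxon
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from statsmodels.stats.multitest import multipletests

from .curation import CVScheme, make_cv_folds
from .features import Featurizer
from .modeling import ModelSpec, train_classifier


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y, yhat) -> ConfusionMatrix:
    """2x2 counts with class 1 = synergistic = positive."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if len(y) == 0:
        raise ValueError("empty inputs")
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    if not (np.isin(y, (0, 1)).all() and np.isin(yhat, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    mcc: float
    auroc: float
    precision: float
    recall: float
    f1: float
    n: int
    scheme: str = ""
    fold: str = ""

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n": self.n,
            "scheme": self.scheme,
            "fold": self.fold,
        }


def metric_suite(
    y, scores, threshold: float = 0.5, scheme: str = "", fold: str = ""
) -> MetricsReport:
    """The seven-metric bundle from probability scores.

    Predictions are ``score >= threshold``.  AUROC is the Mann-Whitney
    rank statistic (ties count one half); when only one class is present
    it is reported as NaN rather than imputed, and MCC degenerates to 0
    when a denominator factor vanishes.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    yhat = (scores >= threshold).astype(int)
    single_class = len(np.unique(y)) < 2
    auroc = float("nan") if single_class else float(roc_auc_score(y, scores))
    return MetricsReport(
        accuracy=float(accuracy_score(y, yhat)),
        balanced_accuracy=float(balanced_accuracy_score(y, yhat)),
        mcc=float(matthews_corrcoef(y, yhat)),
        auroc=auroc,
        precision=float(precision_score(y, yhat, zero_division=0)),
        recall=float(recall_score(y, yhat, zero_division=0)),
        f1=float(f1_score(y, yhat, zero_division=0)),
        n=len(y),
        scheme=scheme,
        fold=fold,
    )


@dataclass
class EvaluationResult:
    fold_reports: list
    pooled: MetricsReport
    oof_scores: pd.Series  # out-of-fold P(synergistic) per instance
    n_undefined_auroc: int = 0

    def mean_metrics(self) -> dict:
        """Fold-mean of each metric; undefined (NaN) folds excluded."""
        out = {}
        for m in ("accuracy", "balanced_accuracy", "mcc", "auroc",
                  "precision", "recall", "f1"):
            vals = [getattr(r, m) for r in self.fold_reports]
            vals = [v for v in vals if np.isfinite(v)]
            out[m] = float(np.mean(vals)) if vals else float("nan")
        return out


def evaluate_scheme(
    df: pd.DataFrame,
    scheme: CVScheme,
    spec: ModelSpec,
    featurizer: Featurizer = None,
    threshold: float = 0.5,
) -> EvaluationResult:
    """Fit-and-score a model spec under a cross-validation scheme.

    Per-drug feature vectors are cached across folds, so the cost is one
    model fit per fold.  Folds whose test side contains a single class
    get NaN AUROC and are excluded from fold means with a logged count.
    For partition schemes the pooled report covers every instance exactly
    once (pooled n = dataset size).
    """
    if featurizer is None:
        featurizer = Featurizer()
    X, origin = featurizer.pair_matrix(df, augment=False)
    pos = {idx: i for i, idx in enumerate(origin)}
    y = df["label"].to_numpy(dtype=int)
    ypos = {idx: i for i, idx in enumerate(df.index)}

    folds = make_cv_folds(df, scheme)
    reports = []
    oof = pd.Series(np.nan, index=df.index, dtype=float)
    pooled_y, pooled_s = [], []
    n_undef = 0
    for tr_idx, te_idx, fold_id in folds:
        tr = [pos[i] for i in tr_idx]
        te = [pos[i] for i in te_idx]
        model = train_classifier(
            X[tr], y[[ypos[i] for i in tr_idx]], spec,
            feature_names=featurizer.feature_names,
            config_hash=featurizer.config.hash(),
        )
        s = model.predict_proba(X[te])
        yte = y[[ypos[i] for i in te_idx]]
        rep = metric_suite(yte, s, threshold, scheme=scheme.kind, fold=fold_id)
        if not np.isfinite(rep.auroc):
            n_undef += 1
        reports.append(rep)
        pooled_y.extend(yte)
        pooled_s.extend(s)
        if scheme.is_partition:
            oof[te_idx] = s
    pooled = metric_suite(
        np.asarray(pooled_y), np.asarray(pooled_s), threshold,
        scheme=scheme.kind, fold="pooled",
    )
    return EvaluationResult(
        fold_reports=reports,
        pooled=pooled,
        oof_scores=oof,
        n_undefined_auroc=n_undef,
    )


# ---------------------------------------------------------------------------
# Discriminative-feature analysis


def ks_discriminative_features(
    df: pd.DataFrame, featurizer: Featurizer = None
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov screen of pair-level features.

    Per-drug features are aggregated to pair level by summing the two
    drugs' blocks (symmetric, hence order-invariant); for each feature
    the KS D statistic compares its distribution in synergistic vs
    antagonistic instances.  Returns a table ranked by D descending with
    Benjamini-Hochberg adjusted p-values.
    """
    if featurizer is None:
        featurizer = Featurizer()
    if df["label"].nunique() < 2:
        raise ValueError("both classes must be present")
    names = featurizer.config.drug_feature_names()
    rows = np.asarray(
        [
            featurizer.drug_vector(a) + featurizer.drug_vector(b)
            for a, b in zip(df["drug_a_smiles"], df["drug_b_smiles"])
        ]
    )
    y = df["label"].to_numpy(dtype=int)
    stats, pvals = [], []
    for j in range(rows.shape[1]):
        pos, neg = rows[y == 1, j], rows[y == 0, j]
        if np.ptp(rows[:, j]) == 0:  # constant feature: D is 0 by definition
            stats.append(0.0)
            pvals.append(1.0)
            continue
        res = ks_2samp(pos, neg)
        stats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {"feature": names, "D": stats, "p": pvals, "p_adj": p_adj}
    ).sort_values("D", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def wilcoxon_fold_comparison(metrics_a, metrics_b) -> dict:
    """Wilcoxon signed-rank test over paired per-fold metric values."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("need paired per-fold values")
    stat, p = wilcoxon(a, b)
    return {"statistic": float(stat), "p": float(p), "n": len(a)}
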