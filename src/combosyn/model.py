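"""High-level Model/Results interface for synergy classification.

:class:`SynergyModel` is built from a curated synergy table (or a CSV in
that schema) plus a feature configuration; :meth:`SynergyModel.fit`
featurizes, optionally grid-searches and greedy-selects features, trains
the classifier and returns a :class:`SynergyResults` carrying the fitted
estimator, cross-validated performance, the selection trace and the
attribution / risk-profile helpers.  This mirrors the model-object style
of statistical packages: the model owns the data and configuration, the
results object owns the estimates and diagnostics.

Example
-------
>>> from combosyn import simulate, SynergyModel
>>> _, table = simulate.simulate_screen()
>>> res = SynergyModel(table).fit()
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import curation, evaluation, interpret
from .curation import CVScheme
from .features import FeatureConfig, Featurizer
from .modeling import (
    DEFAULT_GRIDS,
    FeatureSelectionTrace,
    ModelSpec,
    TrainedModel,
    grid_search,
    greedy_forward_selection,
    train_classifier,
)

DEFAULT_SPEC = ModelSpec(
    family="extremely_randomized_trees", hyperparameters={"n_estimators": 300}
)


class SynergyModel:
    """A drug-pair synergy classifier bound to a dataset.

    Parameters
    ----------
    data : DataFrame in the synergy-table schema (drug_a_smiles,
        drug_b_smiles, cell_line, tissue, synergy_score and/or label).
        Binarization at the Loewe threshold (default 10) is applied if
        labels are absent.
    feature_config : FeatureConfig, optional
        Signature cutoffs, pharmacophore classes, descriptor manifest and
        pair policy; defaults to the shipped configuration.
    spec : ModelSpec, optional
        Classifier family and hyperparameters (default: extremely
        randomized trees with 300 trees).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_config: FeatureConfig = None,
        spec: ModelSpec = DEFAULT_SPEC,
        threshold: float = curation.SYNERGY_THRESHOLD,
        aggregate: str = "none",
    ):
        self.data = curation.curate_table(data, threshold=threshold, aggregate=aggregate)
        self.config = feature_config if feature_config is not None else FeatureConfig()
        self.spec = spec
        self.featurizer = Featurizer(self.config)
        self._X = None
        self._origin = None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SynergyModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- feature access -----------------------------------------------------

    @property
    def exog(self) -> np.ndarray:
        """The pair feature matrix (training orderings included)."""
        if self._X is None:
            self._X, self._origin = self.featurizer.pair_matrix(self.data)
        return self._X

    @property
    def endog(self) -> np.ndarray:
        if self._origin is None:
            _ = self.exog
        ypos = dict(zip(self.data.index, self.data["label"].astype(int)))
        return np.asarray([ypos[i] for i in self._origin])

    @property
    def feature_names(self) -> list:
        return self.featurizer.feature_names

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        tune: bool = False,
        grid: dict = None,
        select_features: int = None,
        selection_cv: int = 10,
        seed: int = None,
    ) -> "SynergyResults":
        """Train the classifier; optionally tune and select features.

        ``tune=True`` grid-searches the family's grid (default grids are
        documented in :data:`combosyn.modeling.DEFAULT_GRIDS`) by
        stratified 5-fold CV MCC before training.  ``select_features=N``
        runs bottom-up greedy selection (``selection_cv``-fold CV MCC) up
        to N features and trains on the selected subset.
        """
        spec = self.spec
        if seed is not None:
            spec = ModelSpec(spec.family, dict(spec.hyperparameters), seed)
        X, y = self.exog, self.endog
        gs = None
        if tune:
            gs = grid_search(
                X, y, spec.family,
                grid if grid is not None else DEFAULT_GRIDS[spec.family],
                k=5, seed=spec.seed,
            )
            spec = gs.best
        trace = None
        cols = list(range(X.shape[1]))
        names = self.feature_names
        if select_features is not None:
            trace = greedy_forward_selection(
                X, y, spec, feature_names=names,
                k=selection_cv, max_features=select_features, seed=spec.seed,
            )
            name_to_col = {n: j for j, n in enumerate(names)}
            cols = [name_to_col[n] for n in trace.selected]
            names = trace.selected
        model = train_classifier(
            X[:, cols], y, spec, feature_names=names,
            config_hash=self.config.hash(),
        )
        return SynergyResults(
            model=self,
            trained=model,
            selected_columns=cols,
            selection_trace=trace,
            grid_search=gs,
        )

    def evaluate(
        self, scheme: CVScheme = None, spec: ModelSpec = None
    ) -> evaluation.EvaluationResult:
        """Cross-validate the (untuned) spec under a CV scheme."""
        if scheme is None:
            scheme = CVScheme("stratified_kfold", k=5)
        return evaluation.evaluate_scheme(
            self.data, scheme, spec if spec is not None else self.spec,
            featurizer=self.featurizer,
        )

    def nonredundant_split(
        self, test_fraction: float = 0.2, sim_threshold: float = 0.6, seed: int = 0
    ):
        """Butina-cluster the drugs and split without pair-cluster leakage."""
        drugs = set(self.data["drug_a_smiles"]) | set(self.data["drug_b_smiles"])
        clusters = curation.cluster_drugs(
            sorted(drugs), sim_threshold,
            radius=self.config.fp_radius, nbits=self.config.fp_nbits,
        )
        split = curation.nonredundant_split(self.data, clusters, test_fraction, seed)
        return split, clusters


@dataclass
class SynergyResults:
    """Fitted synergy classifier with its diagnostics and attributions."""

    model: SynergyModel
    trained: TrainedModel
    selected_columns: list
    selection_trace: FeatureSelectionTrace = None
    grid_search: object = None
    _cv_cache: dict = field(default_factory=dict, repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.trained.spec

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, pairs) -> np.ndarray:
        """P(synergistic) for a pair table or a single (smiles_a, smiles_b).

        Under the symmetric-augment policy the two orderings are averaged;
        under the canonical policy they produce the same vector anyway.
        """
        if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], str):
            pairs = pd.DataFrame(
                [{"drug_a_smiles": pairs[0], "drug_b_smiles": pairs[1]}]
            )
        fz = self.model.featurizer
        cols = self.selected_columns
        if fz.config.pair_policy == "symmetric-augment":
            fwd, rev = fz.pair_matrix_both_orders(pairs)
            p = 0.5 * (
                self.trained.predict_proba(fwd[:, cols])
                + self.trained.predict_proba(rev[:, cols])
            )
        else:
            X, _ = fz.pair_matrix(pairs, augment=False)
            p = self.trained.predict_proba(X[:, cols])
        return p

    def predict(self, pairs, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(pairs) >= threshold).astype(int)

    # -- diagnostics --------------------------------------------------------

    def cross_validate(self, scheme: CVScheme = None) -> evaluation.EvaluationResult:
        if scheme is None:
            scheme = CVScheme("stratified_kfold", k=5, seed=self.spec.seed)
        key = (scheme.kind, scheme.k, scheme.seed)
        if key not in self._cv_cache:
            self._cv_cache[key] = evaluation.evaluate_scheme(
                self.model.data, scheme, self.spec, featurizer=self.model.featurizer
            )
        return self._cv_cache[key]

    def permutation_importance(self, n_repeats: int = 5, seed: int = 0):
        X = self.model.exog[:, self.selected_columns]
        return interpret.permutation_importance(
            self.trained, X, self.model.endog, n_repeats=n_repeats, seed=seed
        )

    def global_importance(self, seed: int = 0):
        X = self.model.exog[:, self.selected_columns]
        return interpret.global_importance(
            self.trained, X, y=self.model.endog, seed=seed
        )

    def risk_profile(self, feature: str, grid_size: int = 25):
        """Contribution curve for a feature; flat zero if it was not selected."""
        if feature not in self.trained.feature_names:
            if feature in self.model.feature_names:
                j = self.model.feature_names.index(feature)
                vals = self.model.exog[:, j]
                grid = np.linspace(vals.min(), vals.max(), grid_size)
                counts, edges = np.histogram(vals, bins=min(20, max(5, grid_size // 2)))
                return interpret.RiskProfile(
                    feature=feature, grid=grid,
                    contribution=np.zeros_like(grid),
                    histogram=(counts, edges), method="not_selected",
                )
            raise KeyError(f"unknown feature {feature!r}")
        X = self.model.exog[:, self.selected_columns]
        return interpret.risk_profile(self.trained, feature, X, grid_size)

    def ks_discriminative_features(self) -> pd.DataFrame:
        return evaluation.ks_discriminative_features(
            self.model.data, self.model.featurizer
        )

    # -- reporting ----------------------------------------------------------

    def summary(self, cv_scheme: CVScheme = None) -> str:
        cv = self.cross_validate(cv_scheme)
        mean = cv.mean_metrics()
        lines = [
            "Drug-combination synergy classifier",
            "=" * 51,
            f"Model family:        {self.spec.family}",
            f"Hyperparameters:     {self.spec.hyperparameters or 'defaults'}",
            f"Seed:                {self.spec.seed}",
            f"Instances:           {len(self.model.data)}"
            f"  (synergistic: {int(self.model.data['label'].sum())})",
            f"Features used:       {len(self.selected_columns)}"
            f" of {len(self.model.feature_names)}",
            f"Feature-config hash: {self.model.config.hash()}",
            "-" * 51,
            f"CV scheme:           {cv.pooled.scheme} "
            f"({len(cv.fold_reports)} folds)",
            "                     pooled    fold-mean",
        ]
        for m in ("auroc", "mcc", "balanced_accuracy", "precision", "recall", "f1"):
            lines.append(
                f"{m:<21}{getattr(cv.pooled, m):>6.3f}    {mean[m]:>6.3f}"
            )
        if self.selection_trace is not None:
            lines.append("-" * 51)
            lines.append("Greedy selection trace (feature, CV MCC):")
            for name, mcc in self.selection_trace.steps:
                lines.append(f"  {name:<40}{mcc:>6.3f}")
            lines.append(f"  stopped: {self.selection_trace.stopping_reason}")
        return "\n".join(lines)

    def save(self, path):
        self.trained.save(path)
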