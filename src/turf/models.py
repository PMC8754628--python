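"""Random-forest scoring models, statsmodels-style.

Two model classes mirror the two stages of the score:

* :class:`VariantFunctionModel` — the generic stage.  A 500-tree random
  forest over the 15 generic features predicts the probability G that a
  variant is functional in *any* tissue.  ``fit()`` returns a
  :class:`VariantFunctionResults` carrying the fitted forest, the
  feature-importance table (mean decrease of impurity, normalized to sum
  to 1) and a held-out AUROC diagnostic.
* :class:`TissueFunctionModel` — the tissue stage.  A random forest over
  the binary tissue features, fitted with balanced class weights, one
  model per training cell line (positives = that cell line's ASB SNVs,
  controls = the remaining training variants).

:class:`TissueEnsemble` averages the probabilities of six cell-line
results (unweighted mean, order-invariant).  The tissue-specific score is
the product ``S_t = G * T_t`` of the generic probability and the ensemble
tissue probability, so ``0 <= S_t <= G <= 1`` always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split
from statsmodels.iolib.table import SimpleTable

from .asb import TrainingSet
from .features import (
    GENERIC_SCHEMA,
    TISSUE_SCHEMA,
    AnnotationBundle,
    FeatureSchema,
    generic_feature_matrix,
    tissue_feature_matrix,
)
from .genomic import Variant

DEFAULT_N_TREES = 500


class _ForestModelBase:
    """Shared scaffolding for the two forest stages."""

    schema: FeatureSchema
    results_class: type

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[int] | np.ndarray | pd.Series,
        weights: Sequence[float] | np.ndarray | pd.Series | None = None,
        schema: FeatureSchema | None = None,
    ) -> None:
        if schema is not None:
            self.schema = schema
        missing = [c for c in self.schema.columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix missing column(s) {missing}")
        self.features = features.loc[:, list(self.schema.columns)].astype(float)
        self.labels = np.asarray(labels, dtype=int)
        if self.labels.shape[0] != len(self.features):
            raise ValueError("labels and feature matrix differ in length")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("training data contains a single class")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def _forest(self, n_trees: int, seed: int) -> RandomForestClassifier:
        raise NotImplementedError

    def fit(self, n_trees: int = DEFAULT_N_TREES, seed: int = 0, holdout_fraction: float = 0.2):
        """Fit the forest; a stratified hold-out split supplies the AUROC diagnostic."""
        idx = np.arange(len(self.features))
        if 0.0 < holdout_fraction < 1.0:
            train_idx, test_idx = train_test_split(
                idx,
                test_size=holdout_fraction,
                random_state=seed,
                stratify=self.labels,
            )
        else:
            train_idx, test_idx = idx, np.array([], dtype=int)
        forest = self._forest(n_trees, seed)
        sw = None if self.weights is None else self.weights[train_idx]
        forest.fit(self.features.iloc[train_idx], self.labels[train_idx], sample_weight=sw)
        if test_idx.size:
            probs = forest.predict_proba(self.features.iloc[test_idx])[:, 1]
            auroc = float(roc_auc_score(self.labels[test_idx], probs))
            aupr = float(average_precision_score(self.labels[test_idx], probs))
        else:
            auroc = aupr = float("nan")
        importances = pd.Series(
            forest.feature_importances_, index=list(self.schema.columns), name="importance"
        )
        total = importances.sum()
        if total > 0:
            importances = importances / total
        return self.results_class(self, forest, importances, auroc, aupr, seed)


@dataclass
class _ForestResultsBase:
    """Fitted-forest results: estimates, diagnostics and a summary table."""

    model: _ForestModelBase
    forest: RandomForestClassifier
    feature_importances: pd.Series
    holdout_auroc: float
    holdout_aupr: float
    seed: int

    _title = "Random forest results"

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Class-1 probability (raw forest vote fraction, uncalibrated)."""
        X = features.loc[:, list(self.model.schema.columns)].astype(float)
        return self.forest.predict_proba(X)[:, 1]

    def summary(self) -> SimpleTable:
        rows = [
            ["n observations", f"{len(self.model.features)}"],
            ["n positives", f"{int(self.model.labels.sum())}"],
            ["n trees", f"{self.forest.n_estimators}"],
            ["feature schema", self.model.schema.name],
            ["seed", f"{self.seed}"],
            ["held-out AUROC", f"{self.holdout_auroc:.4f}"],
            ["held-out AUPR", f"{self.holdout_aupr:.4f}"],
        ]
        rows += [
            [f"importance[{name}]", f"{val:.4f}"]
            for name, val in self.feature_importances.sort_values(ascending=False).items()
        ]
        return SimpleTable(rows, headers=["", ""], title=self._title)


class VariantFunctionResults(_ForestResultsBase):
    _title = "Generic variant-function model"


class VariantFunctionModel(_ForestModelBase):
    """Generic-stage model: probability a variant is functional in any tissue."""

    schema = GENERIC_SCHEMA
    results_class = VariantFunctionResults

    @classmethod
    def from_training_set(
        cls,
        training: TrainingSet,
        bundle: AnnotationBundle,
        deepsea: Mapping[str, float] | None = None,
    ) -> "VariantFunctionModel":
        """Build the design matrix from a TrainingSet and the pooled bundle.

        Per-example weights follow the training set's equal-thirds negative
        weighting.
        """
        variants = training.positives + [
            v for sub in training.negative_sublists().values() for v in sub
        ]
        X = generic_feature_matrix(variants, bundle, deepsea)
        y = [1] * len(training.positives) + [0] * (len(variants) - len(training.positives))
        w = [training.weights[v.key] for v in variants]
        return cls(X, y, weights=w)

    def _forest(self, n_trees: int, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)


class TissueFunctionResults(_ForestResultsBase):
    _title = "Tissue-specific variant-function model"

    @property
    def cell_line(self) -> str:
        return getattr(self.model, "cell_line", "")


class TissueFunctionModel(_ForestModelBase):
    """Tissue-stage model for one training cell line (balanced class weights)."""

    schema = TISSUE_SCHEMA
    results_class = TissueFunctionResults

    def __init__(self, features, labels, weights=None, schema=None, cell_line: str = ""):
        super().__init__(features, labels, weights=weights, schema=schema)
        self.cell_line = cell_line

    @classmethod
    def from_cell_line(
        cls,
        asb_by_cell_line: Mapping[str, Sequence[Variant]],
        cell_line: str,
        bundles: Mapping[str, AnnotationBundle],
        extra_controls: Sequence[Variant] = (),
        schema: FeatureSchema = TISSUE_SCHEMA,
    ) -> "TissueFunctionModel":
        """Positives = ASB SNVs of ``cell_line``; controls = all other variants.

        Features are extracted from ``bundles[cell_line]`` for every variant
        (the model asks whether a variant looks functional *in this tissue*).
        """
        if cell_line not in asb_by_cell_line:
            raise KeyError(f"unknown cell line {cell_line!r}")
        positives = list(asb_by_cell_line[cell_line])
        controls = [
            v
            for cl, vs in asb_by_cell_line.items()
            if cl != cell_line
            for v in vs
        ] + list(extra_controls)
        variants = positives + controls
        X = tissue_feature_matrix(variants, bundles[cell_line], schema)
        y = [1] * len(positives) + [0] * len(controls)
        return cls(X, y, schema=schema, cell_line=cell_line)

    def _forest(self, n_trees: int, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, class_weight="balanced", n_jobs=1
        )


class TissueEnsemble:
    """Unweighted average of per-cell-line tissue models.

    The ensemble restricts the feature schema to DNase peak + footprint +
    the five widely-assayed histone marks, so it transfers to tissues
    outside the training cell lines.
    """

    def __init__(self, members: Sequence[TissueFunctionResults]) -> None:
        if not members:
            raise ValueError("ensemble needs at least one member")
        schemas = {m.model.schema.name for m in members}
        if len(schemas) != 1:
            raise ValueError(f"ensemble members use mixed schemas: {sorted(schemas)}")
        self.members = list(members)
        self.schema = self.members[0].model.schema

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Mean member probability; invariant to member ordering."""
        probs = np.stack([m.predict(features) for m in self.members])
        return probs.mean(axis=0)


@dataclass
class ScoreTable:
    """Per-variant generic (G), tissue probability (T_t) and score S_t = G*T_t."""

    frame: pd.DataFrame  # index: variant key; columns: generic, {t}_prob, {t}_score
    tissues: tuple[str, ...]

    def generic(self) -> pd.Series:
        return self.frame["generic"]

    def tissue_scores(self) -> pd.DataFrame:
        return self.frame[[f"{t}_score" for t in self.tissues]].rename(
            columns={f"{t}_score": t for t in self.tissues}
        )

    def validate(self) -> None:
        G = self.frame["generic"].to_numpy()
        if np.any((G < 0) | (G > 1)):
            raise AssertionError("generic score outside [0, 1]")
        for t in self.tissues:
            S = self.frame[f"{t}_score"].to_numpy()
            if np.any(S > G + 1e-12) or np.any(S < -1e-12):
                raise AssertionError(f"tissue score bound violated for {t}")


def score_variants(
    variants: Sequence[Variant],
    generic_results: VariantFunctionResults,
    ensemble: TissueEnsemble,
    generic_bundle: AnnotationBundle,
    bundles_by_tissue: Mapping[str, AnnotationBundle],
    deepsea: Mapping[str, float] | None = None,
) -> ScoreTable:
    """Score variants: G from the generic model once, S_t = G * T_t per tissue.

    Tissues without an annotation bundle are skipped (empty mapping entries
    count as missing); the ScoreTable records only scored tissues.
    """
    keys = [v.key for v in variants]
    Xg = generic_feature_matrix(variants, generic_bundle, deepsea)
    G = generic_results.predict(Xg)
    data: dict[str, np.ndarray] = {"generic": G}
    tissues = []
    for tissue, bundle in bundles_by_tissue.items():
        if bundle is None:
            continue
        Xt = tissue_feature_matrix(variants, bundle, ensemble.schema)
        T = ensemble.predict(Xt)
        data[f"{tissue}_prob"] = T
        data[f"{tissue}_score"] = G * T
        tissues.append(tissue)
    table = ScoreTable(pd.DataFrame(data, index=keys), tuple(tissues))
    table.validate()
    return table


def repeated_partition_evaluation(
    features: pd.DataFrame,
    labels: Sequence[int],
    model_factory,
    n_replicates: int = 1000,
    test_fraction: float = 0.2,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated random 4:1 partition evaluation (AUROC / AUPR per replicate).

    ``model_factory(features, labels)`` must return an unfitted model
    object with a ``fit`` method as above.  The replicate count is
    configurable; each replicate draws its own split from the seed stream.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_replicates):
        split_seed = int(rng.integers(0, 2**31 - 1))
        train_idx, test_idx = train_test_split(
            np.arange(len(y)), test_size=test_fraction, random_state=split_seed, stratify=y
        )
        model = model_factory(features.iloc[train_idx], y[train_idx])
        res = model.fit(n_trees=n_trees, seed=split_seed, holdout_fraction=0.0)
        probs = res.predict(features.iloc[test_idx])
        records.append(
            {
                "replicate": rep,
                "auroc": roc_auc_score(y[test_idx], probs),
                "aupr": average_precision_score(y[test_idx], probs),
            }
        )
    return pd.DataFrame(records)
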