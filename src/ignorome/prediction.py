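"""Monte-Carlo cross-validated gradient-boosted regression.

The modeling engine behind every prediction in the package: repeated
random 90/10 train/test splits of the complete-catalog genes, a
300-stage gradient-boosted tree ensemble with Huber loss per split,
out-of-sample predictions pooled per gene by the median, and feature
importances aggregated across randomizations.

Organized as a model / results pair: :class:`MonteCarloRegression` is
built from data and ``fit()`` returns a :class:`MonteCarloResults`
carrying pooled predictions, importances, diagnostics and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.manifold import TSNE

from .containers import FeatureMatrix

__all__ = [
    "ModelSpec",
    "MonteCarloRegression",
    "MonteCarloResults",
    "monte_carlo_fit",
    "importance_summary",
    "reduced_model",
    "augment_features",
    "embed_feature_space",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one Monte-Carlo regression run.

    ``n_randomizations`` defaults to 50 for routine work; full-scale runs
    use at least 400.  Ensemble settings beyond the 300 estimators and
    the Huber loss are the tree implementation's defaults, frozen here so
    every run records them.
    """

    target_name: str = "log10_publications"
    n_randomizations: int = 50
    train_fraction: float = 0.9
    n_estimators: int = 300
    loss: str = "huber"
    learning_rate: float = 0.1
    max_depth: int = 3
    huber_alpha: float = 0.9

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.n_randomizations < 1:
            raise ValueError("need at least one randomization")

    def manifest(self) -> dict:
        return {f: getattr(self, f) for f in (
            "target_name", "n_randomizations", "train_fraction",
            "n_estimators", "loss", "learning_rate", "max_depth",
            "huber_alpha",
        )}


class MonteCarloRegression:
    """Gradient-boosted regression with Monte-Carlo cross-validation.

    Parameters
    ----------
    target : pd.Series
        Per-gene response (e.g. log10 publication count), indexed by
        gene id.
    features : pd.DataFrame
        Per-gene predictors; no missing values allowed (restrict to the
        complete-catalog genes first).
    spec : ModelSpec
    """

    def __init__(self, target: pd.Series, features: pd.DataFrame,
                 spec: ModelSpec | None = None):
        spec = spec or ModelSpec()
        common = target.dropna().index.intersection(features.dropna().index)
        if len(common) < 10:
            raise ValueError("too few genes with complete data")
        self.endog = target.loc[common].astype(float)
        self.exog = features.loc[common].astype(float)
        if self.exog.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.spec = spec

    @classmethod
    def from_feature_matrix(
        cls, features: FeatureMatrix, target: pd.Series,
        spec: ModelSpec | None = None,
        feature_names: Sequence[str] | None = None,
    ) -> "MonteCarloRegression":
        """Build from a FeatureMatrix, using only complete-catalog genes."""
        frame = features.values
        if feature_names is not None:
            missing = set(feature_names) - set(frame.columns)
            if missing:
                raise ValueError(f"unknown features: {sorted(missing)}")
            frame = frame[list(feature_names)]
        complete = frame.index[~frame.isna().any(axis=1)]
        return cls(target, frame.loc[complete], spec)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, target_col: str,
        feature_cols: Sequence[str] | None = None,
        spec: ModelSpec | None = None,
    ) -> "MonteCarloRegression":
        feature_cols = feature_cols or [c for c in data.columns if c != target_col]
        return cls(data[target_col], data[list(feature_cols)], spec)

    def reduced(self, feature_names: Sequence[str]) -> "MonteCarloRegression":
        """The same model restricted to a feature subset."""
        missing = set(feature_names) - set(self.exog.columns)
        if missing:
            raise ValueError(f"unknown features: {sorted(missing)}")
        return MonteCarloRegression(
            self.endog, self.exog[list(feature_names)], self.spec
        )

    def fit(self, seed: int = 0) -> "MonteCarloResults":
        """Run the randomizations and pool out-of-sample predictions."""
        spec = self.spec
        rng = np.random.default_rng(seed)
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        n = len(y)
        n_train = int(round(spec.train_fraction * n))
        preds = np.full((n, spec.n_randomizations), np.nan)
        importances = np.zeros((spec.n_randomizations, X.shape[1]))
        for r in range(spec.n_randomizations):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            est = GradientBoostingRegressor(
                n_estimators=spec.n_estimators,
                loss=spec.loss,
                learning_rate=spec.learning_rate,
                max_depth=spec.max_depth,
                alpha=spec.huber_alpha,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            est.fit(X[train], y[train])
            preds[test, r] = est.predict(X[test])
            imp = est.feature_importances_
            total = imp.sum()
            importances[r] = imp / total if total > 0 else imp
        return MonteCarloResults(self, preds, importances, seed)


class MonteCarloResults:
    """Pooled out-of-sample predictions and importances of a run."""

    def __init__(self, model: MonteCarloRegression, heldout_predictions:
                 np.ndarray, importances: np.ndarray, seed: int):
        self.model = model
        self.seed = seed
        index = model.endog.index
        self._raw = heldout_predictions
        self.n_held_out = pd.Series(
            (~np.isnan(heldout_predictions)).sum(axis=1), index=index,
            name="n_held_out",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pooled = np.nanmedian(heldout_predictions, axis=1)
        self.pooled_predictions = pd.Series(
            pooled, index=index, name="pooled_prediction"
        )
        self.never_held_out = index[self.n_held_out == 0]
        if len(self.never_held_out):
            warnings.warn(
                f"{len(self.never_held_out)} genes never held out; excluded "
                "from evaluation", stacklevel=2,
            )
        self.importances = pd.DataFrame(
            importances, columns=model.exog.columns
        )
        self.importances.index.name = "randomization"

    @property
    def spearman(self) -> float:
        """Spearman rank correlation of pooled predictions vs truth
        (average ranks on ties), over genes held out at least once."""
        ok = self.n_held_out > 0
        return float(stats.spearmanr(
            self.pooled_predictions[ok], self.model.endog[ok]
        ).statistic)

    def median_importance(self) -> pd.Series:
        return self.importances.median(axis=0).sort_values(ascending=False)

    def top_features(self, k: int = 15) -> list[str]:
        med = self.median_importance()
        if k > len(med):
            warnings.warn("k exceeds the number of features; returning all",
                          stacklevel=2)
            k = len(med)
        return list(med.index[:k])

    def summary(self) -> str:
        lines = [
            "Monte-Carlo gradient-boosted regression",
            "=" * 55,
            f"target:            {self.model.spec.target_name}",
            f"genes:             {len(self.model.endog)}",
            f"features:          {self.model.exog.shape[1]}",
            f"randomizations:    {self.model.spec.n_randomizations}"
            f"  (train fraction {self.model.spec.train_fraction})",
            f"estimators / loss: {self.model.spec.n_estimators}"
            f" / {self.model.spec.loss}",
            f"pooled Spearman:   {self.spearman:.3f}",
            f"never held out:    {len(self.never_held_out)}",
            "-" * 55,
            "top features by median importance:",
        ]
        med = self.median_importance()
        for name, value in med.head(10).items():
            lines.append(f"  {name:<30s} {value:.4f}")
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ok = self.n_held_out > 0
        ax.scatter(self.model.endog[ok], self.pooled_predictions[ok], s=4,
                   alpha=0.4)
        ax.set_xlabel(f"observed {self.model.spec.target_name}")
        ax.set_ylabel("pooled out-of-sample prediction")
        ax.set_title(f"Spearman = {self.spearman:.2f}")
        return ax


def monte_carlo_fit(
    features: pd.DataFrame | FeatureMatrix, target: pd.Series,
    spec: ModelSpec | None = None, seed: int = 0,
) -> MonteCarloResults:
    """Fit the Monte-Carlo regression (functional entry point)."""
    if isinstance(features, FeatureMatrix):
        model = MonteCarloRegression.from_feature_matrix(features, target, spec)
    else:
        model = MonteCarloRegression(target, features, spec)
    return model.fit(seed)


def importance_summary(
    result: MonteCarloResults, k: int = 15
) -> dict:
    """Median importances, top-k features and a Ward display ordering.

    Ward linkage is computed over the per-feature importance vectors
    across randomizations (standard display ordering for importance
    heatmaps).
    """
    if result.importances.shape[0] < 2:
        raise ValueError("need at least 2 randomizations")
    med = result.median_importance()
    top = result.top_features(k)
    matrix = result.importances.T  # features x randomizations
    link = linkage(matrix.to_numpy(), method="ward")
    order = [matrix.index[i] for i in leaves_list(link)]
    return {"median_importance": med, "top_features": top,
            "ward_linkage": link, "display_order": order}


def reduced_model(
    features: pd.DataFrame | FeatureMatrix, target: pd.Series,
    top_features: Sequence[str], spec: ModelSpec | None = None, seed: int = 0,
) -> MonteCarloResults:
    """Monte-Carlo fit restricted to the given features.

    Also usable on the wider gene set where only those features are
    defined: genes are filtered on the reduced columns, not the full
    catalog.
    """
    if isinstance(features, FeatureMatrix):
        model = MonteCarloRegression.from_feature_matrix(
            features, target, spec, feature_names=top_features
        )
    else:
        model = MonteCarloRegression(target, features[list(top_features)], spec)
    return model.fit(seed)


def augment_features(
    features: FeatureMatrix,
    additions: pd.DataFrame | None,
    min_disease_genes: int = 10,
    disease_prefix: str = "disease_",
) -> FeatureMatrix:
    """Merge extra predictor columns into a feature matrix.

    Additions may include the human discovery year, per-taxon homolog
    discovery years, homolog single-gene-publication years, homolog
    publication counts, and disease-annotation indicator columns.
    Missing homolog values become -1 (absence of a homolog or of
    publications is informative); disease indicator columns supported by
    fewer than ``min_disease_genes`` genes are removed.  Column-name
    collisions raise.
    """
    if additions is None or additions.shape[1] == 0:
        return features.copy()
    collisions = set(additions.columns) & set(features.values.columns)
    if collisions:
        raise ValueError(f"feature name collisions: {sorted(collisions)}")
    add = additions.reindex(features.gene_ids).copy()
    for col in list(add.columns):
        if col.startswith(disease_prefix):
            if (add[col].fillna(0) != 0).sum() < min_disease_genes:
                add = add.drop(columns=col)
                continue
            add[col] = add[col].fillna(0)
        elif col.startswith("homolog_") or col == "discovery_year":
            add[col] = add[col].fillna(-1.0)
    values = pd.concat([features.values, add], axis=1)
    mask = pd.concat(
        [features.missing, pd.DataFrame(False, index=add.index,
                                        columns=add.columns)], axis=1,
    )
    mask[add.columns] = values[add.columns].isna()
    return FeatureMatrix(values, mask, False, features.constant_features)


def embed_feature_space(
    zscored: pd.DataFrame, seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """2-D t-SNE embedding of a z-scored feature matrix.

    Deterministic under a fixed seed; the caller is expected to persist
    the coordinates so downstream overlays reuse identical maps.
    Features must be z-scored over exactly the genes embedded.
    """
    if zscored.isna().any().any():
        raise ValueError("embedding input must have no missing values")
    perplexity = min(perplexity, max(1.0, (len(zscored) - 1) / 3))
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
              init="pca")
    coords = ts.fit_transform(zscored.to_numpy())
    return pd.DataFrame(coords, index=zscored.index, columns=["tsne_1", "tsne_2"])
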