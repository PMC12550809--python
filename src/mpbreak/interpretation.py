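"""Cross-fold feature importance and Shapley substructure attribution.

The workflow mirrors how the final model is read mechanistically: rank
features by impurity importance averaged across CV folds, optionally retrain
on the top-k features only, then compute additive Shapley attributions of
the fitted values so each substructure's push on predicted breakthrough can
be inspected per molecule.

Attributions are computed on the raw ensemble and rescaled by the
bias-correction slope (an affine map preserves additivity and, for positive
slope, signs), so ``base_value + sum(attributions)`` equals the *adjusted*
fitted value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._treeshap import forest_shap_values
from .descriptors import FingerprintMatrix, maccs_key_description
from .modeling import ModelBundle, train_bundle

logger = logging.getLogger(__name__)


def cv_feature_importance(models: list, feature_names: list[str]) -> pd.DataFrame:
    """Average impurity-based importances over per-fold fitted ensembles.

    Returns a frame with columns ``feature, mean_importance, sd_importance,
    rank`` sorted by rank; per-fold importances follow sklearn's
    normalization (each fold sums to 1).
    """
    if len(models) < 2:
        raise ValueError("need at least two folds of fitted models")
    rows = []
    for m in models:
        if not hasattr(m, "feature_importances_"):
            raise TypeError(f"model {type(m).__name__} has no feature importances")
        imp = np.asarray(m.feature_importances_, dtype=float)
        if len(imp) != len(feature_names):
            raise ValueError("importance length does not match feature names")
        rows.append(imp)
    mat = np.vstack(rows)
    out = pd.DataFrame(
        {
            "feature": feature_names,
            "mean_importance": mat.mean(axis=0),
            "sd_importance": mat.std(axis=0, ddof=1),
        }
    ).sort_values("mean_importance", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


@dataclass
class AttributionTable:
    """Additive per-prediction attributions in adjusted-logB units."""

    substance_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_substances, n_features)
    base_value: float
    fitted: np.ndarray  # adjusted fitted values, for the local-accuracy check

    def check_local_accuracy(self, rtol_scale: float = 1e-6) -> None:
        recon = self.base_value + self.values.sum(axis=1)
        scale = max(1.0, float(np.abs(self.fitted).max()))
        if not np.allclose(recon, self.fitted, atol=rtol_scale * scale):
            raise AssertionError("local accuracy violated: attributions do not sum to fit")

    def to_long_frame(self, presence: np.ndarray | None = None) -> pd.DataFrame:
        """Long export (substance, feature, present, attribution) for plotting."""
        rows = []
        for i, sid in enumerate(self.substance_ids):
            for j, feat in enumerate(self.feature_names):
                rows.append(
                    {
                        "substance_id": sid,
                        "feature": feat,
                        "description": maccs_key_description(feat),
                        "present": int(presence[i, j]) if presence is not None else None,
                        "attribution": float(self.values[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def shap_attributions(bundle: ModelBundle, X: FingerprintMatrix) -> AttributionTable:
    """Shapley attributions of the bundle's fitted values on ``X``.

    Only defined for the final tree ensemble.  Raw-ensemble attributions are
    multiplied by the bias-correction slope and the base shifted by the
    intercept so the table decomposes the adjusted prediction.
    """
    if not isinstance(bundle.ensemble, RandomForestRegressor):
        raise TypeError("Shapley attribution is only supported for the tree ensemble")
    frame = X.to_frame()
    missing = set(bundle.feature_subset) - set(frame.columns)
    if missing:
        raise ValueError(f"input matrix lacks bundle features: {sorted(missing)[:5]}")
    Xa = frame[bundle.feature_subset].to_numpy(dtype=float)
    phi_raw, base_raw = forest_shap_values(bundle.ensemble, Xa)
    raw_pred = bundle.ensemble.predict(Xa)
    table = AttributionTable(
        substance_ids=list(frame.index),
        feature_names=list(bundle.feature_subset),
        values=bundle.bias_slope * phi_raw,
        base_value=bundle.bias_slope * base_raw + bundle.bias_intercept,
        fitted=bundle.bias_slope * raw_pred + bundle.bias_intercept,
    )
    table.check_local_accuracy()
    return table


def mean_attribution_when_present(table: AttributionTable, X: FingerprintMatrix) -> pd.DataFrame:
    """Per-feature mean attribution split by substructure presence/absence."""
    frame = X.to_frame()[table.feature_names]
    present = frame.loc[table.substance_ids].to_numpy(dtype=bool)
    rows = []
    for j, feat in enumerate(table.feature_names):
        on = table.values[present[:, j], j]
        off = table.values[~present[:, j], j]
        rows.append(
            {
                "feature": feat,
                "description": maccs_key_description(feat),
                "n_present": int(present[:, j].sum()),
                "mean_attr_present": float(on.mean()) if on.size else float("nan"),
                "mean_attr_absent": float(off.mean()) if off.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rank_features_by_cv(
    X: FingerprintMatrix,
    y: pd.Series,
    params: dict | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Importance ranking from forests fitted per CV fold (no test leakage)."""
    frame = X.to_frame()
    y = y.loc[frame.index]
    Xa, ya = frame.to_numpy(dtype=float), y.to_numpy(dtype=float)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    models = []
    for train_idx, _ in kf.split(Xa):
        rf = RandomForestRegressor(random_state=seed, n_jobs=1, **(params or {}))
        rf.fit(Xa[train_idx], ya[train_idx])
        models.append(rf)
    return cv_feature_importance(models, list(frame.columns))


def retrain_on_top_features(
    X: FingerprintMatrix,
    y: pd.Series,
    k: int,
    params: dict | None = None,
    seed: int = 0,
    importance: pd.DataFrame | None = None,
) -> ModelBundle:
    """Retrain the bundle on the ``k`` most important features.

    ``importance`` defaults to a fresh cross-fold ranking on (X, y).  The
    bundle records its ``feature_subset`` so prediction on full-width
    matrices auto-slices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.n_bits:
        raise ValueError(f"k={k} exceeds the {X.n_bits} available features")
    if importance is None:
        importance = rank_features_by_cv(X, y, params=params, seed=seed)
    top = importance.sort_values("rank")["feature"].head(k).tolist()
    logger.info("retraining on top-%d features: %s...", k, top[: min(5, k)])
    return train_bundle(X, y, params=params, seed=seed, feature_subset=top,
                        metadata={"top_k": k})
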