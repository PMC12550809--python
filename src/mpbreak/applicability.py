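"""Applicability domain: similarity metrics, confidence and coverage curves.

Per-prediction confidence signals:

- ``similarity_nearest`` / ``similarity_nearest5``: Tanimoto similarity to
  the most similar training molecule, and the mean over the five nearest;
- ``tree_sd``: the standard deviation of the individual tree predictions in
  the ensemble — when the trees disagree, the prediction is less reliable;
- ``confidence``: 1 minus the rank percentile of ``tree_sd`` within the
  tree-SD distribution of the training set (an internal convention: the
  underlying studies report a 0-1 confidence without defining its formula,
  so this mapping is ours and is documented as such).

Coverage curves quantify how the error shrinks as low-confidence
predictions are excluded, and the ideal-model simulation benchmarks any
model against the irreducible experimental variability of the monitoring
data itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score

logger = logging.getLogger(__name__)

#: Retained-fraction grid for coverage curves: 100% down to 10% in 5% steps.
COVERAGE_FRACTIONS = tuple(np.round(np.arange(1.0, 0.0999, -0.05), 2))


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors have an undefined ratio; it is reported as 0.0
    with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"bit-vector length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("Tanimoto of two all-zero vectors defined as 0.0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(queries: np.ndarray, training: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto similarities, queries x training."""
    q = np.asarray(queries, dtype=np.float64)
    t = np.asarray(training, dtype=np.float64)
    if q.ndim != 2 or t.ndim != 2 or q.shape[1] != t.shape[1]:
        raise ValueError("queries and training must be 2-D with equal bit width")
    inter = q @ t.T
    union = q.sum(axis=1)[:, None] + t.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def similarity_profile(query_fp, training_bits) -> tuple[float, float]:
    """(similarity_nearest, similarity_nearest5) of a query to a training set.

    With fewer than five training molecules the nearest-5 average runs over
    what exists (logged).  Ties at the 5th position are broken by value, so
    the result has no dependence on training-set ordering.
    """
    training_bits = np.asarray(training_bits)
    if training_bits.ndim != 2 or len(training_bits) == 0:
        raise ValueError("training fingerprint matrix must be 2-D and non-empty")
    sims = tanimoto_matrix(np.asarray(query_fp)[None, :], training_bits)[0]
    k = min(5, len(sims))
    if k < 5:
        logger.info("nearest5 averaged over only %d training molecules", k)
    top = np.sort(sims)[::-1][:k]
    return float(top[0]), float(top.mean())


def confidence_score(tree_sd: float, training_tree_sd: np.ndarray) -> float:
    """Confidence in [0, 1]: 1 - mid-rank percentile of tree_sd in training.

    ``tree_sd = 0`` (perfect tree agreement) always maps to confidence 1.0;
    a tree_sd at the training median maps to 0.5.  Monotone non-increasing
    in ``tree_sd`` by construction.
    """
    if tree_sd < 0:
        raise ValueError("tree_sd must be >= 0")
    ref = np.asarray(training_tree_sd, dtype=float)
    if ref.size == 0:
        raise ValueError("empty training tree_sd distribution")
    if tree_sd == 0:
        return 1.0
    pct = (np.sum(ref < tree_sd) + 0.5 * np.sum(ref == tree_sd)) / ref.size
    return float(1.0 - pct)


RANKINGS = ("similarity_nearest", "similarity_nearest5", "tree_sd")


def coverage_curve(
    y_true,
    y_pred,
    ranking_values,
    ranking: str = "tree_sd",
) -> pd.DataFrame:
    """RMSE/R² as low-confidence predictions are progressively excluded.

    For similarity rankings the *most similar* predictions are retained;
    for ``tree_sd`` the *lowest*-SD predictions are retained.  Fractions run
    from 100% down to 10% in 5% steps.  Ties at a cutoff keep every tied
    item, so a row's actual fraction can slightly exceed the nominal one
    (both are reported).  The 100% row reproduces the global metrics
    exactly.
    """
    if ranking not in RANKINGS:
        raise ValueError(f"ranking must be one of {RANKINGS}")
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rank_vals = np.asarray(ranking_values, dtype=float)
    n = len(y_true)
    if not (len(y_pred) == len(rank_vals) == n):
        raise ValueError("inputs must be equal length")
    if n < 20:
        raise ValueError("coverage curve needs at least 20 predictions")

    # high rank value = keep first for similarities, last for tree_sd
    keep_high = ranking != "tree_sd"
    order_vals = rank_vals if keep_high else -rank_vals

    rows = []
    for frac in COVERAGE_FRACTIONS:
        k = max(1, int(np.ceil(frac * n)))
        cutoff = np.sort(order_vals)[::-1][k - 1]
        mask = order_vals >= cutoff  # ties at the cutoff are all kept
        yt, yp = y_true[mask], y_pred[mask]
        rows.append(
            {
                "fraction_nominal": float(frac),
                "fraction_actual": float(mask.sum() / n),
                "n": int(mask.sum()),
                "rmse": float(np.sqrt(mean_squared_error(yt, yp))),
                "r2": float(r2_score(yt, yp)) if len(yt) > 1 and np.ptp(yt) > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IdealModelResult:
    mean_r2: float
    median_rmse: float
    per_repeat: pd.DataFrame  # columns: repeat, r2, rmse


def ideal_model_simulation(
    values: pd.DataFrame,
    n_repeats: int = 100,
    seed: int = 0,
    scheme: str = "resample",
) -> IdealModelResult:
    """Simulate a model that predicts within the experimental variability.

    ``values`` is a breakthrough long table (columns ``substance_id``,
    ``plant_id``, ``logB``); only substances with at least two plant-level
    values enter.  Per repeat, each substance's "prediction" is one of its
    observed per-plant logB values drawn uniformly (``scheme="resample"``)
    or a Gaussian draw with the substance's observed mean and SD
    (``scheme="gaussian"``); it is scored against the substance median.
    Returns the mean R² and median RMSE over repeats.
    """
    if scheme not in ("resample", "gaussian"):
        raise ValueError(f"unknown scheme {scheme!r}")
    per_plant = (
        values.groupby(["substance_id", "plant_id"])["logB"].median().reset_index()
    )
    counts = per_plant.groupby("substance_id").size()
    eligible = sorted(counts.index[counts >= 2])
    if not eligible:
        raise ValueError("no substances with >= 2 plant-level values")

    obs = {sid: per_plant.loc[per_plant["substance_id"] == sid, "logB"].to_numpy()
           for sid in eligible}
    medians = np.array([np.median(obs[sid]) for sid in eligible])

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        if scheme == "resample":
            preds = np.array([rng.choice(obs[sid]) for sid in eligible])
        else:
            preds = np.array(
                [rng.normal(np.mean(obs[sid]), np.std(obs[sid], ddof=1)) for sid in eligible]
            )
        rows.append(
            {
                "repeat": rep,
                "r2": float(r2_score(medians, preds)),
                "rmse": float(np.sqrt(mean_squared_error(medians, preds))),
            }
        )
    per_repeat = pd.DataFrame(rows)
    return IdealModelResult(
        mean_r2=float(per_repeat["r2"].mean()),
        median_rmse=float(per_repeat["rmse"].median()),
        per_repeat=per_repeat,
    )
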