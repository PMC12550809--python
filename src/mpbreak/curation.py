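"""Data curation criteria and the combinatorial curation sweep.

Base curation (duplicate merging, influent-below-LOQ rejection, plant-type
restriction) lives in :mod:`mpbreak.structures` and
:mod:`mpbreak.monitoring`; this module implements the five additional
criteria and the sweep that evaluates every on/off combination of them on a
fixed held-out high-confidence pool.

Criteria
--------
I    drop substances with breakthrough values from fewer than ``min_plants``
     treatment plants;
II   drop substances with any breakthrough value above ``max_B``
     (possible analytical artifacts or in-plant formation);
III  drop substances whose cross-plant SD of logB is >= ``max_sd_logB``;
IV   drop individual entries whose effluent is below the LOQ, then
     re-summarize (entry-level, applied before the substance-level criteria);
V    drop substances that sorb strongly (K_OC above threshold) or volatilize
     (Henry constant above threshold), since their removal is not dominated
     by biotransformation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold

from .monitoring import summarize_all

logger = logging.getLogger(__name__)

CRITERIA_NAMES = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class CurationCriteria:
    use_I: bool = False
    min_plants: int = 3
    use_II: bool = False
    max_B: float = 1.2
    use_III: bool = False
    max_sd_logB: float = 0.7
    use_IV: bool = False
    use_V: bool = False
    koc_threshold: float = 4000.0  # L/kg
    henry_threshold: float = 1e-5  # atm*m^3/mol
    # "any": any plant-level B above max_B excludes; "median": only the
    # substance median B is checked
    criterion_ii_basis: str = "any"
    # behaviour for criterion V when a substance has no property row
    missing_property: str = "error"  # or "drop"

    def __post_init__(self):
        for name in ("min_plants", "max_B", "max_sd_logB", "koc_threshold", "henry_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def flags(self) -> tuple[bool, ...]:
        return (self.use_I, self.use_II, self.use_III, self.use_IV, self.use_V)

    @property
    def label(self) -> str:
        on = [n for n, f in zip(CRITERIA_NAMES, self.flags) if f]
        return "+".join(on) if on else "none"


@dataclass(frozen=True)
class PropertyTable:
    """Per-substance K_OC (L/kg) and Henry constant (atm*m^3/mol)."""

    table: pd.DataFrame  # columns: substance_id, koc, henry
    source: str = ""

    def __post_init__(self):
        missing = {"substance_id", "koc", "henry"} - set(self.table.columns)
        if missing:
            raise ValueError(f"property table missing columns: {sorted(missing)}")
        if self.table["substance_id"].duplicated().any():
            raise ValueError("property table has duplicated substance ids")

    def lookup(self, substance_id: str) -> tuple[float, float] | None:
        row = self.table[self.table["substance_id"] == substance_id]
        if row.empty:
            return None
        return float(row["koc"].iloc[0]), float(row["henry"].iloc[0])


def apply_criteria(
    summaries: pd.DataFrame,
    values: pd.DataFrame,
    criteria: CurationCriteria,
    props: PropertyTable | None = None,
    plant_filter: set[str] | None = None,
    aggregation: str = "two_stage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the enabled criteria; returns (curated summaries, audit trail).

    Criterion IV acts on entries first (values with effluent below LOQ are
    dropped and the remaining entries re-summarized with the same
    ``plant_filter``/``aggregation`` used upstream); the substance-level
    criteria then act on the resulting summaries.  The audit trail has one
    row per (substance, fired criterion); every dropped substance appears
    with at least one reason.
    """
    if criteria.use_V and props is None:
        raise ValueError("criterion V requires a property table")

    audit: list[dict] = []
    working = summaries.copy()

    if criteria.use_IV:
        kept_values = values[~values["effluent_below_loq"].astype(bool)]
        resummarized = summarize_all(
            kept_values, plant_filter=plant_filter, aggregation=aggregation
        )
        lost = set(working["substance_id"]) - set(resummarized["substance_id"])
        for sid in sorted(lost):
            audit.append({"substance_id": sid, "criterion": "IV"})
        working = resummarized[resummarized["substance_id"].isin(set(working["substance_id"]))]

    drop: set[str] = set()
    for row in working.itertuples():
        sid = row.substance_id
        if criteria.use_I and row.n_plants < criteria.min_plants:
            audit.append({"substance_id": sid, "criterion": "I"})
            drop.add(sid)
        if criteria.use_II:
            basis = row.max_B if criteria.criterion_ii_basis == "any" else 10.0**row.median_logB
            if basis > criteria.max_B:
                audit.append({"substance_id": sid, "criterion": "II"})
                drop.add(sid)
        if criteria.use_III:
            # substances with undefined SD (single plant) are kept: missing
            # SD is not evidence of high variability
            if np.isfinite(row.sd_logB) and row.sd_logB >= criteria.max_sd_logB:
                audit.append({"substance_id": sid, "criterion": "III"})
                drop.add(sid)
        if criteria.use_V:
            assert props is not None
            props_row = props.lookup(sid)
            if props_row is None:
                if criteria.missing_property == "error":
                    raise KeyError(f"criterion V: no property row for substance {sid!r}")
                audit.append({"substance_id": sid, "criterion": "V-missing"})
                drop.add(sid)
            else:
                koc, henry = props_row
                if koc > criteria.koc_threshold or henry > criteria.henry_threshold:
                    audit.append({"substance_id": sid, "criterion": "V"})
                    drop.add(sid)

    curated = working[~working["substance_id"].isin(drop)].reset_index(drop=True)
    audit_df = pd.DataFrame(audit, columns=["substance_id", "criterion"])
    logger.info(
        "curation %s: %d -> %d substances", criteria.label, len(summaries), len(curated)
    )
    return curated, audit_df


def all_combinations(base: CurationCriteria | None = None) -> list[CurationCriteria]:
    """All 32 on/off combinations of criteria I-V, thresholds from ``base``."""
    base = base or CurationCriteria()
    combos = []
    for flags in itertools.product([False, True], repeat=5):
        combos.append(
            replace(base, use_I=flags[0], use_II=flags[1], use_III=flags[2],
                    use_IV=flags[3], use_V=flags[4])
        )
    return combos


@dataclass
class SweepResult:
    report: pd.DataFrame = field(default_factory=pd.DataFrame)
    pool_ids: list[str] = field(default_factory=list)
    fold_assignment: dict[str, int] = field(default_factory=dict)


def criteria_sweep(
    summaries: pd.DataFrame,
    values: pd.DataFrame,
    features: pd.DataFrame,
    model_factory,
    props: PropertyTable | None = None,
    n_folds: int = 5,
    seed: int = 0,
    base: CurationCriteria | None = None,
    plant_filter: set[str] | None = None,
    aggregation: str = "two_stage",
) -> SweepResult:
    """Evaluate every criteria combination on a fixed high-confidence pool.

    The pool is the set surviving *all* criteria; it is split into
    ``n_folds`` disjoint test folds used only for evaluation.  For each of
    the 32 combinations, a fresh model from ``model_factory()`` is trained
    on the combination's curated data minus the test fold and scored on the
    fold (targets for test substances always come from the pool summaries).
    Pool substances in a test fold never enter that fold's training set.

    ``features`` is a numeric matrix indexed by substance_id.  Combinations
    yielding an empty training set report NaN metrics.
    """
    base = base or CurationCriteria()
    strictest = replace(base, use_I=True, use_II=True, use_III=True, use_IV=True, use_V=True)
    pool, _ = apply_criteria(
        summaries, values, strictest, props, plant_filter=plant_filter, aggregation=aggregation
    )
    pool = pool[pool["substance_id"].isin(features.index)]
    pool_ids = sorted(pool["substance_id"])
    if len(pool_ids) < n_folds:
        raise ValueError(f"pool of {len(pool_ids)} substances too small for {n_folds} folds")

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignment: dict[str, int] = {}
    folds: list[list[str]] = []
    for fold_idx, (_, test_idx) in enumerate(kf.split(pool_ids)):
        fold = [pool_ids[i] for i in test_idx]
        folds.append(fold)
        for sid in fold:
            fold_assignment[sid] = fold_idx

    pool_y = pool.set_index("substance_id")["median_logB"]

    rows = []
    for combo in all_combinations(base):
        curated, _ = apply_criteria(
            summaries, values, combo, props, plant_filter=plant_filter, aggregation=aggregation
        )
        curated = curated[curated["substance_id"].isin(features.index)]
        curated_y = curated.set_index("substance_id")["median_logB"]
        r2s, rmses, sizes = [], [], []
        for fold in folds:
            test_ids = fold
            train_ids = [sid for sid in curated_y.index if sid not in set(test_ids)]
            assert set(train_ids).isdisjoint(test_ids)  # leakage guard
            if not train_ids:
                r2s.append(np.nan)
                rmses.append(np.nan)
                sizes.append(0)
                continue
            model = model_factory()
            model.fit(features.loc[train_ids].to_numpy(), curated_y.loc[train_ids].to_numpy())
            pred = model.predict(features.loc[test_ids].to_numpy())
            truth = pool_y.loc[test_ids].to_numpy()
            r2s.append(r2_score(truth, pred))
            rmses.append(float(np.sqrt(mean_squared_error(truth, pred))))
            sizes.append(len(train_ids))
        rows.append(
            {
                "combination": combo.label,
                "use_I": combo.use_I,
                "use_II": combo.use_II,
                "use_III": combo.use_III,
                "use_IV": combo.use_IV,
                "use_V": combo.use_V,
                "n_train": float(np.mean(sizes)),
                "mean_R2": float(np.mean(r2s)) if not np.all(np.isnan(r2s)) else np.nan,
                "mean_RMSE": float(np.mean(rmses)) if not np.all(np.isnan(rmses)) else np.nan,
            }
        )
    return SweepResult(report=pd.DataFrame(rows), pool_ids=pool_ids,
                       fold_assignment=fold_assignment)
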