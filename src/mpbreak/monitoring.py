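"""Monitoring data model, breakthrough computation and aggregation.

Breakthrough for one record is the effluent/influent concentration ratio

    B = c_effluent / c_influent

and the modeling target is its base-10 logarithm, aggregated per substance
as the median across treatment plants.  Records whose influent is below the
limit of quantification are rejected outright; effluent values below the LOQ
are used as measured but flagged, so the flag can drive entry-level curation
later.

The per-substance endpoint uses two-stage aggregation by default: median of
a plant's replicate records first, then the median across plants.  A flat
median over all records is available via ``aggregation="flat"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "substance_id",
    "plant_id",
    "dataset_id",
    "c_influent",
    "c_effluent",
    "influent_below_loq",
    "effluent_below_loq",
]


@dataclass(frozen=True)
class MonitoringRecord:
    substance_id: str
    plant_id: str
    dataset_id: str
    c_influent: float
    c_effluent: float
    influent_below_loq: bool = False
    effluent_below_loq: bool = False


@dataclass(frozen=True)
class PlantMeta:
    plant_id: str
    n_eliminating: bool
    country: str | None = None


@dataclass(frozen=True)
class BreakthroughValue:
    substance_id: str
    plant_id: str
    dataset_id: str
    B: float
    logB: float
    effluent_below_loq: bool = False


@dataclass(frozen=True)
class SubstanceSummary:
    substance_id: str
    median_logB: float
    n_plants: int
    sd_logB: float  # NaN when n_plants < 2
    max_B: float
    any_effluent_below_loq: bool


@dataclass(frozen=True)
class Rejection:
    substance_id: str
    plant_id: str
    dataset_id: str
    reason: str


def compute_breakthrough(
    record: MonitoringRecord, zero_effluent_floor: float | None = None
) -> BreakthroughValue | Rejection:
    """Compute B and logB for one record, or reject it with a reason.

    Rejection reasons: ``"influent below LOQ"`` and ``"zero effluent"``.
    ``zero_effluent_floor``, if given, substitutes that value for a zero
    effluent concentration instead of rejecting (off by default: measured
    values are used as-is, never imputed).
    """
    if record.c_influent <= 0:
        raise ValueError(f"c_influent must be > 0, got {record.c_influent}")
    if record.c_effluent < 0:
        raise ValueError(f"c_effluent must be >= 0, got {record.c_effluent}")

    if record.influent_below_loq:
        return Rejection(
            record.substance_id, record.plant_id, record.dataset_id, "influent below LOQ"
        )
    c_eff = record.c_effluent
    if c_eff == 0:
        if zero_effluent_floor is None:
            return Rejection(
                record.substance_id, record.plant_id, record.dataset_id, "zero effluent"
            )
        c_eff = zero_effluent_floor
    b = c_eff / record.c_influent
    return BreakthroughValue(
        substance_id=record.substance_id,
        plant_id=record.plant_id,
        dataset_id=record.dataset_id,
        B=b,
        logB=math.log10(b),
        effluent_below_loq=record.effluent_below_loq,
    )


def compute_breakthrough_table(
    records: pd.DataFrame, zero_effluent_floor: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vector version of :func:`compute_breakthrough` over a records table.

    Returns ``(values, rejections)``; the row counts sum to ``len(records)``.
    """
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    values, rejections = [], []
    for row in records.itertuples():
        rec = MonitoringRecord(
            substance_id=str(row.substance_id),
            plant_id=str(row.plant_id),
            dataset_id=str(row.dataset_id),
            c_influent=float(row.c_influent),
            c_effluent=float(row.c_effluent),
            influent_below_loq=bool(row.influent_below_loq),
            effluent_below_loq=bool(row.effluent_below_loq),
        )
        out = compute_breakthrough(rec, zero_effluent_floor=zero_effluent_floor)
        (values if isinstance(out, BreakthroughValue) else rejections).append(out)
    values_df = pd.DataFrame(
        [v.__dict__ for v in values],
        columns=["substance_id", "plant_id", "dataset_id", "B", "logB", "effluent_below_loq"],
    )
    rej_df = pd.DataFrame(
        [r.__dict__ for r in rejections],
        columns=["substance_id", "plant_id", "dataset_id", "reason"],
    )
    return values_df, rej_df


def summarize_substance(
    values: list[BreakthroughValue],
    plant_filter: set[str] | None = None,
    aggregation: str = "two_stage",
) -> SubstanceSummary | None:
    """Aggregate one substance's breakthrough values to its endpoint.

    ``plant_filter`` restricts to the given plant ids (e.g. the N-eliminating
    plants).  Returns ``None`` when nothing survives the filter.
    """
    if not values:
        return None
    sids = {v.substance_id for v in values}
    if len(sids) != 1:
        raise ValueError(f"values mix substance ids: {sorted(sids)}")
    if plant_filter is not None:
        values = [v for v in values if v.plant_id in plant_filter]
    if not values:
        logger.info("substance %s: no values after plant filter", sids.pop())
        return None

    if aggregation == "two_stage":
        per_plant_log: dict[str, float] = {}
        per_plant_maxb: dict[str, float] = {}
        for pid in {v.plant_id for v in values}:
            plant_vals = [v for v in values if v.plant_id == pid]
            per_plant_log[pid] = float(np.median([v.logB for v in plant_vals]))
            per_plant_maxb[pid] = max(v.B for v in plant_vals)
        log_values = np.array(list(per_plant_log.values()))
        max_b = max(per_plant_maxb.values())
        n_plants = len(per_plant_log)
    elif aggregation == "flat":
        log_values = np.array([v.logB for v in values])
        max_b = max(v.B for v in values)
        n_plants = len({v.plant_id for v in values})
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    return SubstanceSummary(
        substance_id=values[0].substance_id,
        median_logB=float(np.median(log_values)),
        n_plants=n_plants,
        sd_logB=float(np.std(log_values, ddof=1)) if len(log_values) >= 2 else float("nan"),
        max_B=float(max_b),
        any_effluent_below_loq=any(v.effluent_below_loq for v in values),
    )


def summarize_all(
    values: pd.DataFrame,
    plant_filter: set[str] | None = None,
    aggregation: str = "two_stage",
) -> pd.DataFrame:
    """Per-substance summaries for a breakthrough values table."""
    rows = []
    for sid, grp in values.groupby("substance_id", sort=True):
        vals = [
            BreakthroughValue(
                substance_id=str(sid),
                plant_id=str(r.plant_id),
                dataset_id=str(r.dataset_id),
                B=float(r.B),
                logB=float(r.logB),
                effluent_below_loq=bool(r.effluent_below_loq),
            )
            for r in grp.itertuples()
        ]
        summ = summarize_substance(vals, plant_filter=plant_filter, aggregation=aggregation)
        if summ is not None:
            rows.append(summ.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "substance_id",
            "median_logB",
            "n_plants",
            "sd_logB",
            "max_B",
            "any_effluent_below_loq",
        ],
    )


def n_eliminating_plants(plant_meta: pd.DataFrame) -> set[str]:
    """Plant ids flagged as having a nitrifying-denitrifying step."""
    missing = {"plant_id", "n_eliminating"} - set(plant_meta.columns)
    if missing:
        raise ValueError(f"plant metadata missing columns: {sorted(missing)}")
    mask = plant_meta["n_eliminating"].astype(bool)
    return set(plant_meta.loc[mask, "plant_id"].astype(str))


def batch_effect_check(values: pd.DataFrame, min_per_dataset: int = 3) -> dict:
    """Compare between-substance and between-dataset variability of logB.

    Only substances with at least ``min_per_dataset`` values in each of two
    or more datasets are eligible.  For each eligible substance the report
    lists the within-dataset (pooled) and between-dataset variance of its
    logB values.  The pooled decomposition uses one-way method-of-moments
    components: the between-substance component comes from a one-way layout
    with substance as the factor, and the between-dataset component from a
    one-way layout with dataset as the factor after centering each
    substance's values on its own mean (so the substance signal does not
    masquerade as a dataset effect).

    Returns a dict with keys ``n_eligible``, ``per_substance`` (DataFrame),
    ``var_between_substances`` and ``var_between_datasets``.
    """
    counts = values.groupby(["substance_id", "dataset_id"]).size().unstack(fill_value=0)
    eligible = counts.index[((counts >= min_per_dataset).sum(axis=1)) >= 2]
    if len(eligible) == 0:
        logger.info("batch-effect check: no eligible substances")
        return {
            "n_eligible": 0,
            "per_substance": pd.DataFrame(
                columns=["substance_id", "within_dataset_var", "between_dataset_var"]
            ),
            "var_between_substances": float("nan"),
            "var_between_datasets": float("nan"),
        }

    sub = values[values["substance_id"].isin(eligible)].copy()
    # drop sparse substance x dataset cells so groups meet the minimum
    sub = sub.groupby(["substance_id", "dataset_id"]).filter(lambda g: len(g) >= min_per_dataset)

    rows = []
    for sid, grp in sub.groupby("substance_id"):
        by_ds = grp.groupby("dataset_id")["logB"]
        within = float(np.mean([v.var(ddof=1) for _, v in by_ds]))
        between = float(by_ds.mean().var(ddof=1))
        rows.append(
            {"substance_id": sid, "within_dataset_var": within, "between_dataset_var": between}
        )
    per_substance = pd.DataFrame(rows)

    var_sub = _oneway_between_component(sub, "substance_id")
    centered = sub.copy()
    centered["logB"] = centered["logB"] - centered.groupby("substance_id")["logB"].transform(
        "mean"
    )
    var_ds = _oneway_between_component(centered, "dataset_id")
    return {
        "n_eligible": int(len(eligible)),
        "per_substance": per_substance,
        "var_between_substances": var_sub,
        "var_between_datasets": var_ds,
    }


def _oneway_between_component(values: pd.DataFrame, factor: str) -> float:
    """Method-of-moments between-group variance component, one-way layout.

    sigma_b^2 = (MSB - MSW) / n0 with n0 = (N - sum n_i^2 / N) / (k - 1);
    negative estimates are truncated to zero.
    """
    groups = [g["logB"].to_numpy() for _, g in values.groupby(factor)]
    k = len(groups)
    if k < 2:
        return float("nan")
    n = np.array([len(g) for g in groups], dtype=float)
    total_n = n.sum()
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(n * (np.array([g.mean() for g in groups]) - grand) ** 2))
    ssw = float(np.sum([np.sum((g - g.mean()) ** 2) for g in groups]))
    msb = ssb / (k - 1)
    msw = ssw / (total_n - k) if total_n > k else 0.0
    n0 = (total_n - float(np.sum(n**2)) / total_n) / (k - 1)
    return max(0.0, (msb - msw) / n0)
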