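import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from mpbreak.curation import (
    CurationCriteria,
    PropertyTable,
    all_combinations,
    apply_criteria,
    criteria_sweep,
)
from mpbreak.descriptors import FingerprintKind, compute_fingerprints
from mpbreak.monitoring import compute_breakthrough_table, n_eliminating_plants, summarize_all

from conftest import make_values_frame

ALL_ON = CurationCriteria(use_I=True, use_II=True, use_III=True, use_IV=True, use_V=True)


def _summaries(values):
    return summarize_all(values)


class TestCriteriaDefaults:
    def test_defaults_match_documented_thresholds(self):
        c = CurationCriteria()
        assert c.min_plants == 3
        assert c.max_B == pytest.approx(1.2)
        assert c.max_sd_logB == pytest.approx(0.7)
        assert c.koc_threshold == pytest.approx(4000.0)
        assert c.henry_threshold == pytest.approx(1e-5)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            CurationCriteria(min_plants=0)

    def test_labels(self):
        assert CurationCriteria().label == "none"
        assert ALL_ON.label == "I+II+III+IV+V"


class TestApplyCriteria:
    def test_hand_enumerated_fixture(self, curation_fixture):
        values, props_df = curation_fixture
        summaries = _summaries(values)
        props = PropertyTable(table=props_df)
        curated, audit = apply_criteria(summaries, values, ALL_ON, props)

        assert sorted(curated["substance_id"]) == ["sub01", "sub08"]
        reasons = audit.groupby("substance_id")["criterion"].apply(set).to_dict()
        assert reasons["sub02"] == {"I"}
        assert reasons["sub03"] == {"II"}
        assert reasons["sub04"] == {"III"}
        assert reasons["sub05"] == {"IV"}
        assert reasons["sub06"] == {"V"}
        assert reasons["sub07"] == {"V"}
        assert reasons["sub09"] == {"I"}
        assert reasons["sub10"] == {"II", "III"}

    def test_audit_covers_every_dropped_substance(self, curation_fixture):
        values, props_df = curation_fixture
        summaries = _summaries(values)
        curated, audit = apply_criteria(summaries, values, ALL_ON, PropertyTable(table=props_df))
        dropped = set(summaries["substance_id"]) - set(curated["substance_id"])
        assert dropped == set(audit["substance_id"])

    def test_min_plants_boundary(self, curation_fixture):
        values, _ = curation_fixture
        summaries = _summaries(values)
        curated, audit = apply_criteria(summaries, values, CurationCriteria(use_I=True))
        assert "sub02" not in set(curated["substance_id"])  # 2 plants < 3
        assert "sub03" in set(curated["substance_id"])  # exactly 3 plants kept

    def test_criterion_iii_keeps_missing_sd(self, curation_fixture):
        values, _ = curation_fixture
        summaries = _summaries(values)
        curated, _ = apply_criteria(summaries, values, CurationCriteria(use_III=True))
        assert "sub09" in set(curated["substance_id"])  # single plant, SD undefined

    def test_criterion_ii_median_basis_switch(self, curation_fixture):
        values, _ = curation_fixture
        summaries = _summaries(values)
        # sub03 has one B=1.3 entry but median well below 1.2
        any_basis, _ = apply_criteria(summaries, values, CurationCriteria(use_II=True))
        med_basis, _ = apply_criteria(
            summaries, values, CurationCriteria(use_II=True, criterion_ii_basis="median")
        )
        assert "sub03" not in set(any_basis["substance_id"])
        assert "sub03" in set(med_basis["substance_id"])

    def test_criterion_iv_resummarizes_entries(self):
        rows = [
            ("a", "p1", "D0", -1.0, False),
            ("a", "p2", "D0", -1.2, False),
            ("a", "p3", "D0", 0.5, True),  # suspicious entry below effluent LOQ
        ]
        values = make_values_frame(rows)
        summaries = _summaries(values)
        curated, _ = apply_criteria(summaries, values, CurationCriteria(use_IV=True))
        assert curated.loc[0, "median_logB"] == pytest.approx(-1.1)
        assert curated.loc[0, "n_plants"] == 2

    def test_use_v_without_props_raises(self, curation_fixture):
        values, _ = curation_fixture
        with pytest.raises(ValueError, match="criterion V"):
            apply_criteria(_summaries(values), values, CurationCriteria(use_V=True))

    def test_missing_property_row_error_or_drop(self, curation_fixture):
        values, props_df = curation_fixture
        summaries = _summaries(values)
        props = PropertyTable(table=props_df[props_df["substance_id"] != "sub01"])
        with pytest.raises(KeyError, match="sub01"):
            apply_criteria(summaries, values, CurationCriteria(use_V=True), props)
        lenient = CurationCriteria(use_V=True, missing_property="drop")
        curated, audit = apply_criteria(summaries, values, lenient, props)
        assert "sub01" not in set(curated["substance_id"])
        fired = audit[audit["substance_id"] == "sub01"]["criterion"].tolist()
        assert fired == ["V-missing"]

    def test_no_criteria_is_identity(self, curation_fixture):
        values, _ = curation_fixture
        summaries = _summaries(values)
        curated, audit = apply_criteria(summaries, values, CurationCriteria())
        pd.testing.assert_frame_equal(curated, summaries)
        assert audit.empty


def test_all_combinations_cover_32():
    combos = all_combinations()
    assert len(combos) == 32
    assert len({c.flags for c in combos}) == 32


@pytest.fixture(scope="module")
def sweep_inputs():
    from mpbreak.synthetic import GeneratorConfig, generate_all

    cfg = GeneratorConfig(n_substances=70, n_plants=16, seed=21, loq_quantile=0.08,
                          artifact_rate=0.05)
    data = generate_all(cfg)
    values, _ = compute_breakthrough_table(data.records)
    plant_filter = n_eliminating_plants(data.plant_meta)
    summaries = summarize_all(values, plant_filter=plant_filter)
    keep = set(summaries["substance_id"])
    structures = [s for s in data.structures if s.substance_id in keep]
    fps = compute_fingerprints(structures, FingerprintKind.MACCS)
    return summaries, values, fps.to_frame(), data.props, plant_filter


class TestCriteriaSweep:
    def test_sweep_report_properties(self, sweep_inputs):
        summaries, values, features, props, plant_filter = sweep_inputs
        result = criteria_sweep(
            summaries, values, features,
            model_factory=lambda: RandomForestRegressor(n_estimators=15, random_state=0),
            props=props, seed=3, plant_filter=plant_filter,
        )
        report = result.report
        assert len(report) == 32

        # filters only remove: "none" has the largest, "all on" the smallest size
        by_combo = report.set_index("combination")["n_train"]
        assert by_combo["none"] == by_combo.max()
        assert by_combo["I+II+III+IV+V"] == by_combo.min()

        # adding criteria to any fixed combination never increases n_train
        flags = report[["use_I", "use_II", "use_III", "use_IV", "use_V"]].to_numpy(bool)
        sizes = report["n_train"].to_numpy()
        for i in range(len(report)):
            for j in range(len(report)):
                if (flags[i] | flags[j] == flags[j]).all():  # i subset of j
                    assert sizes[j] <= sizes[i] + 1e-9

        # 5 disjoint test folds of ~1/5 of the pool each
        fold_sizes = pd.Series(result.fold_assignment).value_counts()
        assert len(fold_sizes) == 5
        assert fold_sizes.max() - fold_sizes.min() <= 1
        assert set(result.fold_assignment) == set(result.pool_ids)

    def test_dropping_criterion_iv_not_harmful(self, sweep_inputs):
        """Paired comparison over seeds: IV off does not degrade beyond noise."""
        summaries, values, features, props, plant_filter = sweep_inputs
        from sklearn.metrics import mean_squared_error
        from sklearn.model_selection import KFold

        base = CurationCriteria(use_I=True, use_III=True)
        with_iv = CurationCriteria(use_I=True, use_III=True, use_IV=True)
        diffs = []
        pool, _ = apply_criteria(summaries, values, ALL_ON, PropertyTable(table=props.table),
                                 plant_filter=plant_filter)
        pool = pool[pool["substance_id"].isin(features.index)]
        pool_y = pool.set_index("substance_id")["median_logB"]
        for seed in range(10):
            kf = KFold(5, shuffle=True, random_state=seed)
            pool_ids = sorted(pool_y.index)
            fold_rmse = {"with": [], "without": []}
            for _, test_idx in kf.split(pool_ids):
                test_ids = [pool_ids[i] for i in test_idx]
                for tag, crit in (("without", base), ("with", with_iv)):
                    curated, _ = apply_criteria(summaries, values, crit,
                                                plant_filter=plant_filter)
                    curated = curated[curated["substance_id"].isin(features.index)]
                    train = curated[~curated["substance_id"].isin(test_ids)]
                    rf = RandomForestRegressor(n_estimators=15, random_state=seed)
                    rf.fit(features.loc[train["substance_id"]],
                           train.set_index("substance_id")["median_logB"])
                    pred = rf.predict(features.loc[test_ids])
                    fold_rmse[tag].append(
                        np.sqrt(mean_squared_error(pool_y.loc[test_ids], pred))
                    )
            diffs.append(np.mean(fold_rmse["without"]) - np.mean(fold_rmse["with"]))
        assert np.mean(diffs) < 0.1  # dropping IV costs less than 0.1 log units RMSE
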