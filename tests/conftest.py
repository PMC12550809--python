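import numpy as np
import pandas as pd
import pytest

from mpbreak.descriptors import FingerprintKind, compute_fingerprints
from mpbreak.monitoring import compute_breakthrough_table, n_eliminating_plants, summarize_all
from mpbreak.synthetic import GeneratorConfig, generate_all


@pytest.fixture(scope="session")
def small_campaign():
    """An 80-substance synthetic campaign shared by read-only tests."""
    cfg = GeneratorConfig(n_substances=80, n_plants=12, seed=11)
    return generate_all(cfg)


@pytest.fixture(scope="session")
def small_modeling_data(small_campaign):
    """(fps, y, summaries, values) for the small campaign, MACCS features."""
    data = small_campaign
    values, _ = compute_breakthrough_table(data.records)
    plant_filter = n_eliminating_plants(data.plant_meta)
    summaries = summarize_all(values, plant_filter=plant_filter)
    keep = set(summaries["substance_id"])
    structures = [s for s in data.structures if s.substance_id in keep and s.valid]
    fps = compute_fingerprints(structures, FingerprintKind.MACCS)
    y = summaries.set_index("substance_id")["median_logB"].loc[fps.substance_ids]
    return fps, y, summaries, values


def make_values_frame(rows):
    """Long breakthrough table from (sid, plant, dataset, logB, eff_below_loq)."""
    return pd.DataFrame(
        [
            {
                "substance_id": sid,
                "plant_id": plant,
                "dataset_id": ds,
                "B": 10.0**logb,
                "logB": logb,
                "effluent_below_loq": below,
            }
            for sid, plant, ds, logb, below in rows
        ]
    )


@pytest.fixture
def curation_fixture():
    """Ten substances with designed violations of each criterion I-V.

    Hand-enumerated expectations (criteria all on, defaults):
      sub01 clean            -> survives
      sub02 two plants       -> I
      sub03 max B = 1.3      -> II
      sub04 sd(logB) = 0.9   -> III
      sub05 all entries below effluent LOQ -> IV
      sub06 K_OC = 5000      -> V
      sub07 H = 1e-3         -> V
      sub08 clean            -> survives
      sub09 single plant     -> I (kept under III alone: SD missing)
      sub10 max B = 1.25 and sd ~0.95 -> II and III
    """
    rows = []
    def add(sid, logbs, below=False):
        for i, lb in enumerate(logbs):
            rows.append((sid, f"p{i+1}", "D0", lb, below))

    add("sub01", [-1.0, -0.9, -1.1, -0.8, -1.2])
    add("sub02", [-1.0, -1.0])
    add("sub03", [np.log10(1.3), -1.0, -1.0])
    add("sub04", [-2.0, -1.1, -0.2])
    add("sub05", [-1.0, -1.0, -1.0], below=True)
    add("sub06", [-1.0, -1.0, -1.0])
    add("sub07", [-1.0, -1.0, -1.0])
    add("sub08", [-0.5, -0.6, -0.4, -0.55])
    add("sub09", [-1.0])
    add("sub10", [np.log10(1.25), -1.6, -1.5])
    values = make_values_frame(rows)

    props = pd.DataFrame(
        {
            "substance_id": [f"sub{i:02d}" for i in range(1, 11)],
            "koc": [100.0] * 5 + [5000.0] + [100.0] * 4,
            "henry": [1e-8] * 6 + [1e-3] + [1e-8] * 3,
        }
    )
    return values, props
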