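"""Synthetic monitoring campaigns with planted structure-breakthrough signal.

Everything downstream (curation, featurization, modeling, attribution) is
testable offline against known ground truth: structures are assembled from a
small fragment library with controlled presence of halogen, hydroxyl and
ring moieties, each of which shifts the substance's true logB additively;
monitoring records add per-plant noise, per-campaign offsets, LOQ censoring,
occasional >120% breakthrough artifacts, and a shift for plants without a
nitrogen-eliminating step.

Decoy fragments (ester, nitrile, amine, ether, methyl branches) diversify
the chemistry without touching the planted effects, and are chosen so the
flag semantics stay crisp: esters are used instead of carboxylic acids so
the hydroxyl flag is equivalent to an O-H substructure match.

The generative R² ceiling — the score of an oracle predicting each
substance's true logB — is computable from the emitted ground truth and
bounds any model's achievable performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import PropertyTable
from .structures import ChemicalStructure, standardize_structure

FRAGMENT_FLAGS = ("halogen", "hydroxyl", "ring", "ester", "nitrile", "amine", "ether")


@dataclass
class GeneratorConfig:
    n_substances: int = 300
    n_plants: int = 10
    n_eliminating_fraction: float = 0.8
    n_datasets: int = 4
    overlap_fraction: float = 0.3  # substances present in a second campaign
    effects: dict = field(
        default_factory=lambda: {"halogen": 0.5, "hydroxyl": -0.4, "ring": 0.2}
    )
    fragment_probs: dict = field(
        default_factory=lambda: {
            "halogen": 0.5, "hydroxyl": 0.5, "ring": 0.4,
            "ester": 0.3, "nitrile": 0.2, "amine": 0.3, "ether": 0.3,
        }
    )
    baseline_logB: float = -1.0
    logB_cap: float = 0.3
    plant_sd: float = 0.3
    dataset_offset_sd: float = 0.1
    loq_quantile: float = 0.05
    artifact_rate: float = 0.02
    c_plant_shift: float = 0.3  # extra logB at plants without N elimination
    sorbing_fraction: float = 0.05
    volatile_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_eliminating_fraction", "overlap_fraction", "loq_quantile",
                     "artifact_rate", "sorbing_fraction", "volatile_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("plant_sd", "dataset_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_BRANCH_SMILES = {
    "hydroxyl": "O",
    "ester": "C(=O)OC",
    "nitrile": "C#N",
    "amine": "N",
    "ether": "OC",
}


def _assemble_smiles(flags: dict[str, bool], rng: np.random.Generator) -> str:
    """Build a valid SMILES carrying exactly the flagged fragments."""
    branches: list[str] = []
    if flags["ring"]:
        aromatic = rng.random() < 0.7
        if flags["halogen"]:
            hal = rng.choice(["F", "Cl", "Br"])
            ring = f"c1ccc({hal})cc1" if aromatic else f"C1CCC({hal})CC1"
        else:
            ring = "c1ccccc1" if aromatic else "C1CCCCC1"
        branches.append(ring)
    elif flags["halogen"]:
        branches.append(str(rng.choice(["F", "Cl", "Br"])))
    for name, smi in _BRANCH_SMILES.items():
        if flags[name]:
            branches.append(smi)
    n_methyl = int(rng.integers(0, 3))
    branches.extend(["C"] * n_methyl)

    chain_len = max(3, len(branches)) + int(rng.integers(0, 4))
    positions = rng.choice(chain_len, size=len(branches), replace=False)
    per_pos: dict[int, list[str]] = {}
    for pos, br in zip(positions, branches):
        per_pos.setdefault(int(pos), []).append(br)
    tokens = []
    for i in range(chain_len):
        tokens.append("C")
        for br in per_pos.get(i, []):
            tokens.append(f"({br})")
    return "".join(tokens)


def generate_structures(
    config: GeneratorConfig,
) -> tuple[list[ChemicalStructure], pd.DataFrame]:
    """Structures plus a ground-truth table of fragment flags and true logB.

    Every emitted structure passes standardization; substance ids are
    ``S0000`` onward and structures are unique at the structure-key level.
    """
    rng = np.random.default_rng(config.seed)
    structures: list[ChemicalStructure] = []
    rows = []
    seen_keys: set[str] = set()
    i = 0
    while len(structures) < config.n_substances:
        flags = {name: bool(rng.random() < config.fragment_probs.get(name, 0.0))
                 for name in FRAGMENT_FLAGS}
        smiles = _assemble_smiles(flags, rng)
        sid = f"S{i:04d}"
        s = standardize_structure(smiles, substance_id=sid)
        if not s.valid or s.structure_key in seen_keys:
            continue  # resample; rng state advances so retries differ
        seen_keys.add(s.structure_key)
        true_logb = config.baseline_logB + sum(
            config.effects.get(name, 0.0) for name, on in flags.items() if on
        )
        true_logb = min(true_logb, config.logB_cap)
        rows.append({"substance_id": sid, "smiles": smiles, "true_logB": true_logb,
                     **{f"has_{k}": v for k, v in flags.items()}})
        structures.append(s)
        i += 1
    return structures, pd.DataFrame(rows)


def generate_monitoring(
    truth: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monitoring records and plant metadata for the given ground truth.

    Uses an independent stream of ``config.seed`` so records are reproducible
    given the same truth table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_elim = int(round(config.n_eliminating_fraction * config.n_plants))
    plants = pd.DataFrame(
        {
            "plant_id": [f"P{i:03d}" for i in range(config.n_plants)],
            "n_eliminating": [i < n_elim for i in range(config.n_plants)],
            "dataset_id": [f"D{i % config.n_datasets}" for i in range(config.n_plants)],
        }
    )
    offsets = rng.normal(0.0, config.dataset_offset_sd, size=config.n_datasets)
    dataset_offset = {f"D{i}": offsets[i] for i in range(config.n_datasets)}

    records = []
    for row in truth.itertuples():
        primary = int(rng.integers(config.n_datasets))
        datasets = {f"D{primary}"}
        if config.n_datasets > 1 and rng.random() < config.overlap_fraction:
            extra = int(rng.integers(config.n_datasets - 1))
            if extra >= primary:
                extra += 1
            datasets.add(f"D{extra}")
        for ds in sorted(datasets):
            for plant in plants[plants["dataset_id"] == ds].itertuples():
                logb = (
                    row.true_logB
                    + rng.normal(0.0, config.plant_sd)
                    + dataset_offset[ds]
                    + (0.0 if plant.n_eliminating else config.c_plant_shift)
                )
                if rng.random() < config.artifact_rate:
                    logb += np.log10(rng.uniform(1.5, 3.0))
                c_inf = 10.0 ** rng.normal(2.0, 0.5)
                records.append(
                    {
                        "substance_id": row.substance_id,
                        "plant_id": plant.plant_id,
                        "dataset_id": ds,
                        "c_influent": c_inf,
                        "c_effluent": c_inf * 10.0**logb,
                    }
                )
    rec = pd.DataFrame(records)
    # per-stream quantiles so both influent and effluent censoring occur
    if config.loq_quantile > 0:
        loq_inf = float(np.quantile(rec["c_influent"], config.loq_quantile))
        loq_eff = float(np.quantile(rec["c_effluent"], config.loq_quantile))
    else:
        loq_inf = loq_eff = 0.0
    rec["influent_below_loq"] = rec["c_influent"] < loq_inf
    rec["effluent_below_loq"] = rec["c_effluent"] < loq_eff
    return rec, plants[["plant_id", "n_eliminating"]]


def generate_properties(truth: pd.DataFrame, config: GeneratorConfig) -> PropertyTable:
    """Synthetic K_OC / Henry table with planted sorbing and volatile outliers."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(truth)
    koc = 10.0 ** rng.normal(2.5, 0.4, size=n)  # well below 4000 L/kg
    henry = 10.0 ** rng.normal(-8.0, 0.8, size=n)  # well below 1e-5
    sorbing = rng.random(n) < config.sorbing_fraction
    volatile = rng.random(n) < config.volatile_fraction
    koc[sorbing] = 10.0 ** rng.normal(4.3, 0.2, size=int(sorbing.sum()))
    henry[volatile] = 10.0 ** rng.normal(-3.5, 0.5, size=int(volatile.sum()))
    table = pd.DataFrame(
        {"substance_id": truth["substance_id"], "koc": koc, "henry": henry,
         "is_sorbing": sorbing, "is_volatile": volatile}
    )
    return PropertyTable(table=table[["substance_id", "koc", "henry"]],
                         source="synthetic"), table


@dataclass
class SyntheticDataset:
    structures: list[ChemicalStructure]
    truth: pd.DataFrame
    records: pd.DataFrame
    plant_meta: pd.DataFrame
    props: PropertyTable
    prop_truth: pd.DataFrame
    config: GeneratorConfig


def generate_all(config: GeneratorConfig) -> SyntheticDataset:
    structures, truth = generate_structures(config)
    records, plant_meta = generate_monitoring(truth, config)
    props, prop_truth = generate_properties(truth, config)
    return SyntheticDataset(structures, truth, records, plant_meta, props,
                            prop_truth, config)


def r2_ceiling(truth: pd.DataFrame, summaries: pd.DataFrame) -> float:
    """R² of the oracle predicting each substance's true logB.

    ``1 - E[(median - true)^2] / Var(median)``: the irreducible noise in the
    observed medians bounds what any structure-based model can achieve.
    """
    merged = summaries.merge(truth[["substance_id", "true_logB"]], on="substance_id")
    if merged.empty:
        raise ValueError("no overlap between truth and summaries")
    err = merged["median_logB"] - merged["true_logB"]
    var = float(np.var(merged["median_logB"]))
    if var == 0:
        raise ValueError("observed medians have zero variance")
    return float(1.0 - np.mean(err**2) / var)
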