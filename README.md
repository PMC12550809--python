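# mpbreak

Predict micropollutant breakthrough in conventional wastewater treatment
directly from molecular structure.

Breakthrough is the effluent/influent concentration ratio of a substance at
a treatment plant (`B = c_effluent / c_influent`); its base-10 logarithm,
aggregated as the median across plants, is the modeling endpoint. The
package covers the full workflow:

- **structures** — SMILES/SDF standardization (salt stripping, charge
  neutralization, canonicalization) and duplicate merging via
  connectivity-level InChIKey blocks.
- **monitoring** — the monitoring-record data model, breakthrough
  computation with LOQ handling, per-substance aggregation, and a
  batch-effect check comparing between-substance vs between-campaign
  variance components.
- **curation** — five configurable quality criteria (minimum plant count,
  breakthrough cap, cross-plant variability cap, effluent-LOQ entry
  filtering, sorption/volatility exclusion via K_OC and Henry constants)
  plus a 32-combination sweep evaluated on a fixed high-confidence pool.
- **descriptors** — MACCS (166 keys), Morgan/ECFP (radius 2, 2048 bits),
  RDKit path fingerprints, and a rule-based fingerprint that one-hot
  encodes which biotransformation-trigger SMARTS rules match a molecule
  (a documented default rule file ships with the package; any tab-separated
  `rule_id  smarts  description` file can be substituted). Fingerprint
  collision analysis included.
- **modeling** — twelve regressor families behind one contract, 5-fold
  nested cross-validation with shared outer splits, y-scrambling over the
  full workflow, two-stage hyperparameter search with
  simplicity-preferring tie-breaks, post-hoc affine bias correction fitted
  on training data only, and serializable prediction bundles.
- **applicability** — Tanimoto nearest/nearest-5 similarity to the training
  set, per-prediction ensemble disagreement (tree SD), a rank-percentile
  confidence score, coverage–error curves, and an "ideal model" simulation
  that benchmarks against experimental variability.
- **interpretation** — cross-fold feature importance, retraining on top-k
  features, and exact Shapley attributions for the tree ensemble (a
  numba-compiled path-dependent tree-Shapley implementation, verified
  against a brute-force oracle in the tests).
- **synthetic** — ground-truth monitoring campaigns with planted
  structure→breakthrough effects (halogen up, hydroxyl down, ring up),
  plant noise, campaign offsets, LOQ censoring and artifact spikes, used
  throughout the test suite.

## Command-line usage

The `mpbreak` entry point exposes the staged workflow:

```bash
# generate a synthetic campaign with ground truth
mpbreak simulate --n-substances 300 --seed 0 --out sim/

# full pipeline: standardize -> breakthrough -> curate -> featurize ->
# train -> predict -> explain, with a run log and per-stage tables
mpbreak run --config run.cfg

# individual stages
mpbreak curate --config run.cfg
mpbreak featurize --structures sim/structures.csv --descriptors MACCS --out fps.csv
mpbreak benchmark --config run.cfg --regressors RF,SVR,KNN --seed 0 --out bench.csv
mpbreak train --config run.cfg
mpbreak predict --bundle out/model_bundle.joblib --structures new.csv --out preds.csv
mpbreak explain --config run.cfg
mpbreak ad-curve --predictions preds_with_truth.csv --ranking tree_sd --out curve.csv
```

Config files are flat `key = value` text (see `RunConfig` in
`mpbreak/cli.py` for all keys):

```ini
monitoring_csv = sim/monitoring.csv
structures_csv = sim/structures.csv
plant_meta_csv = sim/plant_meta.csv
descriptor = MACCS
use_I = true          # >= 3 plants
use_III = true        # cross-plant SD of logB < 0.7
seed = 0
output_dir = out
```

Exit codes: 0 success, 2 configuration error, 3 data error.

### Input schemas (CSV)

- `monitoring.csv`: `substance_id, plant_id, dataset_id, c_influent,
  c_effluent, influent_below_loq, effluent_below_loq` (concentrations in
  plant-consistent units; the ratio is what matters).
- `structures.csv`: `substance_id, smiles`.
- `plant_meta.csv`: `plant_id, n_eliminating`.
- `properties.csv` (criterion V only): `substance_id, koc, henry`
  (K_OC in L/kg, Henry constant in atm·m³/mol).

## Notes and conventions

- logB is base-10 throughout; RMSE values are in log10 units.
- The confidence score is defined as 1 minus the rank percentile of a
  prediction's tree SD within the training set's tree-SD distribution.
  This mapping is an internal convention of this package.
- A fold whose true targets are constant is scored R² = 0 (no variance to
  explain), never 1.
- Records with influent below the LOQ are rejected; effluent values below
  the LOQ are used as measured and flagged (curation criterion IV can drop
  them later). Zero effluent concentrations are rejected by default; a
  substitution floor is available but off by default.
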