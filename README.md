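# eggchem

Chemometric discrimination of free-range vs caged eggs from 16-element
eggshell profiles (Zn, Pb, Cd, Co, Ni, Fe, Mn, Cr, Mg, Cu, Se, Ca, Al,
Sr, Na, K measured by ICP-AES).

The package implements the full analysis workflow as tested, reusable
pieces:

- **`eggchem.panel`** — the 16-element analytical panel (wavelengths,
  detection limits) and class-conditional concentration distributions,
  shipped as YAML.
- **`eggchem.simulate`** — synthetic profile generator: zero-truncated
  normal marginals per class, optional shared-factor correlation,
  triplicate measurement averaging, detection-limit censoring, exact-zero
  nondetects (free-range Cd), and planted gross outliers for recovery
  experiments.
- **`eggchem.preprocess`** — profile-table CSV I/O, the 3-sigma blank
  detection-limit estimator, censoring, row-wise division by sample
  weight and column-wise autoscaling with explicit reference subsets.
- **`eggchem.outliers`** — Stahel–Donoho-style outlyingness via random
  projections (|x·a − median| / (1.4826·MAD), max over 1000 unit
  directions), flagged above a fixed cutoff of 3, screened per class.
- **`eggchem.split`** — Kennard–Stone maximin selection of training
  samples, run separately per class.
- **`eggchem.models`** — PCA (SVD), PLS-DA (single-response NIPALS) and
  LS-SVM with RBF kernel (KKT linear system), all written from their
  defining linear algebra, plus leak-free autoscaling classifier
  wrappers.
- **`eggchem.validation`** — confusion counts, sensitivity/specificity/
  accuracy (exact half-up percentage rounding), Monte Carlo cross
  validation (100 stratified 70/30 splits) and shared-split grid search.
- **`eggchem.pipeline` / `eggchem.cli`** — one-config orchestration with
  per-stage seeds, JSON/CSV artifacts and a machine-readable run report.

## Command line

```sh
# synthetic table: 127 free-range + 122 caged samples
eggchem simulate --n-per-class 127 122 --seed 7 --out profiles.csv

# stage by stage
eggchem screen --input profiles.csv --out screen/ --seed 1
eggchem split  --input screen/screened.csv --n-train 80 --out split.json
eggchem train  --input screen/screened.csv --split split.json --out models/
eggchem evaluate --input screen/screened.csv --split split.json \
    --model models/model_plsda.json --model models/model_lssvm.json

# or everything from one config
eggchem run-all --config src/eggchem/data/default_pipeline.yaml --out run/
```

`run/report.json` records per-stage provenance, outlier reports, the
train/test split, selected parameters (latent-variable count for PLS-DA,
(sigma², gamma) for LS-SVM), test-set confusion counts/metrics and a
checksum manifest of every artifact. Reruns with the same config and
seed are bit-identical.

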