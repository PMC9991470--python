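# Default end-to-end pipeline configuration: synthetic 127 + 122 table
# with 2 + 1 planted gross outliers, 1000-projection outlier screen at
# cutoff 3, 80 training samples per class, and MCCV (100 splits, 70/30)
# tuning for both classifier families.
seed: 20190101
input_csv: null
generator:
  n_per_class: {free-range: 127, caged: 122}
  planted_outliers: {free-range: 2, caged: 1}
  displacement: 10.0
outlier_screen:
  n_projections: 1000
  cutoff: 3.0
split:
  n_train_per_class: 80
mccv:
  n_splits: 100
  train_frac: 0.7
  stratified: true
models:
  - family: plsda
  - family: lssvm
out_dir: eggchem-run
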