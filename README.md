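# strataclock

Stratified CpG feature selection, a neural-network DNA-methylation age clock
with leave-one-cohort-out (LOCO) ensembling, gradient-Shapley attribution,
and multiscale-bootstrap discovery of age-phase ("wave") structure — with a
first-class synthetic-methylome module that plants ground truth for every
downstream stage.

## What's inside

| module | purpose |
| --- | --- |
| `strataclock.simulate` | seeded synthetic cohorts with planted CpG classes (linear / logistic / piecewise-phase / sex-modulated / null), cohort offsets and phase boundaries |
| `strataclock.io` | beta-matrix and sample-sheet TSV/CSV I/O, EPICv2 suffix collapsing, cross-platform probe harmonization, imputation |
| `strataclock.selection` | age x sex stratified Spearman correlation, top-fraction selection with provenance, stratified-vs-pooled detectability classes |
| `strataclock.model` | NumPy feed-forward age regressor (Adam, dropout, L2), LOCO ensembling, seeded random hyperparameter search |
| `strataclock.attribution` | expected-gradients Shapley attribution, 5-year age-bin profiles, top/bottom-K CpG sets |
| `strataclock.phases` | Ward.D2 clustering, multiscale-bootstrap AU/BP edge support, fixed-height phase cuts, sex-stratified comparison, raw-beta route |
| `strataclock.evaluation` | calibration panel (MAE/MedAE/RMSE/bias/r/rho/R2/slope/intercept/Age_Accel_SD), clock ranking, delta-age, cell-composition sensitivity |
| `strataclock.pipeline` + `strataclock.cli` | end-to-end orchestration with seeded stage fan-out and a hashed run manifest |

The network, the expected-gradients estimator and the random search are
implemented directly on NumPy so training and attribution are deterministic
from a seed and input gradients are exact.

## CLI

Each pipeline stage is a subcommand working on plain-text artifacts:

```bash
strataclock simulate --samples-per-cohort 200 --cohorts 3 --seed 1 --out data/
strataclock select-features --beta data/beta.tsv --meta data/meta.csv --fraction 0.01 --out sel/
strataclock train --beta data/beta.tsv --meta data/meta.csv --features sel/features.txt --out model/
strataclock predict --beta data/beta.tsv --meta data/meta.csv --model model/ --out predictions.csv
strataclock explain --beta data/beta.tsv --meta data/meta.csv --model model/ --out expl/
strataclock phases --profiles expl/bin_profiles.tsv --k 4 --out phases/
strataclock evaluate --predictions predictions.csv --meta data/meta.csv --out calibration.json
```

or run everything from one YAML config (see `PipelineConfig.to_yaml` for the
schema; exactly one of `synthetic:` or `inputs:` must be set):

```bash
strataclock run-all --config config.yaml
```

The output directory contains the feature set, model bundle, predictions,
calibration report, attribution matrix, bin profiles, supported dendrograms
(combined and per sex, as JSON and Newick), phase tables, and a
`manifest.json` with per-stage seeds and SHA-256 hashes of every artifact.
Re-running with the same config and seed reproduces all numeric artifacts.

## Conventions

- Sex is encoded 0 = female, 1 = male (-1 = unknown) everywhere.
- Age-bin strata are half-open `[lo, hi)` with the last bin closed.
- Missing betas are empty fields or `NA` on disk and NaN in memory.
- R^2 in calibration reports is the squared Pearson correlation of predicted
  vs chronological age; standard deviations use the n-1 denominator.
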