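# molarage

Statistical toolkit for assessing whether a sub-adult is older than 18
years from MRI-segmented tooth tissue volumes of 1st/2nd molars.

The package covers the full pipeline:

- **`molarage.voxel`** — T2 intensity-threshold segmentation (hard tooth
  tissue 0–63, low-signal soft tissue 64–100, high-signal soft tissue
  ≥101) and voxel-count-to-ml conversion on 3-D toy phantoms.
- **`molarage.transforms`** — the ten volume-transformation outcomes
  (total, `x/(total−x)`, `x/total`, `(x+y)/total` families), their
  natural logs, and a Pearson redundancy screen (|R| ≥ 0.999 on the log
  scale flags overlapping outcomes; family-2 members are dropped).
- **`molarage.regression`** — weighted linear regression grid: five sex
  structures (sex ignored; per-sex intercept; per-sex slope; both;
  fully separate models) × three variance weightings
  (`Var = σ²·v(age)`, `v ∈ {1, age, 1/age}`), AIC model selection, and
  ranking of outcome/tooth-set candidates by per-sex age p-value.
- **`molarage.posterior`** — Bayesian age prediction: uniform prior on
  [14, 23] years, Gaussian predictive likelihood (with parameter
  uncertainty by default), gridded posterior density and P(age > 18).
- **`molarage.combine`** — two-molar combination: bivariate normal
  likelihood with a jointly ML-estimated correlation ρ, supporting
  participants with only one of the two teeth, plus fused posteriors.
- **`molarage.synth`** — synthetic cohort generator calibrated to the
  printed per-sex/per-molar median volumes and per-tooth sample sizes,
  so every stage is testable without participant data.
- **`molarage.io` / `molarage.cli` / `molarage.pipeline`** — cohort CSV
  schema, JSON model artifacts, validated run configuration, and the
  end-to-end orchestration.

## CLI

All commands are subcommands of `molarage`:

```sh
# synthetic cohort with the printed per-tooth sample sizes
molarage simulate --seed 1 --out cohort.csv

# redundancy screen over the ten log outcomes
molarage screen --cohort cohort.csv --out screen.json

# fit one outcome/tooth-set model (AIC-selected structure and weighting)
molarage fit --cohort cohort.csv --outcome 4a --teeth 47 --out model.json

# rank candidates by age p-value
molarage rank --cohort cohort.csv --out ranked.csv

# posterior age density and P(age > 18) for an observation
molarage predict --model model.json --y -2.5 --sex M --out posterior.json
molarage predict --model model.json --volumes 1.1,0.07,0.028 --sex M --out posterior.json

# two-tooth combination (joint ML, correlation included)
molarage fit --cohort cohort.csv --outcome 4a --teeth 46 --out m46.json
molarage combine --cohort cohort.csv --model-a m46.json --model-b model.json --out bivariate.json

# full pipeline: screen -> rank -> fit -> predict (-> combine)
molarage run --cohort cohort.csv --config config.json --out-dir out/
```

The cohort CSV is long format, one row per participant-tooth:
`participant_id, sex, age_years, tooth_fdi, hard_ml, hsst_ml, lsst_ml`.

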