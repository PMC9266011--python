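# gwrisk

Reusable pipeline for assessing heavy-metal contamination of groundwater:

- **Data model & statistics** — validated sites × metals concentration
  tables (CSV, μg/L canonical unit, detection-limit substitution) with
  descriptive summaries (CV%, adjusted Fisher–Pearson skewness/kurtosis).
- **Pollution indices** — weighted water-quality index (WQI) with five
  quality classes, and the unweighted pollution evaluation index (PEI) with
  low/medium/high banding; per-metal contributions to the mean index.
- **Source apportionment** — APCS/MLR receptor modelling: Pearson
  screening, KMO and Bartlett adequacy tests, varimax-rotated PCA, absolute
  principal component scores, per-metal OLS, and per-metal / overall source
  contribution percentages.
- **Health risk** — deterministic USEPA-style engine (ingestion + dermal
  average daily dose, HQ/HI, one-hit ILCR/TCR) for adult males, adult
  females and children.
- **Monte Carlo layer** — lognormal concentration fitting, distributional
  exposure inputs, 10,000-trial simulation with mean/median/SD/CI/percentile
  summaries and exceedance probabilities.
- **Source-oriented risk** — per-metal risks weighted by source
  contribution fractions, with priority rankings of metals and sources.
- **Synthetic generator** — a 60 × 7 latent 3-source mixing model with
  lognormal scores, multiplicative noise, optional outlier inflation, and
  exact ground-truth contribution percentages for recovery testing.

## CLI

All stages are exposed as subcommands of `gwrisk` (also runnable as
`python -m gwrisk.cli`):

```bash
gwrisk simulate --seed 1 --outdir out/            # synthetic table + truth
gwrisk stats out/concentrations.csv               # descriptive summary
gwrisk wqi out/concentrations.csv --out out/wqi.csv
gwrisk pei out/concentrations.csv --out out/pei.csv
gwrisk apportion out/concentrations.csv --outdir out/
gwrisk risk out/concentrations.csv
gwrisk mc-risk out/concentrations.csv --seed 1 --trials 10000
gwrisk source-risk out/concentrations.csv
gwrisk run-all --seed 1 --outdir out/run          # full pipeline + manifest
```

`--config config.yaml` overlays a YAML file onto the shipped defaults
(guideline values, index weights, toxicity values, exposure parameters and
Monte Carlo settings — see `gwrisk.config`). `run-all` writes a
`manifest.yaml` recording the config hash, seed, package version and every
emitted file; reruns with the same config and seed reproduce all outputs.

## Layout

```
src/gwrisk/
  core_data.py     table model, CSV I/O, descriptive statistics
  synthetic.py     latent-source generator + ground truth
  water_quality.py WQI / PEI indices and classification
  apportion.py     correlation, KMO/Bartlett, PCA+varimax, APCS, MLR
  health_risk.py   deterministic dose/HQ/HI/ILCR/TCR engine
  monte_carlo.py   distribution specs, trial sampling, summaries
  source_risk.py   risk × source-contribution coupling, rankings
  config.py        shipped defaults + YAML overlay
  pipeline.py      file-based orchestration and run manifest
  cli.py           click entry points
tests/             unit, property and acceptance suites
scripts/acceptance.py
```
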