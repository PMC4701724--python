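# ecoskill

Skill assessment for ecosystem-model output. Given paired observed/modeled
annual time series of group biomass, fishery landings and primary
production, plus per-group metadata (guild, commercial/TEP flags, trophic
level, price), the package:

- computes seven skill metrics per series and period — average error (AE),
  average absolute error (AAE), RMSE, modeling efficiency (MEF), and
  Spearman/Pearson/Kendall correlations;
- derives 22 ecosystem indicators (total biomass, catch/biomass,
  demersal/pelagic ratio, mean trophic levels, value of the catch, ...)
  from the raw series for both sources and scores them the same way;
- expands stratified survey catch rates to minimum swept-area biomass
  estimates with variance and 95% confidence bands;
- compares forecast skill against the hindcast skill distribution
  (orientation-corrected percent ranks with 40/60 classes) and runs a PCA
  of the metric matrix to expose redundant metrics;
- generates synthetic inputs: stylized mismatch scenarios (perfect fit,
  scale mismatch, inverse variation, lack of correlation, trend mismatch,
  combinations) and full multi-group ecosystems with known ground truth,
  observation error, harvest-linked landings and differential
  missing-data onsets.

Biomass and landings series are z-scored over their full record before
direct comparison; indicators are computed on raw (un-normalized) inputs.

## CLI

The console script `ecoskill` exposes the pipeline:

```sh
# synthetic ecosystem with ground truth
ecoskill simulate --seed 7 --n-groups 30 --skill high --out-dir data/

# full assessment: skill table, quantile comparison, PCA (+ optional plots)
ecoskill assess --series data/series.csv --metadata data/metadata.csv \
    --out-dir results/ --plots

# individual stages
ecoskill indicators --series data/series.csv --metadata data/metadata.csv \
    --source observed --out indicators.csv
ecoskill expand --strata strata.csv --total-area 293000 --swept-area 0.01
ecoskill compare --skill results/skill.csv --out comparison.csv
ecoskill pca --skill results/skill.csv --category biomass --out loadings.csv
ecoskill scenarios --kind scale_mismatch --seed 1 --out scenario.csv
```

`assess` accepts a YAML config overriding the analysis periods (default:
full hindcast 1964–2004, no-spin-up 1974–2004, four decades, forecast
2005–2013):

```yaml
periods:
  - {name: full_hindcast, start_year: 1964, end_year: 2004}
  - {name: forecast, start_year: 2005, end_year: 2013}
hindcast_period: full_hindcast
forecast_period: forecast
```

## File formats

Long-format series CSV: `series_id, category, source, year, value, units`
with `category` in {biomass, landings, primary_production, indicator} and
`source` in {observed, modeled}; empty value cells are gaps. Metadata CSV:
`group_id, name, guild, is_fish, is_commercial, is_tep, trophic_level,
price_per_ton`. Skill tables: `series_id, category, metric, period, value,
n` (NaN value = flagged-undefined cell).

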