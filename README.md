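# topdress

Winter-wheat nitrogen topdressing recommendation from remote-sensing biomass.

The package implements a three-step decision chain:

1. **Biomass estimation** — plot-level aboveground dry biomass (AGB, t/ha)
   is estimated from multispectral reflectance via the two-band enhanced
   vegetation index (EVI2) and a two-level linear model whose intercept and
   slope vary with cumulative growing degree days (GDD).
2. **Data assimilation** — a particle swarm re-estimates four genotype
   traits and three management totals of a daily crop-growth model by
   minimising the mean relative-squared misfit between estimated and
   simulated AGB at the sampled growth stages.
3. **Recommendation** — the assimilated model is swept over a topdressing
   grid (default 0–360 kg N/ha in 10 kg steps); the target yield is the
   yield at the net-benefit-maximising rate (grain 2.4 CNY/kg, N 2.75
   CNY/kg), and the lowest grid rate attaining that target is recommended.
   A fitted power-law curve (N = 92.61 · AGB^−0.88) mapping jointing-stage
   AGB directly to a rate is available for gridded (map) use.

The crop model is a compact surrogate (radiation-use-efficiency growth,
Beer's-law interception, a soil water bucket, critical-N-dilution demand,
GDD-driven phenology) behind a pluggable `CropModel` interface, so a
full cropping-systems model can be substituted without touching the rest
of the chain. A seeded synthetic-data module generates weather, factorial
field trials and reflectance observations so the whole pipeline runs with
no external data.

## Layout

| module | contents |
| --- | --- |
| `topdress.crop_model` | weather/soil/management types, GDD and Angström–Prescott radiation, the daily growth surrogate |
| `topdress.agb` | EVI2, the GDD-modulated biomass model (predict + fit), destructive-sampling conversion |
| `topdress.assimilation` | particle swarm: fitness, swarm init/update, the assimilation loop |
| `topdress.recommendation` | economic benefit, yield response curves, optimum/target rules, power-law reference curve |
| `topdress.evaluation` | RMSE, nRMSE (%), adjusted R² |
| `topdress.synthetic` | seeded weather, trial designs, AGB sampling and reflectance synthesis |
| `topdress.io` | CSV/YAML/raster readers and writers |
| `topdress.pipeline`, `topdress.cli` | orchestration and the `topdress` command |

## CLI

```sh
# generate a synthetic trial (32 plots, 128 AGB samples)
topdress generate --seed 11 --out data/

# fit the biomass model / estimate AGB from reflectance
topdress fit-hlm --obs data/spectra.csv --out hlm.json
topdress estimate-agb --obs data/spectra.csv --out agb_est.csv

# assimilate one plot and recommend a topdressing rate
topdress assimilate --weather data/weather.csv --soil data/soil.yaml \
    --mgmt data/mgmt.yaml --obs agb_est.csv --plot V1N90R1 \
    --free fertilization --seed 7 --out assim.json
topdress recommend --assim assim.json --weather data/weather.csv \
    --soil data/soil.yaml --mgmt data/mgmt.yaml --out rec.json

# gridded mode: jointing AGB raster (CSV matrix) -> N-rate raster
topdress recommend --agb-raster agb_map.csv --out n_map.csv

# metrics between two value files
topdress evaluate --measured m.txt --predicted p.txt --predictors 1

# full pipeline from a YAML config
topdress run --config run.yaml
```

A `run.yaml` names the input files plus swarm/grid/price settings:

```yaml
weather_csv: data/weather.csv
soil_yaml: data/soil.yaml
mgmt_yaml: data/mgmt.yaml
spectra_csv: data/spectra.csv
free_parameters: [fertilization]
swarm: {n_particles: 25, max_iterations: 100}
grid: {n_min: 0, n_max: 360, step: 10}
prices: {grain_price: 2.4, n_price: 2.75}
seed: 7
out_dir: out
```

Reports embed the config hash and seed; reruns with the same config and
seed are byte-identical.

## Notes

* All swarm randomness is driven by a single seeded generator; the crop
  model itself is deterministic.
* The monitoring model's GDD covariate is used exactly as published in the
  prediction API; the synthetic generator documents the scale it uses to
  keep index values physical (`topdress.synthetic.GDD_COVARIATE_SCALE`).
* Yields are dry-basis; a 14 %-moisture equivalence helper is provided but
  never applied implicitly.
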