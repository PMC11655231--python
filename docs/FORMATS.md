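# File formats

One canonical dialect for every table: CSV, UTF-8, dot decimal separator,
mandatory header row. Readers reject unknown columns and report the row and
column of the first violation. Times are minutes as floats; t = 0 is the
moment the meal is mixed with basal SGF.

## psd.csv — particle-size distributions

One row per diameter bin per (sample, time, dispersant). Bins must be
contiguous and strictly increasing; volume fractions are renormalized on
load.

| column      | type  | constraint            |
|-------------|-------|------------------------|
| sample      | text  |                        |
| time_min    | float | >= 0                   |
| dispersant  | text  | `water` or `sds_edta`  |
| bin_lo_um   | float | > 0                    |
| bin_hi_um   | float | > 0, = next bin_lo_um  |
| volume_frac | float | >= 0                   |

```csv
sample,time_min,dispersant,bin_lo_um,bin_hi_um,volume_frac
casein_1,0,water,0.5,2.0,0.6
casein_1,0,water,2.0,4.5,0.4
```

## retention.csv — nutrient retention observations

| column       | type  | constraint                       |
|--------------|-------|-----------------------------------|
| sample       | text  |                                   |
| nutrient     | text  | `protein`, `lipid` or `total`     |
| time_min     | float | >= 0                              |
| retained_pct | float | in [0, 110] (noise above 100 ok)  |

```csv
sample,nutrient,time_min,retained_pct
whey_1,protein,0,100
whey_1,protein,20,71.8
```

## bands.csv — gel densitometry intensities

| column    | type  | constraint |
|-----------|-------|------------|
| sample    | text  |            |
| band      | text  |            |
| time_min  | float | >= 0; a t = 0 row per band is required |
| intensity | float | >= 0       |

```csv
sample,band,time_min,intensity
whey_1,beta_LG,0,1800
whey_1,beta_LG,80,950
```

## groups.csv — profile labels

| column  | type | constraint |
|---------|------|------------|
| sample  | text |            |
| profile | text | `casein_dominant`, `whey_dominant` or `biopolymer_whey` |

```csv
sample,profile
whey_1,whey_dominant
```

## dilution.csv — explicit dilution factors (optional, for `bands`)

| column   | type  | constraint |
|----------|-------|------------|
| time_min | float | >= 0       |
| factor   | float | >= 1       |

```csv
time_min,factor
0,1.0
20,1.0909
```

## Protocol / formula configuration (YAML)

`igastro simulate` reads YAML mirroring `DigestionProtocol` and
`FormulaSpec` field-for-field; unknown keys are rejected.

```yaml
# protocol.yaml (all fields optional; defaults shown)
meal_mass_g: 100.0
basal_sgf_mass_g: 10.0
sgf_flow_ml_min: 0.4
enzyme_flow_ml_min: 0.1
emptying_mass_g: 22.0
emptying_interval_min: 20.0
total_time_min: 160.0
sieve_cutoff_um: 1000.0
sampling_times_min: [15, 40, 80, 120, 160]
pepsin_activity_u_ml: 651.0
lipase_activity_u_ml: 60.0
sgf_ph: 2.0
basal_sgf_ph: 3.0
temperature_c: 37.0
```

```yaml
# formula.yaml
name: casein_if_1
protein_frac: 0.017
fat_frac: 0.0394
whey_casein_ratio: [20, 80]
profile: casein_dominant
curd_protein: {onset_min: 15, rate_per_min: 0.03, plateau: 0.35}
curd_lipid: {onset_min: 15, rate_per_min: 0.025, plateau: 0.28}
```

## Pipeline outputs

* `indices.csv` — sample, time_min, d43_water, d43_buffer, AI, CI
* `elashoff_fits.csv` — sample, nutrient, alpha0, kappa, kappa_e3 (κ×10³),
  beta, rss, converged
* `two_stage.csv` — sample, index_kind, nutrient, breakpoint_pct,
  stage2_slope, stage2_intercept_pct, r_squared_stage2, n_stage1, n_stage2,
  degenerate
* `regressions.csv` — group, slope, intercept, r_squared, n
* `band_residuals.csv` — sample, band, time_min, residual_intact,
  halftime_min, censored
* `run_manifest.json` — SHA-256 of every input, the protocol actually used,
  and output paths
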