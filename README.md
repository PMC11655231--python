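# igastro

Analysis toolkit for **dynamic in vitro infant gastric digestion** of milk
formulae. It is written for food-structure and digestion-kinetics
researchers who run dynamic gastric simulators (continuous secretion,
periodic sieved emptying) and want a reproducible path from raw particle-size
and retention measurements to emptying-rate constants and
structure–function correlations.

## What it computes

**Gastric mass balance.** A digital twin of the infant gastric simulator
protocol: a 100 g formula meal plus 10 g basal simulated gastric fluid
(pH 3.0), nutrient-free secretion at 0.5 mL/min, and withdrawal of 22 g of
chyme through a 1 mm sieve every 20 min over 160 min at 37 °C. Coagulated
protein (curd) and the lipid entrapped in it are sieve-retained and never
appear in emptied aliquots. Mass is conserved to < 1 nanogram at every step.

**Emptying kinetics.** Retention curves are fitted with the modified
power-exponential (Elashoff) model

    y(t) = α₀ · exp(−(κt)^β)

where *y(t)* is % of the nutrient retained, α₀ the value at *t* = 0 (100%
for relative retention), κ the gastric-emptying rate (min⁻¹, conventionally
reported ×10³) and β a dimensionless shape index.

**Colloidal destabilization.** From binned particle-size distributions the
volume-weighted mean diameter d₄,₃ = Σnᵢdᵢ⁴/Σnᵢdᵢ³ is computed in two
dispersant dialects — plain water, and SDS (1%) + EDTA (50 mM) buffer, which
dissolves casein micelles and protein flocs. The Aggregation Index
AI = (d₄,₃(chyme) − d₄,₃(t₀)) / d₄,₃(t₀) on water-dispersed measurements
captures flocculation + coalescence; the Coalescence Index CI (same ratio in
buffer) isolates true oil-droplet coalescence.

**Structure–function correlation.** AI/CI versus % nutrient emptied is
described in two stages (a near-zero plateau driven by withdrawal alone,
then a near-linear rise once destabilization sets in); the stage-2 line's
x-intercept marks the destabilization onset in "% emptied" units. Percent
lipid emptied is regressed on percent protein emptied, overall and per
formula class (casein-dominant, whey-dominant, biopolymer-stabilized).

**Supporting pieces:** dilution-corrected SDS-PAGE densitometry
(residual-intact fractions and hydrolysis half-times), a power-law
flow-curve classifier, and a seeded synthetic-study generator that produces
complete schema-valid bundles for testing and parameter-recovery studies.

## Worked example

```python
import igastro as ig

# a synthetic study: one formula per profile class, fully seeded
bundle = ig.synth_study(n_per_profile=1, seed=1)
fit = ig.fit_retention(bundle.retention["whey_dominant_1"]["protein"])
print(fit.summary())
```

```
Modified power-exponential retention fit
  sample: whey_dominant_1   nutrient: protein
  form: product_power   n = 9   converged: True
  alpha0 =    99.1881 %  (fixed)
  kappa  =   0.016555 /min  (x10^3: 16.56)  +/- 0.000684
  beta   =     1.0212  +/- 0.0741
  rss    =    78.4336
  t_half =      42.19 min
```

The whey-dominant template generates observations with a true
κ = 16.2 × 10⁻³ min⁻¹ plus 2% Gaussian noise; the fit recovers
16.56 × 10⁻³ min⁻¹ with a standard error of 0.68 × 10⁻³, i.e. protein
half-empties in about 42 min. Casein-dominant formulae fit around
11 × 10⁻³ min⁻¹ — slower emptying, driven by curd formation.

The simulator side:

```python
f = ig.FormulaSpec(name="casein_if_1", protein_frac=0.017, fat_frac=0.0394,
                   whey_casein_ratio=(20, 80), profile="casein_dominant")
ts = ig.run_digestion(f, ig.DigestionProtocol())
print("chyme at 160 min: %.1f g" % ts.state_at(160).chyme_mass_g)
print("protein retained at 20 min: %.2f %%" % ig.nutrient_retention(ts, "protein").y[20])
```

```
chyme at 160 min: 14.0 g
protein retained at 20 min: 81.67 %
```

14 g is the closed-form balance 110 + 80 − 8×22; 81.67% = 100·(1 − 22/120)
is the share left after the first well-mixed withdrawal.

### Command line

```bash
igastro synth --n 2 --seed 1 --out bundle/        # synthetic study bundle
igastro pipeline --bundle bundle/ --out results/  # indices → fits → correlations → bands
igastro fit --retention bundle/retention.csv --out fits.csv
```

File schemas are documented with examples in `docs/FORMATS.md`; the model
and its numerical choices in `docs/methods.md`.

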