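# Methods

This note documents the models implemented in `igastro`, the assumptions
behind them, the defaults of the synthetic-data generator, and the numerical
choices that were genuinely open.

## Gastric mass-balance model

The stomach compartment is a single well-mixed reservoir with one
sieve-retained side pool per nutrient. State pools are water (lumping all
non-protein, non-lipid mass), protein and lipid; a sub-ledger tracks how
much of the water was contributed by secretion (used for dilution
correction in densitometry).

Assumptions:

* **Density 1 g/mL for every stream**, so the protocol's mixed use of grams
  and millilitres (22 g vs 22 mL aliquots, mL/min secretion rates) is
  consistent. All bookkeeping is in grams.
* **Secretions are nutrient-free.** Enzymes are protocol metadata
  (activities delivered), not reacting species: hydrolysis is quantified
  only through the densitometry module, never inside the mass balance.
* **Well-mixed emptiable phase.** Each aliquot has exactly the emptiable
  phase's composition. Curd — the sieve-retained fraction — is excluded
  from the emptiable phase and never emptied.
* **Event ordering** at an emptying time is empty → record → secrete: the
  aliquot precedes that instant's secretion increment. This makes t = 0
  retention exactly 100% and gives the first event its 120 g of chyme.
* If less than the scheduled mass is emptiable, the event drains the
  emptiable phase to zero and logs a warning (the real device's behaviour
  in this regime is unknown; draining is the conservative reading of a
  fixed withdrawal schedule).

**Curd time course.** Coagulation is modelled phenomenologically per
nutrient as a saturating fraction

    f(t) = plateau · (1 − exp(−rate · (t − onset)))   for t > onset, else 0

with profile-specific onset (min), rate (min⁻¹) and plateau (–). The hard
onset keeps the early phase exactly curd-free, which makes the zero-curd
invariants (protein and lipid retention identical; regression slope exactly
1) hold to machine precision. The fraction is applied instantaneously at
each emptying event — the emptiable share of a nutrient is (1 − f(t)) of
its current total — rather than integrated as a separate pool. This keeps
mass closure exact and makes retention monotone in f by construction.
Casein-dominant defaults: early onset (15 min), high plateau (0.35 protein /
0.28 lipid); whey-dominant: late (80 min), low (0.08 / 0.10);
biopolymer-stabilized: protein negligible (0.02), lipid moderate (0.25).

**Numerical grid.** Union of a 1-min base grid, all emptying times
(t = interval, 2·interval, …) and the sampling times; points closer than
10⁻⁶ min are merged so float-accumulated event times cannot collide with
base-grid points. Mass conservation
(meal + basal + secreted = chyme + Σ emptied) is verified to 10⁻⁹ g across
randomized protocols in the test suite.

**pH model.** A deliberately simple linear titration with a floor:
pH(t) = max(min_pH, pH₀ − acid(t)/(capacity · protein(t))), with acid
delivered in proportion to the SGF flow. It is used only for qualitative
ordering — a higher buffering capacity (casein-dominant systems, with their
micellar calcium phosphate) yields a pointwise higher trajectory — and is
never fitted to measured pH data. `BufferingParams.initial_ph` defaults to
6.8, a typical reconstituted-formula pH.

## Particle-size metrics

PSDs are binned relative volume densities over strictly increasing diameter
bin edges, normalized to 1 on construction. Bin midpoints are **geometric
means** of the edges, matching the log-spaced binning of laser-diffraction
instruments (arithmetic midpoints differ by <1% at typical resolution; the
geometric choice is fixed and documented). d₄,₃ is the volume-weighted mean
of the midpoints, algebraically identical to the Σnᵢdᵢ⁴/Σnᵢdᵢ³ number-moment
ratio because volume weights are ∝ nᵢdᵢ³.

AI and CI are computed strictly within one dispersant dialect (water and
SDS+EDTA respectively; mixing dialects raises an error), relative to the
undigested formula at t = 0 — not the formula + basal SGF mixture. Negative
values (noise) are reported as-is with a warning, never clamped. When both
chyme and emptied digesta sizes are available, the chyme (gastric-content)
d₄,₃ is the one the indices use.

Flow curves are classified from an OLS fit of log η on log γ̇; the flow
index n within ±0.05 of 1 is called Newtonian (no published threshold
exists; 0.05 is configurable).

## Retention kinetics

The modified power-exponential model is implemented as
y(t) = α₀·exp(−(κt)^β) — the form under which κ is a per-minute rate for
any β — with the alternative α₀·exp(−κ·t^β) behind `form="rate_power"`.
α₀ is fixed at the observed t = 0 value by default (relative retention);
β is a free shape parameter, reported but typically a nuisance. Fitting is
bounded nonlinear least squares (κ ∈ (10⁻⁶, 1), β ∈ (0.1, 5)), initialized
from the log-linear slope of y/α₀ with β₀ = 1, unweighted (no variance
model is assumed for the observations). Standard errors come from the
Gauss–Newton covariance (J'J)⁻¹·RSS/(n−p). Noiseless curves are recovered
to better than 10⁻⁶ relative across κ ∈ [5·10⁻³, 2·10⁻²] and β ∈ [0.6, 2];
under 2% observation noise on 6 points the κ estimator's bias is below 5%
(500-replicate Monte-Carlo check in the suite). The half-emptying time is
t½ = (ln 2)^(1/β)/κ.

Degenerate inputs: constant retention raises an error (no decay to fit);
a non-converged optimizer is flagged on the results object rather than
raised.

## Two-stage analysis and regressions

The stage boundary in index-vs-emptied data is assigned by an **index
floor** (default 0.5): points at or below the floor form the stage-1
plateau, the rest are fitted by OLS, and the stage-2 line's x-intercept
(−intercept/slope) is the destabilization onset in % emptied. The boundary
in the underlying phenomenon is descriptive, not algorithmic, so the simple
thresholded fit is the default; an SSE-minimizing grid search over split
points (`fit(method="grid")`) is provided for sensitivity analysis. Fewer
than two stage-2 points, or none in stage 1, yields a flagged degenerate
fit, not an exception.

Regression direction is lipid emptied (y) on protein emptied (x), with free
intercept. Biopolymer-stabilized samples are excluded from two-stage AI/CI
fits by default — their large initial particle size makes the normalized
indices uninformative — but they keep their own group in the protein–lipid
regressions.

In the pipeline, the % emptied at PSD sampling times is evaluated from the
fitted retention model (retention is observed on the emptying grid, sizes
on the sampling grid; the fitted curve is the natural interpolant).

## Densitometry

Residual intact protein is intensity(t)·DF(t)/intensity(0) per band. The
dilution factor DF(t) is taken from the simulator's mass ledger —
chyme mass over chyme mass with resident secretion removed — because
secretion and emptying interact (the factor is 120/110 ≈ 1.091 just before
and just after the first event, since proportional withdrawal preserves the
ratio). Without a simulator run, users supply factors explicitly. Bands
with zero t = 0 intensity are undefined (NaN), not zero; residuals above 1
are retained with a warning. The default convention is dilution-corrected
absolute intensity; per-lane total normalization is left to the caller.
Hydrolysis half-times are linear-interpolated first crossings of
residual = 0.5, censored when never reached within the window.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes:

* **Initial PSDs** are lognormal volume densities. Monomodal profiles are
  calibrated so the analytic volume mean (median·exp(ln²GSD/2), GSD 1.5)
  equals the profile's initial d₄,₃ anchor — 0.78 µm (water) / 0.66 µm
  (buffer) for casein-dominant, 0.86 / 0.75 µm for whey-dominant. The
  biopolymer profile is bimodal (fine mode median 1 µm, coarse 200 µm)
  with mode fractions solved analytically for overall means of 59.65 µm
  (water) and 54.62 µm (buffer), so its buffer-dispersed size stays large —
  the signature of thickener-borne, not protein-borne, structure.
* **Coarsening** adds a coarse mode whose volume fraction rises as a
  saturating function after a profile-specific onset: 15 min
  (casein-dominant) vs 80 min (whey-dominant) in water. The buffer dialect
  follows separate, slower coalescence parameters, so flocculation is
  "shed" by dispersion while coalescence persists. The flat-then-rising
  construction produces the plateau-then-linear (hinge) shape of
  index-vs-emptied traces by design.
* **Retention** observations follow the power-exponential model with β = 1
  and per-group mean emptying rates as κ anchors (×10⁻³ min⁻¹):
  casein-dominant 11.0 protein / 9.8 lipid; whey-dominant 16.2 / 15.3;
  biopolymer 16.4 protein with lipid depressed to 11.0. Noise is additive
  Gaussian, σ = 2% by default (no variance model is published for such
  observations; 2% is a modelling choice recorded in the bundle manifest),
  clamped to [0, 110]%.
* **Band intensities** decay first-order with κ-casein fastest everywhere
  (rate 0.15 min⁻¹ — essentially gone by 15 min, reflecting pepsin's rapid
  cleavage of its Phe–Met bond), β-lactoglobulin slowest, and whey-profile
  rates ≥ casein-profile rates for caseins and α-lactalbumin (less
  aggregated structure, freer enzyme access). Noise is multiplicative
  log-normal (CV 5%), with a noise-free t = 0 column so normalization is
  exact.
* PSD noise is multiplicative log-normal per bin and renormalized
  (additive noise can produce negative densities).

All randomness flows from explicit seeds; identical seeds give identical
bundles. What the generator does **not** emulate: instrument-specific
scattering artefacts, inter-replicate variance structure, creaming or
visual texture, pH feedback on rates. Passing tests on synthetic bundles
therefore demonstrate correctness of the estimators and plumbing under the
stated statistical model, not the field validity of that model.

## Problem sizes

The default test-suite and acceptance runs use one formula per profile
class, 9 retention time points (0–160 min every 20 min), 6 PSD sampling
times with ~120 log-spaced bins, 100 randomized protocols for the
conservation sweep, and 500 Monte-Carlo replicates for the κ-bias check —
sizes chosen to mirror the study design while keeping a full run in the
order of seconds.

## Known limitations

* The pH model is qualitative; it should never be compared numerically to
  measured profiles.
* The curd model is phenomenological: it reproduces retention behaviour,
  not coagulation mechanism, and its parameters are not identifiable from
  retention data alone.
* The two-stage fit's floor default (0.5 index units) suits index scales
  where destabilization reaches O(1–40); data on other scales need an
  adjusted floor or the grid method.
* Binned d₄,₃ carries a small discretization bias relative to the analytic
  volume mean (well under 0.1% at the default 100–150 bins per 3–5
  decades); tests and calibration targets account for it.
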