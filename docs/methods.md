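# Methods

`pestimix` re-implements, as a tested and seeded pipeline, the analysis of a
soil microcosm experiment in which up to ten currently used pesticides are
applied to grassland soil — individually, as random five-pesticide mixtures,
or as the full ten-pesticide panel — either abruptly (one pulse) or gradually
(five steps), and the consequences for litter decomposition and soil
aggregation are quantified with bootstrap effect sizes and multi-stressor
null models.

## Experimental design model

The pesticide catalogue holds ten active ingredients (two insecticides, four
fungicides, four herbicides) with their maximal soil concentrations measured
across 280 conventionally managed European fields; those maxima, in ng a.i.
g⁻¹ soil, are the cumulative doses applied. The factorial design crosses
pesticide richness (0, 1, 5, 10) with application rate:

- **abrupt** — the full dose of every pesticide in the unit's composition in
  a single application on day 20 of the 50-day incubation;
- **gradual** — one fifth of each dose every 10 days (days 10–50).

Both rates deliver the same cumulative dose (the same area under the
exposure curve); this is enforced structurally and checked exactly in the
tests. Abrupt and control units receive matched solvent–water handling on
the non-dosing days. Richness-5 arms draw an independent uniform 5-subset of
the panel for every replicate (duplicates across replicates allowed);
richness-1 arms repeat one pesticide; richness-10 arms use the full panel.

Default replication: 20 per five- and ten-mixture arm per rate, 20 controls,
and 5 per single-pesticide arm per rate. The source design's single-arm
"n = 10" is ambiguous (10 units per rate vs per pesticide), so replication
per single arm is configurable, with a `paper_layout` option giving one unit
per pesticide per rate. Four solvent-check arms (acetone, tween, water,
combined; n = 5) are included and are effect-neutral by default. Application
volumes (1 mL per event) are bookkeeping only.

## Response variables

- **LD** — litter decomposition, the mass-loss fraction of a 300 mg green-tea
  bag, 1 − final/initial (the remaining fraction is also exposed). Reported
  as mass loss so that "mixtures depress decomposition" carries a negative
  sign.
- **WSA** — percent water-stable aggregates from wet sieving of a 4.0 g
  rewetted sample: 100 · (stable − coarse)/(4.0 − coarse), where coarse
  matter is debris and sand > 0.25 mm.
- **MWD** — mean weight diameter (mm) from dry sieving through a
  2/1/0.25/0.1 mm stack under a 4 mm pre-sieve: Σ x̄ᵢwᵢ with wᵢ the mass
  proportion in class i and x̄ᵢ the class-midpoint diameters
  (3.0, 1.5, 0.625, 0.175, 0.05 mm; configurable via `SieveSpec`).
- **pH** — mean of a triplicate reading of a 1:5 CaCl₂ suspension.
- **EC** — electrical conductivity of a 1:5 soil:water suspension, carried
  through unchanged (no formula applies).

## Synthetic data generator

No raw variances or replicate tables are assumed; the generator produces
replicate-level raw measurables with the structure the analysis needs. For
composition S at rate r the expected response is

    μ_p · (1 + a_r · (Σ_{i∈S} e_{p,i} + γ_p · max(0, |S| − 1))),

with a_abrupt = 1, a_gradual = λ_p ∈ (0, 1]; Gaussian noise is added and the
value clamped to the response's valid range (clamps are logged). Targets are
then inverted into raw measurables — tea masses, wet-sieve masses (with
coarse matter from a truncated normal, mean 0.6 g, SD 0.15 g, bounds
0.2–1.2 g), dry-sieve fraction masses, pH triplicates — so the metric
formulas recover them; with zero noise the round trip is exact to machine
precision. MWD inversion uses a convex combination of a coarse-heavy and a
fine-heavy reference distribution; targets outside the attainable band
(≈ 0.44–1.79 mm with the defaults) raise an error naming the replicate
rather than clamping.

The `paper_like` preset encodes the qualitative field pattern: six
pesticides stimulate decomposition (+6% each), imidacloprid stimulates WSA,
napropamide and metrafenone stimulate MWD, and a negative interaction slope
(γ_LD = −0.07, γ_WSA = −0.05, γ_MWD = −0.02 per pesticide beyond the first)
turns joint effects negative; pH drifts basic and EC declines with richness;
gradual application attenuates all effects (λ = 0.6). Baselines
(LD 0.55, WSA 55%, MWD 1.0 mm, pH 6.8, EC 60) and noise SDs (0.03, 3.0,
0.05, 0.05, 3.0; triplicate pH SD 0.02) are stipulated to give visibly
overlapping but distinguishable arms at n = 20 — the source reports no raw
variances, so these are modelling choices, not estimates. The `null` preset
sets γ = 0 and λ = 1, which makes the generator *exactly additive* on the
mean-difference scale: it is the calibration reference for the null models.

Because the attenuation multiplies the whole effect term, gradual single
applications with positive effects sit *below* their abrupt counterparts;
the generator reproduces attenuation of magnitude, not the observed
gradual-over-abrupt advantage for single pesticides, which under this model
would require negative abrupt single effects. This is a known limitation of
the preset, not of the estimators.

## Effect estimation

Effect sizes are unpaired mean differences (treatment − reference), with the
point estimate computed exactly and a 95% CI from 5000 stratified bootstrap
resamples (groups resampled independently with replacement, sizes
preserved). The CI method defaults to bias-corrected-and-accelerated, with
plain percentile as an option; both are tagged in the output. The pooled
"one" category aggregates all single-pesticide replicates. Rate contrasts
(gradual − abrupt per richness level) are unpaired at the unit level since
arms, not units, are paired. A richness trend is the OLS slope of each
response on richness (0/1/5/10) with a case-resampling percentile bootstrap
CI; resamples collapsing to a single richness level are redrawn.

## Null models and interaction calls

Single effects enter as absolute mean differences from control,
d_i = mean_i − μ_c. Predicted joint effects for composition S:

- additive: Σ d_i
- multiplicative: μ_c · Π (1 + d_i/μ_c) − μ_c  (undefined at μ_c = 0;
  factors < 0, implying a response sign flip, are allowed but logged)
- dominative: the d_i of maximal |d_i|, sign preserved; ties go to the
  pesticide earliest in catalogue order (deterministic and documented).

All three coincide on singletons, and additive and multiplicative agree to
first order in the proportional effects. Five-mixture predictions are the
replicate-weighted average over the arm's realized compositions (an
`expected_subset` mode averages over all subsets instead). CIs come from a
nonparametric bootstrap (1000 iterations, percentile 2.5/97.5): each
iteration resamples the control and every single arm, recomputes μ_c, the
d_i, and the (composition-averaged) prediction. Iterations whose resampled
μ_c is exactly zero are redrawn for the multiplicative model and counted.

The interaction call forms the joint bootstrap distribution of
delta = (mixture mean − μ_c) − prediction, resampling the mixture arm, the
control (shared within an iteration between the observed effect and the
prediction, emulating a coherent re-run of the experiment), and the single
arms. Verdicts: **consistent** if delta's 95% CI covers zero; otherwise
**synergistic** if the deviation points in the direction of the observed
joint effect (the mixture is more extreme than the null model allows —
including the canonical case of a negative joint effect where the singles
predict a neutral-to-positive one), else **antagonistic** (the interaction
damps the joint effect). This directional reading matches the multiple-
stressor literature's use of "synergism" for joint effects stronger than
predicted; a magnitude-only comparison of |observed| vs |predicted| would
mislabel sign-reversing synergy as antagonism.

## Pipeline and reproducibility

`run_pipeline` chains design → simulate (or load a compatible raw CSV) →
metrics → effects → null models → report. A single global seed spawns
independent per-stage seeds, so identical configs give byte-identical CSVs;
every CSV carries a provenance header (package version, config hash — output
location excluded — and seed). Stage failures abort with the stage name and
the offending record. Figures are plain matplotlib exports, off by default.

## Verification

The test suite checks, among others: the catalogue constants and layout
counts; exact dose conservation for every arm; the WSA/MWD formulas against
direct evaluation over thousands of random legal inputs with their bounds;
the zero-noise generator round trip (< 1e-9); 93–97% empirical coverage of
the bootstrap CI over 500 simulated two-group experiments (n = 20); the
dominative model against a brute-force scan and the additive–multiplicative
first-order bound; bootstrap CI endpoints against exhaustive enumeration of
all resamples on groups of size ≤ 3 (compared through cumulative
probabilities, since the discrete resample distribution has coarse atoms);
false-synergism rate ≤ 7.5% under the exactly additive generator and ≥ 80%
synergism detection for the ten-mixture under the paper-like preset (200
simulated experiments each, n = 20 mixture/control and 5 per single arm);
and byte-identical pipeline re-runs. Simulation sizes (200–500 replicates,
1000–5000 bootstrap iterations) keep the full suite under a minute on one
CPU while leaving the Monte-Carlo error well inside every asserted band.

Passing these checks shows the estimators and models behave correctly under
the generator's assumptions — independent Gaussian noise, effects
multiplicative in the baseline, interactions linear in richness. Real soils
add correlated errors, heteroscedasticity, pesticide-specific interaction
structure, and degradation kinetics, none of which the generator emulates;
conclusions about real data rest on the estimators, not on the preset.

## Known limitations

- The generator's rate attenuation cannot reproduce a gradual-over-abrupt
  advantage for positively acting single pesticides (see above).
- EC has no mechanistic model; it is a passthrough with a trend imposed by
  the preset.
- Tea-bag decomposition is single-timepoint mass loss; decomposition-rate
  constants (k, S of the tea-bag protocol) are out of scope.
- The loader accepts only the package's own raw CSV schema; external tables
  must be mapped to it first.
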