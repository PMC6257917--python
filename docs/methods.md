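# Methods

This note documents the models, the synthetic survey generator, the
numerical choices and the known limitations of `sbtindex`.

## Survey structure and strip rule

The unit of effort is a *leg*: a stretch of transect searched by one plane
(one pilot–spotter pair) within one area on one flight, with environmental
readings attached.  A *sighting* is a spotter-defined detection event of one
or more schools; each school carries a perpendicular distance from the line
and one biomass estimate (tonnes) per estimating observer.  Strip-transect
logic: a sighting is analysed iff at least one of its schools lies within
the half-width (default 6 nm), and a retained sighting keeps all its schools
— the sighting, not the school, is the detection unit, and detection inside
the strip is treated as certain.  Effort and sightings are then accumulated
to flight×area cells (distances and counts summed, environmental readings
averaged, zero-sighting cells kept).

## Observer calibrations

**School sizes.**  Under multiplicative observer error, the log-ratio of two
observers' estimates of the same school is Gaussian with mean
`log β_A − log β_B`.  Per-school log-ratios are regressed by least squares on
a signed incidence design with the reference observer's column dropped
(`β_ref ≡ 1`); `β_obs = exp(coef)`, SEs by the delta method.  Identifiability
requires the observer-overlap graph to be connected; observers with no
co-estimated schools at all (a pilot who only ever flew with non-estimating
trainees) keep `β = 1` and their estimates are used unadjusted.  Adjustment
*divides* raw estimates by `β_obs` — `β = 0.81` means a 19 % underestimator,
and dividing restores the reference scale — then a school's biomass is the
mean of its adjusted estimates, treated as exact downstream.

**Pair sighting efficiency.**  Within one flight both spotters face the same
fish and conditions, so conditioning each flight's sighting total on the
split between the two spotters cancels the flight nuisance effect exactly,
leaving a binomial with log-odds `log e_A − log e_B`.  A binomial GLM on
signed incidence rows gives per-observer log spotting rates; a pair's score
is the *sum* of its members' rates (two sets of eyes), normalized so the
best pair is exactly 1.  Only relative efficiency is claimed — the two
spotters share a cockpit and are not independent, so no absolute detection
probability is attempted.

## The penalized GLMM engine

Both component models are log-link GLMs with categorical year/month/area
main effects, centred linear covariates, known offsets, and Gaussian random
effects on the four interaction crossings.  Each random block `Z_m b_m`,
`b_m ~ N(0, σ²_m I)`, is fitted as a ridge penalty `λ_m‖b_m‖²` with
`λ_m = φ/σ²_m`:

* inner loop — penalized IRLS on the working response with step-halving, so
  the penalized deviance is non-increasing within the loop (asserted in
  tests); convergence at relative change < 1e-8 (a flat-tail safeguard
  accepts < 1e-6 per iteration when the maximum iteration count is hit);
* outer loop — REML-type variance-component updates in the Fellner–Schall
  form `λ_m ← φ (q_m/λ_m − tr(A⁻¹)_mm) / ‖b̂_m‖²` (A the penalized normal
  matrix), damped 60 % in log space to break the 2-cycles the raw update can
  fall into; `φ` by the Pearson estimator with effective degrees of freedom
  `edf = tr(A⁻¹ C'WC)`; λ clipped to [1e-7, 1e7].

The joint coefficient covariance is the penalized ("Bayesian") form
`φ A⁻¹`; random-effect combinations never observed are carried as columns so
their coefficients are exactly zero with the prior variance — this is how
strata with little or no effort are predicted.  Predictions are conditional
(random effects included), with SEs from the joint covariance.

The Tweedie density (1 < p < 2) is evaluated by the Dunn–Smyth series with
an adaptive index window (terms kept above 1e-10 of the peak; checked in
tests against an independent series implementation and by quadrature).  The
power p is profiled: full fits on a grid, scored by the series likelihood at
the Pearson dispersion, the maximizer refined by bounded search to 1e-3;
search restricted to [1.01, 1.99].  AIC uses `−2ℓ + 2(edf + #family
parameters)`; with random-effect structure held fixed this makes
fixed-effect comparisons well defined, which is how the backward covariate
screen uses it (fit full model, drop one candidate at a time, retain if the
drop raises AIC; Wald z-tests reported alongside; for the Tweedie model p is
profiled once on the full model and held fixed across comparison refits).
Model diagnostics use simulation-based randomized-quantile (PIT) residuals:
the position of each observation among 250 draws from the fitted
distribution, tie-randomized, uniform under a correct model.

## Index and uncertainty

Reference conditions default to the unweighted mean of each covariate over
all effort cells pooled across years, with the best pair (`Obs = 1`) and
100 nm of effort (the distance and pair choices are pure gauge: they shift
all years equally and cancel in the mean-one index).  Per stratum,
`Â = Ŝ·B̂`; annually, `Â_i = Σ_j Σ_k w_k Â_ijk` (equal area weights by
default — the real stratification's relative areas are not published);
`Î_i = Â_i/mean(Â)`, so `mean(Î) = 1` to 1e-9 by construction.

Variance is assembled in two parts that together equal the full
delta-method quadratic form:

1. *Conditional on the environmental coefficients γ*: the coefficient
   covariance is partitioned, and the cross-stratum conditional covariance
   of the linear predictors `Cov(η) = C_u (V_uu − V_uγ V_γγ⁻¹ V_γu) C_u'` is
   propagated through `V_cond(i) = a_i'(Cov_logB + Cov_logS) a_i`,
   `a_i = w_k Â_ijk`.  The off-diagonal terms matter: strata within a year
   share the estimated year effect, and treating them as independent
   (`Σ w_k² Var(Â_ijk)`, available as the diagonal option) understated the
   realized annual log-error SD by roughly 40 % in calibration studies.
   The two component models are fit to different responses and are treated
   as independent of each other.
2. *Environmental*: `A_i(γ)` is re-evaluated (prediction only, no refit)
   under perturbed coefficients via each stratum's stored sensitivity
   `dη/dγ = c_γ + c_u V_uγ V_γγ⁻¹` — the direct term plus the induced shift
   of the remaining coefficients; central differences with step
   `h = max(1e-4, 1e-3|γ̂|)` give gradients, and
   `V_env(i) = g_i' Cov(γ̂) g_i`.

`CV = √V_total/Â`, and 95 % bounds are `exp(log Â ± 1.96·CV)`; the CVs
attach unchanged to `Î` (normalization treated as a fixed rescale; the
between-year covariance through the shared mean is not propagated).
Uncertainty in the pair-efficiency offsets and in the school-size
calibration is deliberately **not** propagated — the efficiencies enter as
known offsets.  This is the main reason realized interval coverage in
simulation sits below nominal (roughly 0.75–0.92 depending on the replicate
window, typically ≈0.85–0.90, instead of 0.95), concentrated in occasional
whole-series shifts when the calibration of a heavily-used pair errs.

## The synthetic survey generator

No survey data are bundled, so the generator is first-class, tested code.
Its defaults emulate the real 1993–2009 two-spotter programme:

* the published spotter-pair roster by year; trainee spotters (codes 1, 2,
  6, 9) make no biomass estimates;
* observer size effects from the published calibration table; single-school
  estimate noise lognormal with CV 0.25 (chosen so that recovered β SEs
  match the published 0.01–0.02);
* individual spotting rates backed out from the published pair-efficiency
  table by least squares on `e_pilot + e_spotter = eff` (the additive
  decomposition reconstructs the published table to within 0.01); a
  sighting's maker is drawn with probability proportional to rates;
* environmental covariates drawn per flight (SST N(20, 1.4²) with a
  +0.12 °C/yr trend matching the published ≈2 °C rise; wind truncated
  normal; haze/swell/shadow categorical) with small within-flight jitter on
  the continuous variables per area;
* linear effects at the published values (BpS SST 0.326; SpM 0.328, −0.305,
  −0.137, −0.193, −0.053); year effects engineered so the standardized index
  is high 1993–1996 and ≈4× lower after, split evenly between the two
  components — together with the SST trend this reproduces the published
  pattern of roughly flat raw sighting rates and a ≈1.5× decline in mean
  sighting biomass while the standardized index falls 4×;
* random interaction effects drawn once per survey at SDs 0.08–0.20;
* per-sighting biomass Gamma (shape 1.1, mean ≈88 t at reference), split
  into `min(Geometric(0.4), 76)` schools by a symmetric Dirichlet(1) —
  the within-sighting split is a stand-in, as no distribution is published;
* ≈3 % of sightings placed entirely outside the strip to exercise the
  filter; school distances otherwise uniform within the strip.

**Integer counts.**  The sighting count of a cell must be an integer, but a
compound Poisson–gamma total is continuous, and using its Poisson component
alone would give the wrong mean.  Cell counts are therefore drawn as a
Poisson–gamma mixture with per-cell moments matched exactly to the Tweedie
law (`E = μ`, `Var = φμ^p`, exact zeros).  Consequence: the *likelihood*
shape at integers differs from a true Tweedie, and the profiled power on
survey counts lands near 1.05 rather than the generating 1.13 — the
engine's power recovery is therefore validated on exact compound
Poisson–gamma draws, where p̂ = 1.13 ± 0.05 at n = 3000.  Index recovery is
insensitive to this (the mean model is correct either way).

What the generator does **not** emulate: spatially continuous density,
weather-driven effort cancellation (effort imbalance arises only from the
random flight/area draws), school-size/distance interaction in sighting
definition, and measurement error in the environmental readings.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to real-data
misspecification.

## Validation studies and problem sizes

Replicate-survey studies run the full pipeline at the default (full-scale)
configuration: 13 years × 3 months × 18 flights × 5 areas searched per
flight ≈ 3 510 effort cells and ≈1 000–1 300 in-strip sightings per survey —
comparable to the real programme's 105 000 nm and 1 324 sightings.  The test
suite uses 40 replicates and the acceptance script 30 (a few seconds per
replicate with the coarse Tweedie grid (1.05, 1.15, 1.3, 1.5) and no
golden-section refinement; the refinement moves the index negligibly).
Measured at these settings: median per-year |Î/Î_true − 1| ≈ 0.14, 95 % CI
coverage of the annual totals ≈ 0.85–0.92, and year-rank concordance 0.99
for year pairs whose true index differs by more than 1.5× (0.82 over all
pairs — later years are engineered near-ties, as in the real series, so
their ordering is genuinely undetermined at the achievable error level).
Coverage is evaluated against the generator's annual totals at reference
conditions with the true best pair as `Obs = 1`; under this definition the
standardization gauge chosen by each run (estimated best pair, reference
observer scale) contributes real, unpropagated error to A_i — it cancels in
the normalized index.  Pooled coverage varies by roughly ±0.07 between
30-replicate windows because these gauge errors shift whole series at once.
Faster unit tests use a reduced 6-year × 5-area configuration with the same
structure.

## Known limitations

* Pair-efficiency and size-calibration uncertainty excluded from the CIs
  (see above) — the dominant source of the coverage shortfall.
* Environmental effects strictly linear; no covariate interactions or
  smooths.
* Equal area weights by default; supply measured relative areas via
  configuration for real use.
* The Tweedie power reported from integer count data is an effective, not a
  structural, parameter (see the integer-count note).
* CSV-mode ingestion expects model-ready tables (strip-filtered, adjusted
  biomass); the raw-records path is exercised via the simulator.
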