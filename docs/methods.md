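# Methods

This note documents the statistical machinery implemented in `foldbase`,
the assumptions behind it, and the choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Coordinates and the folding basis

All analysis happens on base-10 logs of the primary variables: average
cortical thickness `T` (mm), total pial area `A_T` (mm²) and exposed hull
area `A_E` (mm²), one observation per subject × hemisphere × ROI.
Hemispheres are treated as separate observations throughout (no left/right
averaging); ROIs are `hemisphere` plus four lobes, with `lateral` accepted
as an input alias of `parietal`.

The folding basis is the linear map

| axis | (x_AT, x_AE, x_T2) coefficients |
| --- | --- |
| K | (1, −5/4, 1/4) |
| S (orthogonal) | (3/2, 3/4, −9/4) |
| S (printed) | (3/2, −3/4, −9/4) |
| I | (1, 1, 1) |

Two S conventions exist in the literature.  The orthogonal form is the
unique direction (up to scale) perpendicular to both K and I, which is the
stated geometric construction of the axis; the printed form — identical
except for the sign of the `x_AE` term — is not perpendicular to I (dot
product −3/2).  Because the two cannot both be right, **both are
implemented**; `orthogonal` is the default and every output carries an
explicit `s_variant` tag.  The basis matrices are invertible in either case
(determinants 63/8 and 27/4), and the inverse map is used by the synthetic
generator to construct morphometrics from latent (K, S, I).

The scaling exponent α is estimated by ordinary least squares of
`log10(A_T √T)` on `log10(A_E)` — each hemisphere row one point — with a
Student-t 95% CI on the slope.  No errors-in-variables correction is
applied: the estimator is the field's standard regression, and the
synthetic scenarios keep the regressor noise-free so the estimator is
exactly unbiased there.

## 2. Harmonization model

For each primary variable Y the multisite model is the linear mixed model

    log10 Y = a·age (+ ROI and age×ROI fixed terms) + u_{sample:ROI} + ε
    u ~ N(0, σ_Sample²),   ε ~ N(0, σ_Natural²)

fit by REML (statsmodels `MixedLM`; REML is chosen over ML for unbiased
variance components).  ROI main effects and the age×ROI interaction are
included automatically whenever more than one ROI is present — the random
grouping is always the sample×ROI cell.  Only healthy-control rows inform
the fit by default; patient rows are shifted using the control-derived
prediction for their site (a flag allows all-group fitting).

Harmonization subtracts the predicted random intercept (a BLUP, i.e. a
shrinkage estimate of the site's systematic shift) from the log10 value of
each row.  Because K, S, I are fixed linear combinations of the log
variables, harmonizing T, A_T, A_E and deriving K/S/I afterwards is exactly
equivalent to shifting K/S/I directly — the pipeline therefore harmonizes
the three primaries and derives the folding variables from the result
(direct harmonization of any single column remains available for
exploration).  Note that the folding variables only decouple from site
structure once *all three* primaries are harmonized; deriving K from a
partially harmonized table leaves area offsets confounded with the sites'
age windows.

Degenerate cases are reported, not hidden: a single-sample fit falls back
to OLS with all shifts pinned at zero (`single_sample` flag), and a
random-intercept variance estimated at the boundary (0) is returned with a
`boundary` flag because the uncertainty budget consumes it.  De-aging
(`value' = value − a_ROI·(age − reference)`) uses the per-ROI slope.

## 3. Uncertainty budget

Three uncorrelated tiers are combined in quadrature,
`σ_X = sqrt(σ_Natural² + σ_Random² + σ_Sample²)` (implemented with `hypot`
for under/overflow safety):

* **σ_Natural** — the mixed model's residual SD: inter-individual
  biological spread plus anything else the trend does not capture.
* **σ_Random** — repeat-acquisition noise: per-subject sample SD (n−1
  denominator) over repeated scans, averaged over subjects without bias
  correction.  With 3 repeats this mean-SD estimator is biased low by
  c4(3) ≈ 0.8862; the bias is documented and asserted in the tests rather
  than corrected, matching how such repeat-scan summaries are usually
  reported.  The default design is 50 subjects × 3 repeats.
* **σ_Sample** — the random-intercept SD: the systematic between-site
  shift.

For K, S, I and GI, σ_Random is obtained by mapping each repeat scan
through the change of basis and taking within-subject SDs on the folding
scale (propagation through the transform); refitting the budget directly
on folding columns is also possible since `fit_joint_trend` accepts an
identity transform.  The optional percent column divides σ_X by the
control fixed intercept at age 0 (reference age configurable, and echoed
in outputs, since percent figures are meaningless without it).

A caution on recovery checks: with J sites the SD of an SD estimate scales
like 1/√(2(J−1)) — 25% relative at J = 9 — so σ_Sample is validated
against the *realized* spread of the drawn site offsets (the quantity the
model can identify), while σ_Natural, estimated from thousands of rows, is
validated against the generating value.

## 4. Trend-model selection by marginal likelihood

Candidate models for the per-sample age trend of a log variable:

| id | mean | dispersion | free parameters (J samples) |
| --- | --- | --- | --- |
| base | a·x + b_j | σ_j per sample | 1 + J + J |
| i | a·x + b_j | common σ | 1 + J + 1 |
| ii | a_j·x + b_j | σ_j per sample | 3J |
| iii | a_j·x + b_j | common σ | 2J + 1 |
| iv | c·x² + a·x + b_j | σ_j per sample | 2 + J + J |

The evidence of each model is the prior-weighted integral of the Gaussian
likelihood over all free parameters.  Given the shared parameters, the
per-sample integrals factorize, so the engine nests Gauss–Legendre
quadrature: an outer grid over at most two shared dimensions and per-sample
inner grids of at most three dimensions, evaluated from sufficient
statistics (the residual sum of squares is quadratic in the parameters, so
each grid point costs O(1) regardless of sample size).  Outer blocks are
chunked to bound peak memory.  The numerical error estimate is the change
in log-evidence under a 1.5× grid refinement; the engine reproduces the
closed-form Gaussian-integral oracle of the conjugate 1-D case to ~1e-15
and the default node counts (32–48 per dimension) keep refinement shifts
well below the evidence gaps they need to resolve.

Priors are uninformative by construction and data-driven: uniform for
location parameters over OLS estimate ± 10 standard errors, log-uniform
(1/σ) for dispersions over [s/10, 10s] around the OLS residual SD.  The
realized ranges are recorded on the model object so sensitivity to
doubling them can be reported; a warning is flagged whenever more than 1%
of posterior mass sits on the edge nodes of any range (the signature of a
range that clips the likelihood).  Odds are evidence ratios and posterior
model probabilities assume a uniform model prior.  Leave-one-out parameter
posteriors reuse the same machinery with the target pinned on a grid,
returning the mode (parabolic refinement) and the central 95% credible
interval from the trapezoid CDF.

## 5. Trajectories, contrasts, per-decade α, baselines

Rates are per-(variable, group, ROI) least-squares lines of value on age.
T, A_T, A_E are fit on the back-transformed harmonized scale so the slopes
read in natural units per year; K, S, I, GI are fit as-is.  (The
alternative — log-scale slope × ln10 × value — agrees to first order; the
back-transformed route was chosen because rate tables conventionally print
natural units.)  Percent-per-year divides the slope by the fitted value at
a reference age, by default the control grand mean age of the input, and
the reference is echoed on every fit because the percentage is undefined
without it.

Group slope contrasts come from the full age×group interaction model per
ROI cell (separate lines per group, pooled residual variance): a Wald t on
slope(g₂) − slope(g₁) with the documented convention that supplying
`("CTL", "AD")` reports AD − CTL.  Adjustments: `none`, `bonferroni`
across all contrasts produced by the call, or `tukey` via the studentized
range with k = number of groups (for k = 2 this coincides with the raw
t-test).  Degenerate cells are skipped with a warning naming the cell,
never imputed.

Per-decade α fits partition ages into [0,10), …, [90,100]; bins with fewer
than `min_n` rows (default 10) are omitted and listed with their counts so
the thin tails of a lifespan sample are visible rather than silently
fitted.  Baseline bands join a trajectory line with a budget:
`value(age) ± σ_X`; under the Gaussian error model the ±1σ band should
cover about 68% of held-out control observations, and the suite asserts a
conservative ≥60%.

## 6. The synthetic-cohort generator

The generator is first-class, tested code: its role is to emulate the
structure of multisite cross-sectional morphometrics with fully known
ground truth.

* **Sites** — the default scenario has 9 samples whose sizes and age
  windows mimic a typical multisite compilation (one large elderly cohort
  with a patient arm, several narrow young cohorts, a few wide lifespan
  cohorts; ~3,400 controls and ~190 patients).  Within-site ages are
  uniform by default (truncated normal available); real cohorts are rarely
  uniform, but no published age histograms are assumed.
* **Site effects** — additive per-(sample, ROI, variable) log10 offsets
  drawn N(0, σ_Sample), or pinned explicitly.
* **Trends** — `log_linear` mode: log10 Y = intercept + slope·age + offset
  + N(0, σ_Natural) per variable and group.  `ksi_latent` mode: latent
  (K, S, I) are group-specific linear functions of age (plus optional
  latent noise/spread) inverted through the folding basis, which gives
  exact control of the scaling structure — constant K yields α = 5/4
  exactly in the noise-free limit.  In this mode Gaussian K-noise is
  realized as noise on log10 A_T, i.e. response noise on `log10(A_T√T)`
  with the regressor `log10(A_E)` clean, which is the configuration the
  exponent-recovery checks specify; S and I noise perturbs the latents
  before inversion.
* **Noise tiers** — defaults (σ_Natural, σ_Random, σ_Sample) =
  (0.1, 0.019, 0.085) in log10 units, with the thickness trend
  −0.0044 log10/yr; these are generator defaults seeded from published
  budget magnitudes, not claims about any real dataset.  The patient group
  is generated with a flat K trend matched to late-life control values,
  rising S and shrinking I.
* **Repeats** — per subject, n repeats of each variable about the latent
  value with sd σ_Random on the log10 scale (default 50 × 3).
* **Determinism** — one root seed, split into named substreams
  (offsets / ages / noise) via `SeedSequence`; the same (spec, seed) pair
  reproduces tables bit-identically and the realized truth (offsets,
  slopes, latents, stream seeds) is returned alongside the data.

What the generator does **not** emulate: non-Gaussian and heteroscedastic
biological spread, scanner-specific multiplicative (scale) effects,
age-dependent variance, longitudinal within-subject correlation, missing
data, and nonlinearity of early-life trends.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every feature of real multisite MRI.

The model-selection scenarios deserve a note: "data generated under the
per-sample-dispersion model" is taken literally, so the common-slope
scenario uses a fixed heteroscedastic ramp of σ_j across the nine sites
(0.045…0.20); with homoscedastic data the common-σ model would — correctly
— win by Occam's razor.  The per-sample-slope scenario likewise uses a
fixed standardized pattern of slope offsets with spread 3× the nominal
slope SE; drawing the offsets at random each replicate would make the
winner a coin flip in a sizeable fraction of replicates purely through the
redrawn truth, which is a property of the scenario, not of the selector.

## 7. Numerical conventions and degenerate inputs

* Logs require strictly positive T, A_T, A_E; offending rows are rejected
  with a reason, and hemisphere rows with A_T < A_E are rejected in strict
  mode (warned in lenient mode) since a folded surface must exceed its
  hull — lobe areas may legitimately violate this after curvature
  correction and are only warned about.
* Round trips: CSV I/O uses 12 significant digits; the K/S/I basis
  round-trips to <1e-10; the two algebraic forms of K agree to <1e-12.
* OLS slopes with <3 distinct ages, all-identical regressors, or empty
  cells raise or skip-with-warning; they are never silently imputed.
* Mixed-model convergence falls back from the default optimizer to
  Powell; remaining warnings are attached to the fit and surfaced in the
  pipeline manifest.
* In quadrature, per-sample OLS quantities used for prior ranges are
  floored (residual SD at 1e-8 of the data scale) so noise-free inputs
  produce usable degenerate-likelihood grids.
* Problem sizes in the test suite (9 × 300-row recovery cohorts, 20-replicate
  win-rate simulations, 500-hemisphere exponent replicates) were chosen as
  the smallest designs whose Monte-Carlo error is comfortably below each
  assertion's tolerance.

## 8. Known limitations

* The harmonization cannot identify a global systematic shift common to
  all sites (only relative offsets), and with few sites σ_Sample is pinned
  only up to the realized draw (§3).
* Trend linearity is assumed everywhere; early-life nonlinearity is out of
  scope, and the per-decade α machinery is the intended tool for spotting
  departures.
* The evidence engine integrates at most two shared dimensions by
  quadrature; models with more shared parameters than the implemented
  family would need a different backend.
* σ_Random cannot be decomposed into scanner/field-strength/software
  contributions from the data the pipeline consumes.
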