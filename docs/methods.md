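# Methods

## Model

The unit of observation is one trap-service interval ("sample"). For
each species the expected catch is

    E[y] = days · exp(a₁ + a₂·date + a₃·rain + a₄·deadwood + a_foresttype),

an NB2 log-linear model (Var = μ + μ²/θ) with log effort as an offset.
The model assumes catches are independent across samples given the
covariates, a constant dispersion per species, log-linear covariate
effects, and a time-constant trap efficiency. The covariates:

- **date** — days from a configurable reference instant (default
  2014-09-01T00:00) to the midpoint of the service interval; may be
  negative. A log-linear trend is the only phenology the model carries.
- **rain** — unweighted mean of daily rainfall totals over every calendar
  day whose [00:00, 24:00) window intersects the service interval
  half-openly; partial first/last days count fully. At ~14-day intervals
  the difference from a duration-weighted mean is negligible.
- **deadwood** — per trap, Σ dbh²/distance over dead trees at decay
  level 3 (clearly decaying) in the two 50 × 2.5 m transects, with dbh
  converted from the recorded cm to metres, giving scores of order
  0.01–0.5. A configuration switch (`dbh_unit="cm"`) keeps dbh in cm
  (scores 10⁴ larger, coefficient 10⁴ smaller) for compatibility with
  the cm²·m⁻¹ convention; the two conventions are equivalent up to that
  rescaling. We default to metres because on that scale the strongest
  observed trap score is ≈ 0.27 and the fitted coefficients are O(1–5).
- **forest type** — five levels (primary, swamp, disturbed, clearcut,
  farm), dummy-coded with primary forest as the all-zero reference, so
  each species' primary coefficient is identically 0 and exp(a_type) is
  the catch relative to primary forest.

Samples flagged unusable (damaged, unrepresentative catches) are dropped
first; with weather required, samples whose interval is not fully
covered by daily weather records are dropped too, with one log line per
exclusion. Effort is kept in fractional days throughout.

## Fitting

Coefficients and dispersion are maximum likelihood: damped Fisher
scoring (IRLS) for β given θ, alternating with a bounded profile
maximisation over log θ (θ ∈ [10⁻², 10⁵]; the upper bound is the Poisson
limit), initialised from the count/effort rate and iterated until the
relative log-likelihood change falls below 10⁻⁸ (at most 200
alternations). Fisher steps are limited to 3 units per coefficient per
iteration; a coefficient is clamped at the ±15 cap and *pinned* only
after sitting at the cap for three consecutive iterations, which
separates genuine divergence from transient overshoot. Dummy levels
whose samples catch nothing in total are complete-separation cases,
detected up front, pinned at −15 and flagged; an all-zero species pins
its intercept the same way. Standard errors come from the expected
information (X'WX)⁻¹ of the free columns at the optimum. Species with
fewer than 10 individuals are fitted and pooled into multi-species
statistics but marked `low_n` in all reports.

The fitter is validated two ways in the test suite: against a dense
grid-plus-Nelder-Mead search over (β, θ) on small fixtures (agreement to
10⁻³ in log-likelihood), and against statsmodels' independent
NegativeBinomial implementation on regular designs (agreement to ~10⁻³).

## Significance testing

For a term (date, rain, deadwood, or all four forest dummies jointly)
the statistic is the likelihood ratio between the full model and the
model without the term, per species, and summed over species for the
subfamily-level test. Pairwise forest contrasts use a null model in
which the two levels share one coefficient (merging a level with the
reference drops its dummy). p-values are permutation-style,
(1 + #{resampled ≥ observed})/(B + 1), never 0 and never below
1/(B + 1); no multiplicity adjustment is applied anywhere, so reported
significances may contain false positives.

The null distribution comes from B resampled campaigns (default
B = 999). Four schemes are implemented; the default is the **parametric
bootstrap**: counts are redrawn independently from the per-species null
fits. For species below the low-n threshold the generating model is the
intercept-only fit — a handful of individuals fits the full covariate
set almost perfectly, with interior coefficients overrunning ±10, and
resampling from such a fit produces nonsense campaigns.

Three site-blocked schemes perturb randomized PIT residuals (drawn once
per test, seeded) in whole site blocks: `wild` reflects each site's
residual block by an independent Rademacher sign (u → 1 − u),
`residual` transplants blocks between sites drawn with replacement, and
`permute` transplants them along a site permutation. In calibration
simulations under the default generator (10 heavily unbalanced sites,
site effects on), the parametric scheme was the only one that was both
calibrated and powerful: measured type-I error 0.025 at α = 0.05 over
200 null campaigns, power ≥ 0.9 for every term at the default effect
sizes. Block transplanting is conservative here because unequal donor
and recipient sites force residual rows to be duplicated across traps,
inflating the null tail; sign reflection is calibrated but cannot null
out within-site covariate signal (dead wood varies trap to trap), so it
has almost no power for those terms. The blocked schemes remain
available for sensitivity analysis, and the trade-off matters for real
data: the parametric scheme leans on the NB2 fit absorbing within-site
correlation into θ, which is a cruder shield against site-level
dependence than a well-calibrated block method would be.

Two procedural details make the p-values well-behaved. Resample refits
run through a fixed-budget vectorised batch fitter (warm-started from
the observed fits, with an embedded-null restart whenever the
alternative lands below the null, and fully converged scalar
re-evaluation of the largest statistics); the *observed* statistic used
in exceedance comparisons is computed by that same procedure, so a
resample that reproduces the data ties exactly — the reported LRs are
the fully converged ones. And near-empty species bypass the batch
fitter entirely for an adaptive per-resample scalar fit at the
Poisson-limit dispersion.

`enumerate_null_exact` is the verification oracle: on toys with at most
4 site blocks it enumerates the scheme's full finite assignment set
(2^S sign patterns for `wild`, S^S donor assignments for `residual`)
and returns the exact exceedance proportion, which the Monte-Carlo p
estimates; the identity assignment reproduces the observed statistic,
so the exact p is never 0.

## Synthetic campaigns

The generator emulates a year-long tropical campaign end to end, and its
defaults are the package's study conditions:

- **Layout** — 10 sites, 34 traps: two large primary-forest sites of 8
  traps each (6 primary + 2 swampy), three disturbed sites (2/2/3
  traps), four clearcut former plantations (2/2/2/3), one farmland
  "site" of 2 traps.
- **Calendar** — 2014-09-08 → 2015-09-14; service intervals of 14 ± 2
  days (uniform jitter), per-trap start stagger up to 7 days, intervals
  shorter than 2 days discarded; ~2.2% of samples flagged unusable.
  This yields ≈ 880 usable samples and ≈ 12 000 trap-days.
- **Weather** — zero-inflated gamma daily rainfall with two wet seasons
  (Mar–May, Sep–Nov: rain probability 0.65, Gamma(0.8, 12) mm) and two
  dry seasons (probability 0.25, Gamma(0.8, 6) mm), plus decorative
  min/max temperatures. The fitted model only consumes mean rain, so any
  realistic bimodal driver suffices.
- **Dead wood** — per-trap scores drawn from per-forest-type log-normals
  (log-medians 0.12/0.10/0.07/0.04 from primary to clearcut, log-sd 0.8,
  truncated at 0.8; farmland has no clearly decaying trees at all). The
  transect tree lists are constructed to reproduce each drawn score
  exactly through the dead-wood formula, with living and lightly decayed
  distractor trees around them. The truncation matters: with dead-wood
  coefficients near 4, an untruncated log-normal tail occasionally
  produces traps with implausible hundred-fold catch rates.
- **Species** — six species: four abundant ones with published
  coefficient vectors as the generating truth (their ≈ −12 farmland
  coefficients make farm catches effectively zero, reproducing the
  complete-separation case), and two rare species whose intercepts were
  calibrated by simulation for expected campaign totals of ≈ 6 and ≈ 1
  individuals. Dispersion θ = 2 for abundant species, 1 for rare ones.
- **Dependence** — an optional shared site effect: independent
  N(0, 0.3²) log-scale deviations per (site, species), constant across a
  site's samples, giving within-site correlation for the blocked
  resampling schemes to protect against. Setting `site_effect_sd = 0`
  gives the pure-independence mode used for parameter-recovery and
  coverage checks, which are only well-posed when the data follow the
  fitted model.

Every stage is deterministic given the scenario seed, and all generated
artefacts pass the package's own validation. What passing tests on these
campaigns do *not* show: robustness to spatial autocorrelation between
sites, trap-efficiency decay, non-log-linear phenology, or
misrecorded field data — none of which the generator emulates.

## Problem sizes used in validation

The test suite's statistical experiments use 100 campaigns at 5× the
default layout (the 10-site layout replicated five times) for
recovery/coverage, 200 single-scale null campaigns at B = 199 for
type-I error, 50 campaigns × 4 terms at B = 199 for power, and a
24-sample, 3-site toy for exact enumeration; these sizes give binomial
noise well inside the asserted bands. Production analyses should use
B = 999 (the default).

## Known limitations

- The relative-error target for the *date* coefficient is only met
  pooled across species: the smallest generating date effect
  (0.00197 d⁻¹) carries too little information even at 5× scale for a
  10% relative bound per species.
- With site effects on, Fisher-information standard errors undercover
  (deadwood ≈ 0.81–0.89 at ±2SE) — the model has no cluster term; use
  the resampling tests, not Wald intervals, when clustering is
  suspected.
- The default resampling scheme trades exact within-site dependence
  handling for calibration and power under this design (see above).
- θ is estimated separately under each nested model; on near-empty
  species the profile is flat and θ runs to the Poisson-limit bound by
  design.
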