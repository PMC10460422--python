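# Methods

This note records the modelling choices behind `airburden`: the governing
equations, what the synthetic-data generators do and do not emulate, the
numerical conventions, and the places where the design was genuinely open
and a choice had to be made.

## Burden identity

Attributable deaths are

DAPP = Σ_{a,d} PAF_{a,d} · POP · Rate_{a,d} · AgeP_a,  PAF = (RR − 1)/RR,

over 15 five-year age bands from 25–30 to >95 and six PM2.5-related causes
(COPD, LRI, lung cancer, IHD, stroke, type-2 diabetes).  Ages below 25 are
excluded: the exposure–response evidence base for these outcomes starts in
adulthood.  The PAF is applied at the exposure level directly; no
theoretical-minimum-risk (TMREL) counterfactual is subtracted.  This is
deliberate and documented because comparative-risk-assessment practice
elsewhere (e.g. GBD) subtracts a counterfactual; users comparing against
such numbers should expect ours to be systematically larger at low
concentrations.

## Exposure

**Composition.** PM2.5 = BC + OA + SO4 + NH4 + 0.25·SS + 0.1·dust, with
NH4 = 36·SO4/96 under the assumption that ammonium exists only as ammonium
sulfate (climate-model output reports no surface NH4).  Dust is accepted
explicitly and defaults to zero with a warning if absent.  The operation is
linear and monotone in every component.

**Calibration.** Modelled fields are rescaled per cell by
obs_baseline / est_baseline, where both baselines are multi-year means over
a configurable window (default 2015–2019; 2012–2019 is an equally
defensible window and is available via the `baseline_window` argument —
neither is privileged).  Whether calibration should be per cell or per
region is a genuinely open choice; per-cell is implemented because it
preserves sub-regional gradients.  Cells with a zero baseline estimate and
a positive observation are masked and counted rather than raising, so
degenerate cells (synthetic oceans) cannot poison regional aggregates.
Computing the calibrated field as obs × (future/est) makes the
future = baseline case return the observation field bit-exactly.

**Regridding.** Concentrations (intensive) are bilinearly interpolated;
populations (extensive) are reallocated by 1-D interval-overlap weights,
which conserves the total when the target covers the source domain.  A
single-cell target axis is treated as spanning the source extent (the
collapse case).  Grids are cell-centre registered, latitude ascending.

**Ensemble interval.** The 95% interval across n ensemble members is
mean ± sd · t₀.₉₇₅(n−1) with the *sample standard deviation un-scaled by
1/√n*: the interval describes member spread, which is the convention of
the multi-model literature this emulates.  A `standard_error` mode applies
the 1/√n factor of a textbook t-interval for the ensemble mean; the two
differ by a factor of √n in width and should not be mixed.

## Risk functions

Curves are consumed as tables (grid of concentrations starting at 0, mean
curve, draw ensemble emulating ~1000 meta-regression fits); fitting the
exposure–response model itself is out of scope.  Between grid nodes RR is
linearly interpolated; beyond the last node it is held flat, since the
evidence does not extend further.  Draw values below RR = 1 are floored at
1 (with a logged count) before PAF: the burden accounting models
attributable deaths, not benefits, and a sub-unity draw would produce a
negative fraction.  Draw intervals are empirical 2.5/97.5 percentiles with
the linear-interpolation quantile estimator.  RR is evaluated at the
region-level population-weighted concentration (one value per
region/year/scenario); this matches how exposure is reported and keeps the
PAF table compact.

## Mortality model

ln(m) = β₁·h₁(SDI) + β₂·h₂(SDI) + θ_a·t + α_{la} + ε, with
h₁ = min(SDI, 0.8), h₂ = max(SDI − 0.8, 0): a continuous linear spline.
Two-segment notation is ambiguous between a spline and disjoint segments;
continuity is enforced because a mean function discontinuous in SDI has no
sensible interpretation for a development covariate.  t is the year index
from the first fitted year (not calendar year), so the intercepts carry
the level.  β₁ and β₂ are pooled across regions per cause ("global"
slopes); region-age intercepts absorb levels.  The fit is ordinary least
squares via the normal equations with a pseudoinverse; if every SDI value
falls on one side of the knot the unidentifiable slope is pinned to the
identifiable one with a warning.  Zero or negative rates are rejected
rather than offset-adjusted (the generators never produce them; real data
with zeros needs upstream handling).

**Residuals.** Per-stratum residual series are modelled with ARIMA of
configurable order, default (1,0,0) with no trend term (intercepts leave
residuals mean-zero by construction).  An all-zero series short-circuits
to a zero forecast; a non-convergent fit falls back to white noise with a
logged warning.

**Prediction intervals.** Forecast intervals are
ln(m) ± t₀.₉₇₅(n−2) · se, exponentiated (hence symmetric on the log
scale).  The default `se` is the regression prediction standard error
√(s²(1 + x_f'(X'X)⁻x_f)) — the textbook prediction variance, whose
one-covariate special case is the familiar s²(1 + 1/n + (x_f−x̄)²/S_xx).
An `as_printed` mode computes the reduced form
√(s²·(1/n)·(SDI_f−SDĪ)²/S_xx), which omits the leading 1 and is offered
for comparison only; it is far too narrow to have coverage anywhere near
95% and the coverage test documents the default mode.

**Envelope constraining.** Because only a handful of causes are forecast
directly, cause forecasts are reconciled in two rounds of proportional
scaling per (region, year, age): level-2 causes (NCD, CMNND, injuries) by
the common factor envelope/Σ(level-2) so they sum exactly to the all-cause
rate, then each level-3 family (five NCD causes + rest-NCD; LRI +
rest-CMNND) to its constrained parent.  The reciprocal orientation —
multiplying by Σ(children)/parent — is available as
`orientation="as_printed"`; it appears in some formulations but moves the
total *away* from the envelope whenever children overshoot it, so the
default implements the constraint's stated purpose.  Interval bounds are
scaled by the same factor as the point rate, preserving their ordering.

**Age standardisation.** Summaries use a fixed, configurable standard
age-proportion vector (default uniform over the bands present) rather than
any particular census structure.

## Burden accounting and uncertainty

Stratum deaths multiply PAF, population, rate and age share.  Interval
bounds follow comonotone bound arithmetic: the lower bound evaluates the
product with the PAF lower bound (2.5th draw percentile at the lower
concentration) and the rate lower bound together, the upper analogously.
This treats the three uncertainty sources as perfectly co-moving and is
therefore conservative; a Monte-Carlo mode (`mc_draws > 0`) samples the
inputs independently and typically yields narrower bounds, quantifying
that conservatism side by side.  Annual series are smoothed at the
reporting layer only, with a centred 5-year moving mean (endpoints use the
available window).  Regional summaries offer both sum-of-regions (totals)
and mean-of-regions (per-capita-style comparisons).

## Driver decomposition

Air quality enters the decomposition as the PAF table — the
concentration→RR→PAF composition is evaluated before decomposition — so
swapping a factor swaps a clean multiplicative term and each ordering's
contributions telescope exactly to the net change.  All 24 orders of
introducing {age structure, population, air quality, mortality} are
enumerated and averaged; factor introduction replaces values at all strata
simultaneously.  Per-factor contributions are path dependent: sub-period
contributions need not sum to the full-period contribution (the test suite
constructs an explicit example), while net changes always telescope.  By
default the pipeline decomposes between smoothed (reporting-layer)
endpoint years, consistent with reporting smoothed series;
`decompose_smoothed=False` switches to raw annual endpoints.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, not replicas of any real dataset:

* **Aerosol fields** — a shared smooth log-normal base pattern per
  component (Gaussian-filtered seeded white noise, smoothness scale 2
  cells), multiplicative member spread (15%) and interannual noise (5%),
  and a compounded scenario drift.  The spatial covariance of real
  climate-model output is not targeted; the smoothness scale is a free
  plausibility parameter.  Typical component levels (BC 2, OA 8, SO4 6,
  SS 3, dust 5 µg/m³) put composed PM2.5 in the tens of µg/m³, the range
  of a polluted continental region.
* **Population** — log-normal-ish cell weights, integer allocation by
  largest remainder so regional totals are conserved exactly (exactness is
  what makes conservation testable).
* **Demography** — declining adult age distribution with a multiplicative
  aging tilt per year; proportions renormalised to sum to 1 within 1e-12.
* **Mortality** — levels-3 causes (plus explicit rest-causes) simulated
  from the hinged model itself with AR(1) residuals; level-2 rates are the
  sums of their children and level-1 the sum of level-2, so hierarchy
  consistency holds by construction and named causes always leave a
  positive remainder.  With σ = 0 the generated log-rate equals the
  regression mean exactly.
* **Risk curves** — saturating-concave default RR(c) = 1 + (RRmax−1)(1 −
  e^{−c/h}) (RRmax 1.8, half-point 60 µg/m³), with flat and log-linear
  shapes for testing; draws perturb the log-excess-risk multiplicatively
  so each draw stays anchored at RR(0)=1 and monotone.

Because generated mortality follows the estimator's own functional form,
parameter-recovery results certify the estimator's correctness, not its
robustness to misspecification; and because regions are abstract labels on
abstract grids, nothing here validates against real geography, emission
inventories or registry data.

## Problem sizes and calibration checks

The simulation-based checks use: trend recovery at 20 regions × 30 years
× 15 age bands with iid log-rate noise σ = 0.05, 200 replicates, requiring
each slope within 3 standard errors of truth in ≥95% of replicates; AR(1)
recovery at φ = 0.5, series length 500, 200 replicates; one-step forecast
coverage at n = 20 in-sample years, 500 replicates, accepted within
[90%, 99%].  The pipeline's default synthetic study runs 4 regions on a
12×12 grid with 3 ensemble members over 2000–2035; the test suite
exercises it at 2 regions with white-noise residuals.  All sizes are the
package's own choices and are configurable.

## Known limitations

* All-cause demographic consistency is not enforced: population
  projections and the mortality envelope come from independent generators,
  as they typically do in practice.
* The decomposition is discrete (endpoint-swap); no continuous-time
  (LMDI/IDA-style) variant is provided.
* No years-of-life-lost, DALYs, or economic valuation.
* Sub-unity RR draws are floored, which biases the draw distribution's
  lower tail slightly upward for near-null curves.
* The pipeline forecasts every stratum independently before constraining;
  cross-stratum residual correlation is not modelled.
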