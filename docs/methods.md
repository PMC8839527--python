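# Methods

## Model and assumptions

The package implements a semi-empirical reflectance model for coastal
Case 2 waters: remote-sensing reflectance just below the surface is
taken proportional to b_b/(a + b_b), with the proportionality f/Q
treated as an empirical per-band constant, and the absorption and
backscattering budgets assembled additively from component models.
The assumptions this rests on:

* **Locality.** Every constant is strictly local to the water type the
  calibration data come from (here: southern-Baltic coastal waters,
  CDOM-rich, brackish).  Nothing in the functional forms transfers to
  other regions without recalibration.
* **Band discreteness.** The model exists only at 420, 488, 555 and
  620 nm (the backscattering-meter channels).  Requests for any other
  wavelength raise; there is no spectral interpolation.  For mapping
  radiometer channels onto the model bands a nearest-neighbour helper
  is provided (ties break toward the shorter wavelength).
* **Multiplicative errors.** Component IOPs span orders of magnitude,
  so residuals are treated as log-symmetric: every fit is ordinary
  least squares on log-transformed values and the validation
  statistics include the logarithmic family (standard error factor x,
  asymmetric bounds σ+ = x−1, σ− = 1/x−1).
* **Constant f/Q per band.** In reality f/Q varies with illumination
  geometry and scattering regime; the model freezes one value per band
  (0.07, 0.10, 0.12, 0.13 sr⁻¹), obtained by aggregating per-station
  inversions R_rs·(a+b_b)/b_b.  Whether the original aggregation was a
  mean or median is not documented; the median is the default here
  (robust to log-symmetric radiance noise), the mean is available by
  option.
* **Fixed pure-water constants.** a_w and b_bw per band are constants
  of the coefficient set; no temperature or salinity dependence.

### The CDOM component

The CDOM model is a quadratic in u = log10 a_CDOM(400):
a_CDOM(λ) = 10^(−M·u² + N·u − P).  Two numerical consequences are
handled explicitly:

* at a_CDOM(400) = 0 the continuous limit is 0 (the −M·u² term
  dominates as u → −∞), returned exactly without evaluating log(0);
* the quadratic peaks at u = N/(2M), i.e. a_CDOM(400) ≈ 2.4 m⁻¹ at
  620 nm and ≈ 3.3 m⁻¹ at 555 nm, so the model is increasing in its
  driver only over the calibrated range.  Predictions beyond
  a_CDOM(400) ≈ 2 m⁻¹ at the red bands are extrapolations and should
  not be trusted; the monotonicity tests are restricted accordingly.

### Degenerate ratios

ΣC/Chl a and SPM_inorg/SPM are defined as 0 when numerator and
denominator are both 0; a positive numerator over a zero denominator
is a domain error, never a silent infinity.  All component models
return exactly 0 at a zero primary driver.

## Calibration

Calibration re-derives every constant from a station table in three
stages, mirroring how the constants were originally obtained:

1. **One-parameter power laws** per family and band: OLS of log10(IOP)
   on log10(driver); coefficient = 10^intercept, exponent = slope.
   Nonpositive or missing pairs are dropped and counted; fewer than
   two usable pairs is an error.
2. **Residual-ratio corrections**: the ratio of the one-parameter
   prediction to the measurement is regressed (ln scale) on a
   composition covariate — ΣC/Chl a for phytoplankton, SPM_inorg/SPM
   for particles.  Covariate values outside [0, 2] resp. [0, 1] are
   excluded by default and counted.
3. **Composition**: two-parameter coefficient = one-parameter
   coefficient / prefactor, exponent unchanged, rate = −(residual
   rate).  The exponent is never altered by the correction.

The CDOM constants come from OLS of log10 a_CDOM(λ) on [u², u, 1]
(three unknowns, so at least three non-collinear pairs); f/Q from the
per-station inversion described above.  Pure-water constants are not
fitted.

**Two-step vs joint.**  The two-step procedure above is the default
because it is the documented provenance of the published constants.
It is, however, not exactly closed under noiseless model-generated
data: the one-parameter slope absorbs a share H·ρ²-like of the
covariate effect whenever the sample correlation ρ between the
log-driver and the covariate is nonzero, which at finite n it always
slightly is (order 1/√n even for independent draws; ~0.5% constants
error at n = 300).  The `fit_method="joint"` option — one OLS of
log10(IOP) on [1, log10(driver), covariate] — is exactly closed (the
closure tests recover the generating constants to 1e−8 and better)
and is the recommended mode when the two-parameter constants are the
goal rather than the historical two-step diagnostics.

## Error statistics

For calculated-vs-measured pairs the package reports both arithmetic
statistics of ε_i = (cal−meas)/meas — the mean ⟨ε⟩ (systematic error)
and standard deviation σ_ε (statistical error) — and logarithmic
statistics of log10(cal/meas): the mean log error
⟨ε⟩_g = 10^⟨log ratio⟩ − 1, the standard error factor x = 10^SD, and
σ± as above.  Conventions:

* population (1/N) denominators for both standard deviations by
  default (a sample-SD switch exists but is off);
* statistics are stored as fractions and rendered ×100 in the tables;
* pairs with a nonpositive measured or calculated value are excluded
  with a reported count (log statistics force positivity).

Error tables are emitted per band in the conventional column order
(systematic error, statistical error, systematic log error, standard
error factor, σ+, σ−) plus the pair count.

## Synthetic stations

The generator stands in for a coastal cruise dataset.  Marginals:
Chl a, SPM and a_CDOM(400) lognormal (median, log10-spread); the
inorganic SPM fraction Beta(2, 3) on [0, 1]; ΣC/Chl a a truncated
normal (0.35 ± 0.1 on [0.05, 1.0]).  Constituents are independent
apart from the structural couplings (ΣC from Chl a, SPM_inorg from
SPM) — no cross-correlations are imposed because none are documented.
Measured IOPs are forward-model values times 10^(σ·z) with
independent standard-normal z per station/band/quantity (default
σ = 0.14 dex, matching standard error factors near 1.38); radiometry
is generated by consistent inversion (R_rs from the measured IOPs,
L_u = R_rs·E_d, E_u = Q·L_u with Q = 3.5 sr, E_d = 100 relative
units), so the radiometric identities hold exactly and f/Q inversion
recovers the generating value before any optional radiance noise.

Default medians (Chl a 5 mg m⁻³, SPM 1.3 g m⁻³, a_CDOM(400)
0.9 m⁻¹; spreads 0.4/0.35/0.2 dex) were chosen once so that the
population spans orders of magnitude in each constituent, stays in a
physically sensible brackish-coastal regime, and reproduces the
CDOM-dominated non-water absorption budget at 420 nm — mean shares
near 68% CDOM, 20% phytoplankton, 12% detritus (the generated
population gives ≈ 66/22/12 at n = 1000).  All parameters are
overridable; every routine takes an explicit seed and identical
parameters + seed give byte-identical tables.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real data: seasonal and spatial structure,
upwelling events, depth dependence, constituent cross-correlations,
instrument-specific error structure (the real measurement error of
absorption by non-algal particles, for instance, is far from
log-symmetric-with-one-σ), and any mismatch between the true
functional forms and the model family.  Parameter-recovery results on
synthetic data show the pipeline is self-consistent, not that the
model is correct for any particular sea.

## Problem sizes and numerical choices

Closure tests run at 300–500 stations (closure is exact, size only
conditions the design matrices); stochastic recovery checks use
n = 10⁴ where a 2% tolerance on the error factor is ≈ 3σ, and n = 800
for two-step constant recovery where a ±15% band exceeds 3.5σ for
every constant (the binding term is the aph coefficient, which
inherits mean(ΣC/Chl) times the residual-rate error,
sd ≈ σ_ln/(√n·sd(covariate))).  The absorption-budget check uses
n = 1000, where the ±5-point band is ≈ 10σ for the CDOM share.  OLS
is solved by `numpy.linalg.lstsq`; no iterative optimisation anywhere,
so there are no initialisation or convergence concerns.  All f/Q
round-trip identities are algebraically exact and tested at 1e−12.

## Known limitations

* The published one-parameter a_d(620) coefficient (0.002) is
  inconsistent with the monotone trend of the other bands and with the
  two-parameter K = 0.015; it is implemented as published, excluded
  from headline checks, and flagged here as a probable misprint.
* The published one- and two-parameter constants of the a_d family are
  not mutually consistent under the composition rule, so the two-step
  re-derivation cannot reproduce both simultaneously; the coefficient
  set treats the two-parameter table as canonical.
* Residual-ratio fits for the particle families have intrinsically low
  R² (the composition covariate explains little of the scatter); their
  rates are therefore poorly determined at small n — see the sizing
  note above.
* No uncertainty propagation beyond OLS standard errors, no confidence
  intervals on error statistics, no above-water reflectance or
  atmospheric correction, and no radiative-transfer solver.
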