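# Methods

`greenrisk` implements an area-level (ecological) analysis linking
vegetation cover to counts of psychotic and non-psychotic disorders across
a city's neighbourhoods: satellite vegetation measures are summarised per
areal unit, observed case counts are set against indirectly standardized
expected counts, spatial autocorrelation is screened with a global Moran's
I permutation test, and the association is estimated with a Bayesian
Poisson-lognormal spatial model carrying both a spatially structured (ICAR)
and an unstructured (iid) random effect — the BYM convolution model of
disease mapping.  Because the underlying health extracts are restricted
data and the satellite scenes are specific acquisitions, the package ships
a first-class synthetic-data module that emulates the study's structure, so
every stage is runnable and testable offline.

## Vegetation measures

Raw digital numbers are rescaled to top-of-atmosphere reflectance,
`rho = (M*DN + A)/sin(elev)`, followed by dark-object subtraction (each
band's minimum valid pixel subtracted from all pixels) as a first-order
haze correction.  Three indices are computed from the corrected bands:

- NDVI = (NIR − R)/(NIR + R)
- SAVI = (1 + L)(NIR − R)/(NIR + R + L), soil-brightness term L = 0.5
- EVI = G(NIR − R)/(NIR + C1·R − C2·B + 1), G = 2.5, C1 = 6, C2 = 7.5

Constants follow the USGS Landsat-8 formulations and are configurable
arguments, since published analyses vary (notably SAVI's L).  Non-vegetation
surfaces are removed by masking cells with NDVI at or below a threshold
(default 0 — built surfaces can carry small positive NDVI, so the threshold
is exposed).  Per-unit summaries are the arithmetic mean of valid masked
cells whose **centers** fall inside the unit polygon (the convention of
common zonal-statistics tools; deterministic and resolution-independent in
the limit), and percent cover is the share of valid cells carrying a target
land-cover class.  Nodata propagates through every operation; division by
zero yields nodata, never infinity.  Units with no usable cells are flagged
missing rather than zeroed.

Two area-based measures complete the five-measure suite: `Veg_RF`
(percent vegetation from a classified land-cover raster — the classifier
itself is out of scope, any classified grid is accepted) and `Tree_OD`
(percent tree cover from a mapping product).  In the synthetic preset both
are emulated on the published moment scale.

## Expected counts

Indirect (internal) standardization: study-wide sex-specific rates
`rate_sex = sum_i O_i,sex / sum_i pop_i,sex` are applied back to each
unit's population structure, `E_i = sum_sex rate_sex * pop_i,sex`.  Only
sex strata are used (age grouping was unavailable in the source data), but
the rate table is generic over strata.  Internal standardization conserves
totals — `sum(E) = sum(O)` per disorder — which the tests assert to 1e-9
relative tolerance.  Units with zero population are a hard error, not a
silent drop, because the model's offset requires E_i > 0.

Covariates are assembled as X1 (one vegetation measure per model run) plus
five confounders: four area-marginalization dimensions — material
deprivation (X2), ethnic concentration (X3), residential instability (X4),
dependency (X5) — and the substance-use rate per 1000 (X6).  A screen
reports pairwise Pearson correlations and variance inflation factors
(VIF_j = 1/(1 − R²_j)); flags default to |r| ≥ 0.7 and VIF ≥ 10, common
rules of thumb, since the source analysis reports only that collinearity
was unproblematic.

## Spatial structure

Queen contiguity (any shared boundary point) is the default adjacency,
matching the convention of the GeoDa lineage of tools; rook is available.
One adjacency feeds two weight styles: row-standardized weights for
Moran's I and binary weights for the ICAR prior.  The global Moran's I

    I = (n/S0) * (z' W z)/(z' z),   z = x − mean(x)

is tested by value permutation with pseudo p-value
`(1 + #{I_perm ≥ I_obs})/(1 + n_perm)` (999 permutations by default, seed
mandatory).  Islands contribute zero to Moran's I but are fatal for ICAR
fitting unless dropped explicitly.  The Moran step is a reported gate, not
a hard stop, since it motivates rather than licenses the spatial model; a
config flag can make it blocking.

## The Bayesian spatial model

For one disorder over n units:

    O_i ~ Poisson(lambda_i)
    log lambda_i = log E_i + b0 + sum_{j=1..6} b_j X_ji + u_i + s_i

Priors: b1..b6 ~ Normal(0, precision 1e-5); b0 flat (improper uniform),
paired with a sum-to-zero constraint on s; u_i ~ Normal(0, tau_u^{-1}) iid;
s from the intrinsic CAR kernel `exp(-tau_s/2 sum_{i~j}(s_i − s_j)^2)`
with binary contiguity weights (rank n − G for G connected components);
tau_u, tau_s ~ Gamma(0.001, 0.001).  Each disorder-measure pair is fit as
a separate model — the 5 measures × 2 disorders grid of ten models — with
no sharing across fits.  Covariates enter on their raw scales (the
published coefficient scales are raw-scale), with an optional centering
flag off by default.

### Sampler

Metropolis-within-Gibbs, mirroring the WinBUGS-era machinery the model was
designed around:

- b0..b6: scalar random-walk Metropolis, proposal scales initialised at
  0.05/SD(X_j) so raw-scale covariates (e.g. an index with SD 0.006 vs a
  rate with SD 4.4) start with comparable acceptance behaviour.  A
  covariate move proposes b_j together with the compensating intercept
  shift −delta·mean(x_j): because covariates enter on their raw
  (non-centred) scales, (b_j, b0) posteriors form narrow ridges whenever a
  covariate mean is large relative to its SD, and a purely coordinate-wise
  walk can take thousands of sweeps to traverse them (R-hat far above 1 on
  high-count outcomes).  The paired move is an ordinary Metropolis proposal
  along the ridge (b0 is flat, so no prior term enters), equivalent to
  sampling the centred parameterisation while reporting raw-scale
  coefficients; slope marginals are untouched.
- u: all sites proposed and accepted simultaneously — valid because the
  u_i are conditionally independent given everything else (the likelihood
  factorises over units and the prior is iid).
- s: updated colour class by colour class of the contiguity graph (greedy
  colouring); sites within a class are mutually non-adjacent, hence
  conditionally independent under the ICAR prior, so the vectorised update
  has the same stationary distribution as sequential single-site
  Metropolis.  This is what makes full-length chains cheap in pure numpy.
- tau_u, tau_s: exact Gibbs draws, `tau_u ~ Gamma(a + n/2, b + sum u²/2)`
  and `tau_s ~ Gamma(a + (n−G)/2, b + sum_{edges}(s_i−s_j)²/2)`.

After every sweep the constraint move `(s, b0) -> (s − mean(s),
b0 + mean(s))` re-centres s.  The ICAR kernel depends only on differences
and b0 is flat, so the move is exactly measure-preserving; it resolves the
additive confounding between b0 and the level of s without biasing either.

Step sizes adapt toward ~40% acceptance during burn-in only (multiplicative
update every 100 sweeps); the post-burn-in kernel is fixed.  Defaults:
2 chains × 15,000 sweeps with 5,000 burn-in, thinning 1, all configurable.
Initial values are over-dispersed across chains: b0 offset ±1 around its
configured centre, precisions 10 and 0.1.  A guard rejects any proposal
taking |log relative risk| above 30.  Cached likelihood terms are refreshed
every 500 sweeps to stop incremental floating-point drift.

Chains are seeded by spawning one child seed per chain from the run seed,
so results are bit-reproducible for a fixed seed and chain count.

### Derived quantities

- **psi** — the spatial fraction `SD(s)/(SD(s) + SD(u))`, computed per
  draw from the empirical standard deviations across units (ddof = 1) and
  summarised by posterior mean and 95% CrI.  Per-draw computation (rather
  than a single number from posterior-mean fields) is used because the
  quantity is reported with a credible interval, which presupposes a
  posterior distribution.
- **DIC** — classic form: `Dbar + pD`, `pD = Dbar − D(theta_bar)` with the
  plug-in deviance at the posterior means of b, u and s (not of lambda).
- **Relative risk** — per draw, `r_i = exp(b0 + X_i b + u_i + s_i)`;
  summarised by posterior mean and 95% CrI per unit, exported with
  equal-count quantile bins for choropleth mapping.
- **Diagnostics** — classic Gelman-Rubin R-hat from between/within-chain
  variances (2 chains minimum); Monte Carlo error by non-overlapping batch
  means (50 batches per chain, combined across chains); lag-k
  autocorrelation.  The accuracy rule "MC error < 5% of the posterior SD"
  is evaluated and reported per parameter, never silently enforced.  Batch
  means was chosen for the MC error because the historical software's
  estimator is unspecified; it is simple, consistent, and testable against
  SD/sqrt(N) on iid chains.
- **Significance** — a coefficient is flagged when its 95% CrI excludes
  zero, the convention used for the published coefficient tables.

## Synthetic data

The generator's defaults are the study conditions:

- geography: 14 × 10 square lattice = 140 units (the study's n), queen
  contiguity;
- covariates: independent Normals matched to the published
  per-neighbourhood moments — EVI 0.052 (0.006), NDVI 0.561 (0.035), SAVI
  0.058 (0.006), Veg_RF 20.73 (13.27), Tree_OD 6.54 (5.61); material
  deprivation 0.250 (0.895), ethnic concentration 0.902 (0.838),
  residential instability 0.723 (0.783), dependency −0.228 (0.393),
  substance-use rate 9.988 (4.392).  Independence is the honest default
  (the source reports low inter-correlation among the marginalization
  dimensions); a correlation-matrix hook exists for stress tests.  In the
  pipeline preset the five vegetation measures share one latent field
  rescaled to each measure's moments, making them mutually consistent
  proxies of the same vegetation surface;
- populations: log-normal unit totals around 19,500 (≈ the city's 2016
  population over 140 units; spread sigma 0.4), split 50/50 between sexes
  with a female:male rate ratio of 1.2 — the real split is unpublished, so
  this is an invented, documented preset;
- count scale: sex-specific base rates solved so the mean expected count
  per unit equals the published means (282.9 psychotic, 2239.9
  non-psychotic);
- latent fields: s drawn exactly from the ICAR kernel via the
  eigendecomposition of the graph Laplacian (null-space directions
  excluded, so s sums to zero per connected component; covariance equals
  the scaled Laplacian pseudo-inverse — exactness beats speed at n ≤ 1e3),
  u iid Normal; both rescaled to exact target marginal SDs, defaults
  SD(s) = 0.15 and SD(u) = 0.05, i.e. spatial fraction psi_true = 0.75;
- coefficients: default slopes near the published posterior means
  (−4.0 on the EVI scale for the vegetation effect; 0.12, −0.12, 0.18,
  −0.06, 0.04 for the confounders) with the intercept −0.257 chosen so the
  mean log relative risk is ~0 at the covariate means;
- counts: `O_i ~ Poisson(E_i exp(eta_i))`, split to sexes binomially in
  proportion to the sex-specific expected counts;
- scenes: multiband reflectance rasters painted from rectangular patches
  with per-class reflectance presets (vegetation NDVI ≈ 0.8, water NDVI
  < 0, built-up small positive) plus Gaussian noise, with the ground-truth
  class grid returned for percent-cover checks.

What the generator does **not** emulate: real Landsat radiometry and
atmospheric effects, spatially correlated covariate error, age structure,
irregular polygon geographies, and reporting artifacts in health data.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's statistics under the model's own data-generating mechanism —
not the substantive epidemiological findings, which require the restricted
data.

Zonal summaries taken from the synthetic scenes are not on the published
Table-of-moments scale (a masked vegetation pixel's index is much larger
than a neighbourhood mean), so the model covariates in the pipeline preset
come from the moment-matched generator while the raster chain is exercised
and written alongside.

## Problem sizes used in the shipped checks

The acceptance suite runs the recovery study at the full stated design
(140 units, 2 chains × 15,000 sweeps, 10 replicates — about 3 minutes);
the spatial-fraction discrimination and DIC-ordering studies use the same
geography with 2 chains × 4,000 sweeps (1,000 burn-in) per fit, and the
end-to-end 10-model run uses 2,000 sweeps (500 burn-in) per fit.  The
acceptance script fits one full-length model.  These sizes are the
package's chosen desk-scale defaults; every length is configurable.

## Numerical notes and limitations

- The offset identity (E → cE with b0 shifted by −log c) holds exactly in
  real arithmetic; in floating point the matched-seed posteriors agree to
  ~1e-8 (every Metropolis decision matches unless a log-ratio falls within
  ~1e-15 of the uniform draw, which has negligible probability at these
  chain lengths).  Tests assert agreement at 1e-7.
- VIF for an exactly collinear column is reported as infinity and flagged,
  not raised.
- Quantile bins resolve ties to the lower bin; constant surfaces fall back
  to a single bin with a warning.
- Proper CAR/Leroux models, spatio-temporal extensions, WAIC/LOO,
  covariate selection and zero-inflation are out of scope, as are cloud
  masking, mosaicking and classifier training on the raster side.
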