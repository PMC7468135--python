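# Methods

## Stage 1: the per-series state-space model

Each population's abundance record is first reduced to one observation per
calendar year (arithmetic mean of within-year replicates — the mean is
order-independent and unbiased on the raw scale), filtered to a minimum of
five surveys (shorter records rarely identify a direction), and rescaled
within the series. The default rescaling maps onto [0, 1]
(`(v − min)/(max − min)`), so trends are expressed per unit of the range the
population itself exhibited; a z-score variant (sample sd, n−1) supports the
linear-model comparison path. Constant series cannot be rescaled; they are
retained and flagged (mapped to all-0.5 / all-0) so downstream fits return a
zero trend with zero variance rather than failing — monitoring programmes do
contain genuinely low-variance records and removing them would bias the
collection.

The model for a scaled series is a Gaussian random walk with drift observed
with error:

    X_t = X_{t-1} + mu + eps_t,   eps_t ~ N(0, sigma^2)
    Y_t = X_t + F_t,              F_t   ~ N(0, tau^2)

Conditioning on the first observation, the increments
`D_i = Y_{t_i} − Y_{t_{i−1}}` are jointly normal with mean `mu·Δ_i`,
variance `sigma²·Δ_i + 2·tau²` and lag-1 covariance `−tau²` between
increments sharing a survey. The MA(1) signature is what separates
observation error from process noise; survey gaps enter only through the
Δ-scaled variances, with no imputation. The likelihood is evaluated exactly
in O(n) with a banded Cholesky factorisation of the tridiagonal covariance.

**Estimation.** The default estimator is REML: for fixed `(sigma², tau²)`
the drift is profiled out by GLS and the restricted likelihood
`−½[log|Σ| + log(Δ'Σ⁻¹Δ) + r'Σ⁻¹r]` is minimised by Nelder–Mead from four
deterministic moment-based starts. The 95% interval on `mu` is
`mu ± t_{0.975,q−1}·se(mu)` with `q` increments — the calibration
recommended for exactly this random-walk trend model, and the one that
yields the least-biased variance components on short series. Full ML over
`(mu, sigma², tau²)` with 8 jittered L-BFGS-B starts and a
profile-likelihood interval (χ²(1) cutoff, Wald fallback) is available via
`method='ml'`; `fix_tau2` pins the observation-error variance for
closed-form checks. Boundary estimates (`sigma²` or `tau²` = 0) are legal
and reported as 0; they flag weak identifiability on short series.

**Interval calibration.** On simulated 30-point series
(mu=0.02, sigma=0.03, tau=0.02) the realised coverage of the 95% interval is
about 88% for both REML-t and ML-profile intervals. The shortfall is
intrinsic to plug-in intervals here: when `tau²` is estimated at or near its
boundary, its uncertainty is not propagated into `se(mu)`. Classifications
based on these intervals are therefore mildly anti-conservative on short
series; the package documents rather than hides this, and the permutation
null provides an independent, exactly calibrated benchmark for
significance rates.

**Classification.** *decline* if the interval lies below zero, *increase*
if above, else *no net change*.

**Fluctuation metrics.** Five per-series variability measures: (1) the OLS
slope standard error of abundance vs year, (2) half the 95% interval on
`mu`, (3) the same half-interval with the series' squared observation-error
variance added to the squared standard error (the measurement-error
convention used for stage-2 weighting; equal to (2) when `tau² = 0`),
(4) the process noise `sigma²`, (5) the sample sd of the scaled series.
Before stage-2 modelling each metric is z-scaled across the dataset so
effect sizes are comparable.

## Stage 2: hierarchical Gaussian models

Per-series estimates are modelled as

    y_i = x_i' beta + b_{s(i)} + e_i,
    b_s ~ N(0, var_species),   e_i ~ N(0, var_residual [+ mev_i])

by a blocked Gibbs sampler with conjugate normal updates for `beta` and the
species intercepts and inverse-gamma updates for both variances.
Categorical predictors (realm, biome, taxa, Red-List category, threat type)
use a zero-intercept parameterisation — one coefficient per level, no
reference category — so each level's net trend is tested directly against
zero. Continuous predictors (latitude, log range, log population size,
habitat specificity, number of threats, duration) get an ordinary
intercept, except the duration sensitivity model, whose intercept is
suppressed because zero monitoring duration cannot have produced change.

Priors are N(0, 10⁸) on coefficients and inverse-gamma(0.001, 0.001) on
variances (a proper, weakly informative stand-in for the improper limiting
variance prior sometimes quoted for such models); both are configurable.
Default run length is 120 000 sweeps, 20 000 burn-in, thinning 10, one
chain (10 000 retained draws); tests assert convergence with 4 chains and
split-R̂ < 1.05 at shorter lengths.

**Measurement-error weighting.** "Weighting by tau²" is implemented as a
known per-observation error variance `mev_i = (tau²_i)²` added to
observation i's residual variance. The coefficient and random-effect
updates marginalise the latent truths analytically (per-observation weights
`1/(var_residual + mev_i)` against the observed response), which keeps the
chain mixing even when the residual variance is far smaller than the
measurement variances; latent truths are imputed only for the conjugate
residual-variance update. A relative-precision alternative
(`weighting='precision'`) treats `mev` as relative residual variances.

**Effect standardisation.** Plotted/reported effects can be divided by the
standard deviation of their input data (`standardize_effect`), putting
categorical contrasts and continuous slopes on one scale.

## Phylogenetic models

Within a class, per-series responses get an intercept-only model with two
species-level random effects — one with covariance proportional to the
Brownian-motion correlation implied by a tree (shared root-to-MRCA path
length normalised by `sqrt(depth_a · depth_b)`, so the diagonal is 1 and
ultrametric trees reduce to shared-path/tree-depth) and one iid — plus a
residual. Each random-effect block uses parameter expansion
(`u = alpha·w`, `alpha ~ N(0,1)`, working variance
inverse-gamma(nu/2, nu·V/2) with V=1, nu=1), implying a heavy-tailed
half-Cauchy-like prior on the block sd and good mixing near zero variance.
Tree uncertainty is handled by refitting over 10 trees sampled
seed-reproducibly from a larger pool and reporting the across-tree mean and
range per component. "Pushed against zero" (no effect) is operationalised
as: the 15th percentile of the component's share of total variance falls
below 5% (both thresholds configurable).

Numerically, near-singular tree correlations (zero-length internal
branches) are inverted with eigenvalues floored at 1e-8 — the analogue of
diagonal jitter — and the working-effect precision Cholesky carries a
trace-scaled ridge fallback.

*Identifiability caveat:* with one response per species, separating
tree-structured from iid species variance relies entirely on the tree's
off-diagonal structure. On small shallow trees (≲100 tips, mean pairwise
correlation ~0.15) the posterior on the phylo share is prior-dominated and
need not concentrate at zero under null data; at ~200 species the split is
likelihood-identified and the decomposition recovers simulated shares of 0
and 0.8 within ±0.15. Conclusions about phylogenetic signal should be drawn
at those sizes, as the per-class analyses here do.

## Rarity metrics

Geographic range: occurrence records are cleaned by rule — integer latitude
or longitude ("no decimal places", read literally as equality with the
truncated value), latitude equal to longitude, within 1° of the GBIF
headquarters, within 0.0001° of listed institutions, within 0.1° of listed
capitals; radii are great-circle central angles by default (a coordinate-box
mode is available). Then the lower-0.02/upper-0.98 quantile interval
(linear-interpolation quantiles, boundary inclusive) is applied to latitude
and longitude jointly, a planar convex hull is taken in (lon, lat), and the
polygon's area is evaluated on a sphere of radius 6371 km with the
Chamberlain–Duquette formula (sub-0.1% error at continental scales; the
tests cross-check a spherical-excess triangulation). Hulls spanning the
antimeridian raise an error — a documented v1 limitation that none of the
target use cases (UK and global bird/mammal ranges) hits. Fewer than three
non-collinear surviving points make the range undefined, never silently
zero.

Mean population size is the mean raw abundance over the monitoring period
and is defined only for count-like survey units (indices are excluded).
Habitat specificity is the number of distinct habitat categories a species
occupies; an empty list is a missing-data marker.

## Randomization null and sensitivity analyses

The null asks how many significant trends pure noise with the same
structure produces: abundance values are permuted within each series
(preserving lengths, years, and each series' value distribution; an iid
resampling mode exists as an alternative), an OLS slope of abundance on
year is tested per series, and the two tail percentages at alpha = 0.05 are
reported. Under within-series exchangeability each tail realises slightly
under alpha/2 (~2.3%) because short, tie-prone series make the t-test
conservative. The emulated length structure is a shifted Poisson
(minimum 5, mean 23.3 annual points) over 1970–2014.

Truncation sensitivity removes the first or last five observations
(site-selection bias at survey start/end) and re-applies the minimum-length
filter. The duration model regresses trend on monitoring duration through
the origin. Bimodality of trend distributions is tested with Hartigan's
dip: the implementation minimises, over modal cuts — including modes
carrying an atom at a data value — the deviation demanded of the convex and
concave CDF branches, each obtained from a greatest-convex-minorant /
least-concave-majorant construction on the empirical CDF band; both demands
are monotone in the cut, so large samples use a crossing search. The
statistic is validated exhaustively against a linear-programming
minimisation over piecewise-linear unimodal CDFs; p-values are Monte-Carlo
calibrated against uniform samples of the same size.

## Synthetic data

The generator produces exactly the structures the analysis assumes, with
ground truth recorded for every draw: series from the stage-1 model with
drift = class effect + species intercept (defaults: six classes with
effects −0.01…0.02, species-intercept sd 0.01, sigma 0.03, tau 0.02 on the
[0, 1]-magnitude scale); lengths shifted-Poisson (mean 23.3, min 5) placed
within 1970–2014; realm/biome/unit/Red-List labels at configurable
frequencies; birth–death trees with trait values mixing a Brownian draw and
iid noise at a chosen phylogenetic-signal share; and Gaussian occurrence
clouds with labelled dirty records injected at a chosen fraction. Series
are generated on the model's natural scale directly (an exponential
back-transform to positive counts serves I/O and population-size tests);
recovery tests therefore fit that scale, since per-series min-max rescaling
divides each trend by the series' own range and makes absolute effects
incomparable with the truth.

What the generator does not emulate — and what passing recovery tests
therefore do not establish for real data: taxonomic and geographic sampling
biases of real compilations, non-Gaussian observation error, density
dependence, within-series changes of survey method, and correlated
species×site effects.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at the sizes the analyses
themselves prescribe where feasible — 9286 series for the randomization
null, 500 series (30 points) for stage-1 recovery, a 200-tip tree with
20 000-sweep chains for the phylogenetic decomposition, 2000 series / 400
species for full-pipeline class recovery — and smaller, seed-fixed versions
of the same constructions for per-module checks.
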