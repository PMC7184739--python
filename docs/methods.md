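# Methods

This note documents the statistical models implemented in `potlip`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Scientific setting

Compound-specific carbon isotope analysis of the two dominant saturated
fatty acids preserved in archaeological pottery — palmitic (C16:0) and
stearic (C18:0) acid — discriminates the animal fats processed in a
vessel.  The within-sherd offset

    Δ13C = δ13C_18:0 − δ13C_16:0    (‰ VPDB)

moves toward more negative values from non-ruminant fats through ruminant
carcass fats to ruminant milk fats, reflecting tissue-specific fatty-acid
biosynthesis.  `potlip` carries per-sherd (δ13C16:0, δ13C18:0) pairs
through screening, classification, Bayesian source apportionment and
spatial interpolation.

## Screening

A residue is *interpretable* when its total lipid yield strictly exceeds
5 µg per g of ceramic powder (configurable; the boundary itself is
excluded).  Sherds without a recorded yield are partitioned separately,
never silently dropped.

Aquatic-resource evidence is screened from boolean biomarker flags:
long-chain ω-(o-alkylphenyl)alkanoic acids (APAA C20/C22, formed by
prolonged heating of aquatic unsaturated fatty acids) and isoprenoid
acids (phytanic, pristanic, TMTD).  The decision rule — *positive*
requires a long-chain APAA AND an isoprenoid indicator; either alone is
*partial*; APAA C18 alone is *partial* because it also forms from heated
terrestrial fats — is a documented package convention, configurable via
`AquaticRule`.  The phytanic SRR-diastereomer cutoff of 0.755 is a
literature-derived convention, not a value estimated here.  The rule is
monotone: adding evidence never demotes the level.

## Reference library

Modern reference fats are corrected for the Suess effect (the
industrial-era decline of atmospheric CO₂ δ13C) before use:
`corrected = measured + [δ13C_atm(1850) − δ13C_atm(collection year)]`.
The built-in atmospheric series is a synthetic piecewise-linear curve
from −6.4‰ (1850) to −8.4‰ (2010) with knots mimicking the accelerating
post-1960 decline; any user curve can be substituted.  The correction is
additive and zero at the 1850 baseline.

Per source class (ruminant adipose, ruminant dairy, non-ruminant, marine
oil) the corrected pairs give an arithmetic mean, unbiased sample
covariance and SEM = sqrt(diag(cov)/n).  Confidence ellipses use the
chi-square(2 df) quantile — a 68% ellipse covers 68% of the *population*,
which differs from the 1-SD convention; membership is a Mahalanobis test
with boundary points counted inside.

Packaged C16:0/C18:0 concentrations (% lipid by weight: tallow 26/22,
butter fat 30/12, lard 24/14, fish oil 17/4, with SEMs) are
food-composition-database-style defaults with provenance notes, not
measured values; override freely.

## Classification and the latitudinal gradient

Threshold classes partition the Δ13C line: dairy (Δ ≤ −3.3‰), ruminant
adipose (−3.3 < Δ < −1.0), non-ruminant (Δ ≥ −1.0); the outer boundaries
are inclusive.  Ellipse membership against the reference groups is
reported *alongside*, never merged — a point outside all ellipses is
flagged as a probable mixture.

The latitudinal gradient is the Spearman rank correlation between site
latitude and per-sherd Δ13C (per-site means optional), with average-rank
ties.  The default p-value uses the t-distribution approximation, which
is standard at the n of several hundred this analysis targets; a seeded
permutation test is available for small n.

## Bayesian mixing model

Per region, the observation is the componentwise median (δ13C16:0,
δ13C18:0) pair.  Regions whose isotope values are bimodal (by default
the Western Baltic, split between marine and terrestrial modes) are
refused with an explicit error, because a single median misrepresents a
two-mode distribution.

The forward model weights each source's signature by its share *and* its
fatty-acid content:

    μ_k = Σ_i f_i c_ik δ_ik / Σ_i f_i c_ik ,  k ∈ {16:0, 18:0}

with likelihood y_k ~ Normal(μ_k, σ_obs), σ_obs = 0.5‰ by default.
Priors: f ~ Dirichlet(1,…,1) (flat on the simplex); latent signatures
δ_i ~ N(mean_i, cov_i/n_i) ("covariance" mode; "sem_only" uses
independent SEM normals — the two modes bracket reasonable constructions
of reference-group uncertainty); concentrations normal truncated at
zero with their SEMs.

Sampling is blocked MCMC, vectorised across chains: an adaptive
random-walk Metropolis step on the additive-log-ratio transform of f
(Robbins–Monro scale adaptation toward 30% acceptance during burn-in,
frozen afterwards so the kept chain is Markov), then independence
Metropolis–Hastings updates for the signature and concentration blocks
with proposals drawn from their priors (the acceptance ratio reduces to
a likelihood ratio; because the priors are tight relative to σ_obs,
acceptance stays high).  Defaults: 4 chains with overdispersed starts,
5000 burn-in + 10,000 kept iterations each, pooled for summaries (mean,
median, 68% and 95% equal-tailed credible intervals).  Convergence is
monitored operationally by split-Rhat ≤ 1.05 and bulk ESS (via arviz);
failure raises a prominent warning flag on the results object, never a
silent pass.  Identical seed and configuration reproduce draws
bit-identically.

With two proxies and four sources the posterior is intrinsically
under-determined (equifinality): credible intervals must stay wide, and
the test suite asserts that colinear sources never produce collapsed
intervals.

The simulation-based calibration harness (`recover_parameters`) checks
frequentist coverage of the 95% credible intervals under the model's own
generative process.  Replicate fits use 4 chains of 1000 burn-in + 3000
kept iterations — posterior summaries of this low-dimensional target are
stable well below the headline defaults, and 50 replicates complete in
well under a minute.

## Spatial surfaces

**Mean surface.**  `SurfaceGAMM` fits

    Y_ij = s(longitude, latitude) + u_i + ε_ij

where s is a thin-plate regression spline (radial basis r²·log r with an
affine null space, side constraint absorbed by QR reparameterisation;
knots are the distinct site locations, thinned to rank k — default
min(40, n_locations) — by deterministic k-means when needed), u_i ~
N(0, σ_u²) is a site random intercept fitted as a ridge-penalised block,
and ε_ij ~ N(0, σ_ε²).  The spline smoothing parameter and the
random-intercept precision are chosen by REML (coarse grid + Nelder–Mead
on the log scale).  Predictions are the population surface — random
intercepts excluded — with standard errors from the Bayesian posterior
covariance of the coefficients; grid cells with SE at or above the mask
threshold (default 0.30‰ for Δ13C surfaces) are suppressed, and cells
outside the convex hull of the data are flagged extrapolated.  The
implementation reproduces R mgcv's
`gam(y ~ s(lon,lat,bs="tp") + s(site,bs="re"), method="REML")` to ~1e-5
on shared fixtures (cross-checked in the test suite).

Coordinates enter as raw degrees in an isotropic smoother, matching the
modelling formula above; an optional cos(latitude) scaling of longitude
is provided because a longitude degree shrinks poleward across the
36–58° N span.

**Arrival surface.**  `QuantileSurfaceGAMM` estimates the earliest
arrival of farming as an extreme-quantile surface: the τ = 0.005 (0.5%)
quantile of site dates over space, replacing the outlier-fragile
"minimum date" convention.  The same TPS basis is fitted by minimising a
smoothed pinball loss (τr + ε·softplus(−r/ε), ε = 1% of the date SD)
with the TPS curvature penalty, via L-BFGS warm-started from the
penalised least-squares fit.  The smoothing parameter is chosen by
cross-validated pinball loss over a log grid (seeded folds).  Standard
errors come from a case-resampling bootstrap (default 200 replicates,
seeded) and should be read as optimistic lower bounds: resampling sites
understates uncertainty at an extreme quantile.

## Synthetic data generator

`default_scenario()` emulates the structure of an Atlantic-transect
pottery study: six regions from ~37° N (Portugal) to ~58° N (Scotland)
plus a Western Baltic block, 56 sites, 640 sherds; four bivariate-normal
source signatures at literature-plausible positions (explicitly
synthetic defaults — dairy more depleted in C18:0 than adipose, marine
oils far heavier in both proxies); per-sherd source proportions drawn
from a Dirichlet with concentration 10 around each region's true
proportions (giving within-region scatter comparable to real
assemblages); sherd isotope pairs produced by the concentration-weighted
forward model with per-sherd signature draws plus Normal(0, 0.5‰) noise;
a dairy share rising from 15% of lipid weight in the south to 75% in the
north; arrival dates declining from ~5400 to ~3500 cal BC northward
(SD 150 years); log-normal lipid yields with 5% of sherds placed below
the 5 µg g⁻¹ filter (so a 246-sherd cohort keeps ≈234); and a
marine-dominated subpopulation (40%) only in the Western Baltic,
creating the bimodality that motivates that region's exclusion from
regional mixing.  Reference fats are emitted as *pre-correction*
measurements (the per-year atmospheric shift is subtracted) so that
Suess correction recovers the generating signatures.

What the generator does **not** emulate: diagenetic alteration and
degradation biases, laboratory inter-batch drift, unbalanced and spatially
clustered sampling, non-Gaussian heavy tails in reference collections,
and mixtures involving plant oils or wild resources outside the four
source classes.  Passing tests therefore demonstrate internal
consistency and correct inference under the stated model, not robustness
to every feature of real assemblage data.

## Numerical choices and degenerate inputs

- Simplex draws are produced through the ALR transform; the Dirichlet(1)
  prior contributes Σ log f_i (the transform Jacobian) to the log target.
- Zero-variance source groups receive a 1e-12 ridge before Cholesky.
- REML optimisation is clamped to log λ ∈ [−30, 30]; a plane or constant
  signal drives λ to the upper clamp, correctly collapsing the fit onto
  the affine null space.
- A single-source mixing problem returns the point posterior f ≡ 1.
- Medians of even-length samples use the midpoint convention.
- CSV round-trips preserve numerics to better than 1e-9 (12 significant
  digits on write); the Unicode minus sign and NA sentinels are accepted
  on read, never written.

## Known limitations

- The mixing sampler is an MH scheme, not Gibbs; agreement with the
  model is asserted through the analytic two-source oracle and coverage
  simulation rather than engine identity with any particular BUGS-style
  implementation.
- Bootstrap SEs of the quantile surface are optimistic (see above).
- The GAMM's isotropy in degrees slightly stretches east–west distances
  at high latitude unless `cos_lat=True` is set.
- Regional mixing condenses each region to one median pair; within-region
  heterogeneity is deliberately out of model, mirrored by the bimodality
  refusal.
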