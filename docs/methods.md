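# Methods

## Model

`betabym` fits area-level prevalence proportions — one observation per
area, strictly inside (0, 1) — with a beta likelihood in mean-precision
form and a logit-linked Besag–York–Mollié (BYM) linear predictor:

    y_i | mu_i, phi  ~  Beta(mu_i * phi, (1 - mu_i) * phi)
    logit(mu_i)      =  beta0 + x_i' beta + w_i + v_i

so that E(y_i) = mu_i and Var(y_i) = mu_i (1 - mu_i) / (1 + phi). The
spatially structured effect w follows the intrinsic CAR (ICAR)
distribution: conditionally, w_i | w_{-i} ~ N(mean of neighbors,
sigma_w^2 / n_i), which in joint form is a degenerate Gaussian with
precision Q / sigma_w^2, Q = D - A (degree matrix minus binary
adjacency). v_i ~ N(0, sigma_v^2) is unstructured heterogeneity.

Assumptions worth stating explicitly:

* One observation per area; the survey sampling error behind an observed
  percentage is not modeled separately — it is absorbed by phi and v.
* phi is a single scalar. A per-area precision phi_i is a possible
  extension (the likelihood code takes a vector), but no model for it is
  fitted; constant precision is the minimal model for one observation per
  area, which gives heteroscedastic outcome variance through mu_i anyway.
* w sums to zero within every connected component of the contiguity
  graph. The intrinsic CAR is flat along each component's level, so the
  constraint is required for beta0 to be identified.
* Isolated areas (no neighbors) have w_i fixed at 0 and enter only
  through v_i; the ICAR rank used in the density is
  (#non-isolated areas) − (#components containing an edge).
* Boundary outcomes (exactly 0 or 1) are rejected at ingestion, not
  clamped: the beta likelihood has no mass there, and silent clamping
  would bias the precision estimates.

## Priors

Vague defaults in the style of standard disease-mapping software, all
overridable via `PriorSpec`:

| parameter            | prior                  | default             |
|----------------------|------------------------|---------------------|
| beta_j               | Normal(0, sd)          | sd = 31.62 (precision 0.001) |
| beta0                | flat (improper)        | —                   |
| 1/sigma_w^2, 1/sigma_v^2 | Gamma(shape, rate) | (1, 5e-5)           |
| phi                  | Gamma(shape, rate)     | (1, 0.01)           |

Covariates are kept in their native percent units (no standardization by
default), so a coefficient is a log-odds change per percentage point —
e.g. a sedentary-lifestyle coefficient of 0.023 means each extra percent
of sedentary adults multiplies the prevalence odds by exp(0.023).

## Posterior computation

Inference is adaptive Metropolis-within-Gibbs, written for auditability
against a brute-force oracle rather than raw speed:

* scalar Gaussian random walks for beta0, each beta_j, log sigma_w^2,
  log sigma_v^2, log phi;
* single-site random walks for every w_i and v_i. The w updates are
  vectorized over the classes of a proper graph coloring (no two sites in
  a class are adjacent, so their Metropolis decisions are conditionally
  independent); v updates vectorize in one block;
* joint rescale moves (w, sigma_w^2) -> (c·w, c^2·sigma_w^2) and the
  (v, sigma_v^2) analog. These leave the Gaussian kernels invariant and
  let the chain cross the small-variance "funnel" where single-site
  updates stall; without them the bulk ESS of sigma_v^2 was roughly 50
  per 40,000 iterations, with them roughly 2,000;
* after every w sweep, w is recentered to the per-component sum-to-zero
  constraint, with the removed level folded into beta0. Under a flat
  intercept prior and a connected graph this is an exact
  reparameterization; for multi-component graphs the fold-in uses the
  size-weighted mean and is approximate (all shipped fixtures use
  connected graphs).

Two reparameterizations matter for mixing. First, the chain runs on
mean-centered covariates internally and maps the intercept back on
retention: percent-scale covariates (mean ~25) make beta0 and beta_j
nearly collinear, and split-Rhat sat near 1.4 without centering. Second,
proposal scales adapt by Robbins–Monro (gain (10+t)^-0.6, target
acceptance 0.44) during burn-in only, so the retained chain is Markovian.

Chains are initialized overdispersed: beta0 at logit(mean y) ± N(0, 0.5),
beta jittered around 0, variances log-uniform on [0.005, 0.5] and phi
log-uniform on [20, 500]. (Drawing initial variances from the Gamma(1,
5e-5) precision prior would start every chain at essentially zero
variance — not usefully overdispersed — and its heavy tail occasionally
produces absurd states.)

Defaults: 4 chains × 20,000 iterations, 10,000 burn-in, thin 5 (8,000
retained draws). On the 64-area test lattice this takes ~30 s on one core
and gives split-Rhat < 1.05 for every scalar parameter including each
mu_i. Convergence is summarized by rank-normalized split-Rhat and bulk
ESS (arviz implementations).

Correctness of the sampler is gated on a dense-grid oracle: on a
4-county toy with one covariate, v collapsed and (phi, sigma_w^2) fixed,
posterior means and 95% CrI endpoints of beta0 and beta1 from MCMC must
match 5-dimensional grid integration (an independent scipy-based
implementation, with certified negligible boundary mass) within 3
Monte-Carlo standard errors.

## Reported quantities

* Predicted prevalence: posterior mean of mu_i, with posterior SD and the
  central 95% credible interval. The reported "prediction SD" is the
  posterior SD of mu_i itself, not a back-transformed SD of the linear
  predictor.
* Exceedance probabilities Pr(mu_i > t | data) as the fraction of
  retained draws above t; default thresholds 0.70 and 0.75, configurable.
* A covariate is flagged significant when its 95% CrI excludes zero.
* "Overall" prevalence is the unweighted mean across areas (no
  population weighting).
* Credible-interval endpoints use the median-unbiased empirical quantile
  (Hyndman–Fan type 8).

## Cross-validation

Leave-one-out at the area level: for each fold the model is refit with
that area's likelihood term masked (its random effects remain in the
priors), and the held-out prevalence is predicted per draw as
inv_logit(beta0 + x_i' beta + w_i*), where w_i* is the ICAR conditional
mean — the average of the neighbors' sampled w (0 for an isolated area).
The unstructured effect is unpredictable by construction and enters as 0.
This is a reconstruction of an area-level validation, not a replication
of any specific published procedure. A fast mode restricts to a subset of
folds.

Two structural facts about the resulting Pearson r, established
empirically with this package (tests and the acceptance script recompute
them):

* Information ceiling under signal. Even predicting with the *true*
  parameters, the neighbor-mean rule cannot recover the held-out area's
  own w deviation (conditional variance sigma_w^2 / n_i) or its v_i or
  beta-sampling noise. On 8×8 lattices in the default regime with
  sigma_v^2 small, the true-parameter predictor attains r ≈ 0.6–0.8
  depending on the realization (20-seed mean ≈ 0.69, sd ≈ 0.10); a fitted
  model necessarily sits below its realization's ceiling.
* Leverage anti-correlation under the null. With no covariate or spatial
  signal, held-out predictions have almost no legitimate variance; what
  variance remains comes from re-estimating (beta0, beta) without y_i,
  which moves opposite to y_i's residual. The fold-wise correlation is
  therefore systematically negative and widely dispersed (observed −0.15
  to −0.54 across generator seeds at n = 64), not a tight near-zero
  "no association" value. A near-zero r
  should not be expected from LOOCV correlation under a null; the
  p-value of r is reported but should be read with this artifact in mind.

## Synthetic data generator

`generate_dataset` simulates the exact structure the model assumes: a
rook/queen lattice of unit-square counties (graph + GeoJSON polygons),
spatially smooth covariates (an independent unit-variance ICAR field,
rescaled to a stated percent mean and spread), w drawn exactly from the
ICAR distribution by spectral decomposition (independent normals with
variance sigma_w^2/lambda_j along the positive-eigenvalue eigenvectors),
v iid normal, and y ~ Beta(mu phi, (1-mu) phi). Outcomes landing within
1e-6 of the boundary are redrawn (logged); configurations saturating mu
beyond [0.01, 0.99] for >10% of areas are rejected with advice to shrink
effects.

The default fixture emulates the regime of a US-state county obesity
analysis: 8×8 rook lattice (64 areas, comparable to 67 counties), one
smooth "sedentary %" covariate with mean 25 and spread 5, true
coefficient 0.023 per percentage point, intercept chosen so mean
prevalence ≈ 0.68, sigma_w^2 = 0.05, sigma_v^2 = 0.01, phi = 200, seed
20190401. What the fixture does *not* emulate: survey weighting and
within-county sampling error, irregular county geography and island
adjacency quirks, covariate collinearity structure of real
socio-economic tables. Passing tests therefore demonstrate correctness of
the algorithmic pipeline under the model's own assumptions, not
robustness to real-data violations of them.

In this regime the hyperparameters themselves are only weakly identified:
with one observation per area, phi, sigma_v^2 and (partly) sigma_w^2 all
explain unstructured variation, so their individual posteriors
concentrate away from the generating values (sigma_v^2 in particular is
typically shrunk toward 0 with its share absorbed by phi) and their CrI
coverage is poor. The regression coefficient — the quantity the analysis
interprets — is well calibrated: across 25 replicates its 95% CrI covers
the truth ~92% of the time with mean bias < 0.001. The recovery report
states all of this rather than hiding the variance components.

## Mapping

Static choropleths are matplotlib figures; class breaks are interior
quantiles (5 classes by default; explicit cut points supported for
cross-run comparability) on a light-to-red palette, red = highest burden.
SVG output is byte-deterministic (fixed hash salt, no date metadata).
The interactive map is a single self-contained HTML file with the GeoJSON
payload embedded in a `<script type="application/json">` block — each
feature carries its precomputed fill color, color class and tooltip text
(county name; observed and predicted prevalence and 95% CrI bounds, all
in percent to one decimal; significant risk-factor values) — rendered by
a small inline script with no external references, so it opens offline
and its content is testable by parsing the file.

## Numerical choices

* inv-logit via scipy's expit; logit rejects arguments outside (0, 1).
* Beta log density via log-gamma functions; shapes a = mu phi,
  b = (1-mu) phi.
* Sum-to-zero tolerance 1e-8 when validating w; the field sampler and the
  chain recentring keep it at floating-point residue.
* ICAR eigenvalue cutoff for the null space: lambda > 1e-9 · lambda_max.
* Degenerate draw sets (all equal) report SD exactly 0.
* Ties in quantile class breaks collapse classes; the palette is spread
  over however many classes survive.

## Known limitations

* MCMC is far slower than deterministic approximations for this model
  class; the default budget targets tens of seconds on ~64 areas and a
  few minutes on a few hundred.
* Multi-component graphs: recentring folds a size-weighted mean level
  into the single intercept, which is exact only for connected graphs.
* No BYM2 reparameterization; sigma_w^2 and sigma_v^2 are weakly
  identified with one observation per area (see above).
* Shapefile input is not supported; supply GeoJSON or an edge list.
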