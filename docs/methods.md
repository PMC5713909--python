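# Methods

## The model

`trostar` implements a Bayesian structured additive (geoadditive) logistic
regression for school-based youth tobacco surveys. For student *i* in school
*j*,

    logit P(y_ij = 1) = α + βᵀx_i + γᵀz_j + TRO_j · f(j)

* `y_ij` — binary current-use indicator (past-30-day cigarette or
  e-cigarette use),
* `x_i` — dummy-expanded individual covariates (sex, race/ethnicity in
  three groups, grade, family standard of living, store visits, recall of
  marketing signage, recall of warning signage); reference levels are
  girls, Black, 6th grade, living comfortably, never-visited, no recall,
* `z_j` — three zip-code socioeconomic covariates of the school (percent
  high-school graduates, median household income, percent below poverty),
  standardized within the analysis area to mean 0, sd 1,
* `TRO_j` — indicator that at least one permitted tobacco retail outlet
  lies within the school's buffer,
* `f` — a spatial function over schools with an intrinsic conditional
  autoregressive (ICAR) prior, entering **only through its interaction
  with `TRO_j`**: the spatial effect is the spatially varying association
  of TRO presence with use. At TRO-free schools `f` is informed by the
  prior alone and is reported as weakly identified there.

### Neighbourhood structure

Schools are points, not polygons, so the Markov-random-field neighbourhood
is derived from coordinates: Delaunay triangulation edges by default, or
symmetrized k-nearest-neighbour (k = 4) as an alternative. Disconnected
graphs are repaired by iteratively joining the two closest nodes of
distinct components, so the precision matrix `Q = D − A` (graph Laplacian)
always has rank `n − 1` and the ICAR prior density uses the rank-`n−1`
convention with the generalized determinant.

### Priors

* α, β, γ — independent Normal(0, 100²): effectively flat on the scale of
  logistic coefficients.
* τ² (ICAR variance) — inverse-gamma(0.001, 0.001).
* All hyperparameters are configurable (`ModelConfig`).

### Weights

Two weighting statements are honoured simultaneously as a product weight
per record: the survey sampling weight and the reciprocal of the school's
retained student count (1/n_j), normalized so the weights sum to the
number of records. The weighted Bernoulli likelihood is a
**pseudo-likelihood** — a first-order weight adjustment, not design-based
inference — and both factors can be switched off independently.

### Estimation

Gibbs sampling with Pólya-Gamma (PG) augmentation. The weighted logistic
pseudo-likelihood raises each Bernoulli term to the power of its weight,
which enters the augmentation exactly as the PG shape parameter, so
real-valued weights are supported natively. Update cycle:

1. ω_i ~ PG(w_i, η_i) latent draws;
2. joint Gaussian draw of (α, β, γ) given ω and f;
3. Gaussian Markov-random-field draw of f given ω and (α, β, γ), with
   precision Q/τ² plus data contributions from TRO-exposed records only;
4. re-centre f to sum to zero, the intercept absorbing the shift (the
   linear predictor of TRO-exposed records is exactly unchanged; the
   sum-zero constraint is what makes exp(f) interpretable as risk relative
   to the all-schools baseline);
5. τ² ~ inverse-gamma(a + (n_schools − 1)/2, b + fᵀQf/2).

Because no Pólya-Gamma library is available in the target environment, the
PG sampler is implemented in-package: the infinite sum-of-gammas
representation truncated at 50 terms, plus the *exact* mean of the
discarded tail via the closed form Σ_k 1/((k−1/2)² + a²) = (π/2a)·tanh(πa).
The truncation slightly understates the variance of each latent draw
(≲1% at the default truncation); sampler moments are verified against the
closed-form PG mean and variance, and the full sampler against a
deterministic quadrature oracle and an independent random-walk Metropolis
implementation of the same posterior (available via
`ModelConfig(sampler="rwm")`).

Diagnostics: split-R̂ and effective sample size per fixed effect (via
ArviZ); R̂ > 1.1 raises a warning, not an error. Chains are fully
reproducible under a fixed seed.

### Reported summaries

Adjusted odds ratios are exp(posterior mean coefficient) with equal-tailed
95% credible intervals from the 2.5/97.5 percentiles of the exponentiated
draws; a term is flagged "significant" when the interval excludes 1
(interval-exclusion convention).

## Relative-risk surfaces and kriging

Each retained draw of f is exponentiated per school; under the sum-zero
constraint exp(f_j) is the relative risk at school j compared with the
geometric-mean school. The posterior-mean log-RR values are interpolated
by univariate ordinary kriging:

* empirical semivariogram — classical (Matheron) estimator over 10
  equal-width distance bins up to half the maximum pairwise distance;
* model fit — exponential model (spherical available) by weighted least
  squares with per-bin pair counts as weights, parameters constrained
  nonnegative, deterministic multi-start from a fixed grid. A fitted range
  far below the smallest observed lag is folded into the nugget (the two
  are indistinguishable at the observed distances);
* prediction — ordinary-kriging system per grid node (weights sum to 1 via
  the Lagrange unbiasedness constraint), kriging variance Σwᵢγ(hᵢ₀) + μ.
  Interpolation is on the log scale and exponentiated, keeping the surface
  positive. Grid cells outside the convex hull of the schools (or a
  supplied polygon) are masked.

Hot-spots are cells with kriged RR above a threshold (default 1.0 —
above-baseline risk), replacing colour-scale subjectivity with an explicit
flag; the continuous surface is always exported alongside.

## Synthetic counties

The generator emulates one analysis area of a multi-county school survey:

* 24 schools by default (the study areas span ~20–32), uniform on a
  50 km × 50 km square; enrolment per school uniform in 80–200;
* 75% of schools TRO-exposed (matching the sampling-frame proportion the
  survey reports);
* covariate categories drawn independently from the published non-user
  marginals (e.g. 51.5/48.5 sex split, roughly even grade thirds, 98.7%
  having visited stores near school);
* zip covariates Normal with urban-Texas-like means/sds (configurable);
* f drawn from the ICAR prior on the Delaunay graph via eigendecomposition
  of Q with the null (constant) eigenvector removed — the proper-subspace
  device for simulating an intrinsic field — scaled by √τ² and centred;
* outcomes Bernoulli from the model above with defaults α = −3 (a
  realistic single-digit prevalence), a strong grade gradient, and
  γ = (0.2, −0.2, 0.1);
* optional missingness injection in family standard of living and the
  outcome, with an exact log for testing the exclusion filter;
* sampling weights default to 1 (the survey's weight construction is not
  public; the simulator's inverse-selection-probability model is a
  stand-in and is flagged as such).

What the generator does **not** emulate: the survey's multi-stage design
and design-based variance, within-school covariate correlation,
geodesy/projections (coordinates are abstract planar km), and real
TRO geocoding (the half-mile buffer is abstracted into the binary
indicator). Passing recovery tests therefore demonstrate correctness of
the estimation machinery for the assumed model class, not robustness to
design features the generator omits.

## Recovery harness

`run_recovery` simulates N counties (default 20; 24 schools × 150
students), refits each, and aggregates per-term bias, 95%-interval
coverage over individual-level coefficients, and the correlation between
posterior-mean and true spatial fields at TRO-exposed schools. With the
default harness conditions (10th-grade coefficient log 3,
γ = (0.2, −0.2, 0.1), τ² = 1) the named parameters are recovered to within
a few hundredths, coverage is nominal-like, and the field correlation is
≈0.8.

One caveat worth stating: under the published covariate marginals only
~1.3% of students fall in the "never visited stores" reference cell, so
the split between the intercept and the store-visit coefficient is weakly
identified; its posterior mean carries visible flat-prior skew (and even
maximum likelihood has a per-replicate sd ≈ 0.55 for that term). Interval
coverage remains correct. This mirrors the applied reality that the
store-visit covariate had to be dropped in one analysis area for
convergence; `ModelConfig.covariate_set` supports the same dropping.

## Numerical and design choices

* MCMC defaults: 2000 iterations, 500 burn-in, no thinning; the harness
  uses 1500/500, sized so the full 20-replicate recovery study runs in a
  few minutes on one core.
* Sum-zero of f is enforced every iteration by projection; every retained draw
  sums to zero within 1e-8.
* ICAR simulation/eigen thresholds: eigenvalues below 1e-10 × max are
  treated as null space.
* Kriging uses a 1e-12 diagonal jitter so the nugget-0 exact-interpolation
  path stays well conditioned; duplicate locations are an error naming the
  offending points.
* Weighted chi-square: Pearson X² on the weighted table rescaled to the
  unweighted n — no Rao-Scott design-effect correction, matching the
  information actually available in a published descriptive table; the
  statistic is invariant to uniform weight rescaling.
* Display percentages use half-up rounding to one decimal (the published
  convention), with full precision retained internally.
* One analysis area per run; multiple outcomes loop the full pipeline with
  derived sub-seeds.

## Known limitations

* Pseudo-likelihood weighting gives weighted point estimation, not
  design-based standard errors.
* f at TRO-free schools is identified only by the ICAR prior.
* The PG truncation is an approximation (exact-tail-mean corrected);
  posterior moments were indistinguishable from quadrature oracles in all
  checks, but extremely heavy-tailed augmentation regimes (very large
  |η| with large weights) were not stress-tested.
* Kriging assumes second-order stationarity of log-RR; with ~20-30
  support points the variogram fit is necessarily coarse.
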