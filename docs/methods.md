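# Methods

This note records the statistical model, the inference engine, the synthetic
data-generating process, and the numerical and design choices the package
makes where more than one defensible option existed.

## Model

The observational unit is the survey cluster (PSU): *m* sampled individuals
at a GPS location, *y* of whom report the indicator. The model is a
point-referenced binomial GLM with a logit link,

  Y(s_i) | m(s_i) ~ Binomial(m(s_i), p(s_i)),
  logit p(s_i) = x'(s_i)β + ω(s_i) + ε(s_i),

with a zero-mean Gaussian process ω with exponential covariance
Σ_ω = σ²_ω exp(−φD) on the Euclidean distance matrix D (km), and an iid
Gaussian nugget ε with variance σ²_ε. The spatial range is reported as 3/φ,
the distance at which correlation falls to exp(−3) ≈ 0.05. All coordinates
are planar km in a local frame, so D is exactly Euclidean; no geographic CRS
handling exists anywhere in the package, by design.

### Priors

* β_j ~ N(0, 1000) — effectively flat on the logit scale.
* Range r = 3/φ: penalised-complexity prior π(r) = (λ_r/r²)e^(−λ_r/r) with
  λ_r = −r₀ ln α, so P(r < r₀) = α = 0.01. By default r₀ is 5% of the
  domain's east–west extent; it can be overridden.
* Partial sill σ_ω: exponential PC prior λe^(−λσ). Two directions are
  supported because the tail statement is ambiguous in common usage:
  the default solves P(σ_ω > 3) = 0.01 (the standard PC-prior direction,
  concentrating mass at small σ); `sigma_prior_direction="as_printed"`
  instead solves P(σ_ω < 3) = 0.01, which places 99% of the mass above 3 —
  implausibly diffuse on a logit scale, hence not the default.
* Nugget: Gamma(2, 1) on the precision 1/σ²_ε (the log-gamma-on-log-precision
  convention of common INLA-style software); `iid_prior="as_printed"` puts
  Gamma(2, 1) on the variance instead. Both are proper and weakly
  informative; the default keeps the nugget away from zero, which also
  stabilises the kriging system.

All hyperprior densities are evaluated on θ = (log σ²_ω, log φ, log σ²_ε)
with the appropriate Jacobians; `log_posterior` is the single reference
implementation and is unit-tested term-by-term against scipy densities.

## Inference engine

Estimation is exact-covariance MCMC rather than a mesh/SPDE approximation:
at the few hundred to few thousand clusters this package targets, dense
Cholesky factorisations (O(n³), ~1 ms at n = 300) are cheap, and dropping
the mesh removes a whole class of approximation-tuning questions. The cost
is cubic scaling — beyond roughly n ≈ 3000 the engine becomes impractical,
and that limit is deliberate and documented.

The sampler exploits the model's latent-Gaussian structure:

1. **Collapsed latent update.** The linear predictor v = Xβ + ω + ε has
   Gaussian prior N(0, Q), Q = σ²_β XX' + Σ_ω + σ²_ε I, once β is
   marginalised. v is updated by elliptical slice sampling against the
   binomial likelihood — rejection-free and tuning-free.
2. **Exact β draw.** Given v, the model is the Gaussian linear regression
   v = Xβ + u, so β | v is drawn from its exact conditional (information
   form, Cholesky of X'Σ⁻¹X + I/σ²_β). Drawing β conditionally rather than
   by random walk removes the strong intercept–ω coupling that otherwise
   dominates the autocorrelation time; with this scheme the effective
   sample size of β is typically ≥ 70% of the retained draws.
3. **Adaptive Metropolis on θ.** Given u = v − Xβ, the hyperparameters are
   updated with a joint Gaussian random walk on θ whose proposal covariance
   is adapted (Haario-style, scale 2.38²/3) during burn-in only, so the
   retained chain is a fixed Markov kernel.

Steps 1–2 form a valid partially-collapsed Gibbs block: v is drawn from its
β-marginal conditional and β immediately redrawn from β | v. Defaults are
4000 iterations, 1000 burn-in, thinning 2. Diagnostics (hyper-acceptance
rate in [0.1, 0.6], minimum β ESS by initial-positive-sequence
autocorrelation) are recorded in every fit and flagged with a warning, never
silently. Runs are bit-reproducible given the config seed.

The latent field is initialised at the least-squares projection of the
empirical logits onto the fixed-effect span, with the residual shrunk to the
prior scale of u — starting outside a tight random-effect prior would make
the slice sampler contract only geometrically.

Degenerate variance components can be pinned (`fix_sigma2_omega` etc.), in
which case the model reduces exactly to Bayesian logistic regression; this
is used by the tests as an independent anchor against the GLM MLE.

### Identifiability

σ²_ω, σ²_ε and φ are only weakly separable at a few hundred clusters: part
of a smooth field can be absorbed by the nugget and vice versa. This is a
property of the model, not the sampler, and it is why hyperparameter
summaries carry wide intervals while β — the usual quantity of scientific
interest — is recovered with good coverage. Fitting uses the reported
(displaced) coordinates by default, matching practice with confidentiality-
displaced surveys; `use_true_locations=True` quantifies the displacement
effect in simulations.

## Prediction

For each retained posterior draw (β, σ²_ω, φ, σ²_ε, u), the smooth field at
new locations is simulated from its exact conditional MVN given u (kriging
with nugget: mean C K⁻¹u, covariance Σ** − C K⁻¹C', K = Σ_ω + σ²_ε I). The
per-cell mean and SD over draws form the prediction and uncertainty
surfaces. Joint simulation is done in row blocks (default 512 cells) to
bound memory; blocking leaves per-cell means and SDs exact and only drops
cross-block correlation within individual simulated fields. The nugget is
excluded from cell-level prediction by default — the surface maps the
stable prevalence field, not cluster-level noise — and `include_nugget`
adds σ²_ε to the conditional variance for users who want total-variation
uncertainty. Consequently, at a data site the predicted surface shrinks the
observed proportion toward its spatial neighbours by the nugget fraction;
with the nugget pinned to zero the surface interpolates the data exactly,
which the tests assert.

## Covariate selection

Stage one controls multicollinearity: flag pairs with |r| > 0.8 (absolute
value — strong negative collinearity is equally harmful), fit each flagged
covariate alone (intercept + covariate) in a binomial GLM, keep the
lower-BIC member of each pair, then iteratively drop the worst VIF > 4.
Stage two is steepest-descent backward selection under BIC: try every
single-covariate removal, adopt the best if it lowers BIC, stop otherwise.
BIC uses n = number of clusters, not Bernoulli trials — clusters are the
modelled observational units. Ties in the pairwise BIC retain the
lower-index column, with a warning. The whole pipeline is deterministic.
GLM fitting is IRLS via statsmodels; separation and non-convergence are
surfaced as `converged=False` plus a warning, and such fits are never
scored.

## Cross-validation

k defaults to 5. Folds are a random near-equal partition. Each fold's model
is the full spatial model refitted on the training folds; held-out clusters
are scored by the posterior mean of p at their locations against the
empirical proportions y/m. Metrics: Pearson ρ, RMSE, MAE and percentage
bias 100·Σ(p̂−p)/Σp. Undefined cases (constant vectors, Σp = 0) return NaN
with a warning. The binomial noise floor of y/m at m = 22 is ≈ 0.1 SD, so
pooled RMSE near 0.1 on well-specified simulations is the expected optimum,
not a deficiency.

## District estimators

Rates route by event count: Byar's cube-root approximation above 5 events,
exact Poisson (gamma-quantile) limits at or below 5 — the boundary count 5
goes to the exact method, the conservative choice. The printed-table
lookup of classical practice is replaced by computing the exact limits,
identical by construction. Proportions use Wilson score intervals.
Modelled rates come from saturated exposure-offset Poisson (log link) or
binomial (logit link) GLMs; delta-method intervals are built symmetrically
on the link scale and transformed back, so rate intervals stay
non-negative, while the reported SE is the natural-scale first-order value.
Child mortality between ages 1 and 5 combines the four 12-month segment
probabilities as 1000·(1 − Π(1−q_j)). The published uncertainty metric is
the relative CI width (upper − lower)/estimate, NaN for a zero estimate.

A note on coverage: the Wilson interval's exact coverage at m = 22
oscillates with p because the binomial is discrete; it is ≈ 0.94–0.95 at
moderate p but conservative (0.978) at p = 0.05, where the interval for
y = 4 already excludes 0.05. The tests exercise this directly.

## Synthetic data

The generator emulates the study conditions of a DHS-style national survey:

* clusters placed uniformly (optionally clumped around parent points,
  Thomas-process style) with an urban/rural stratum drawn per cluster
  (default 30% urban);
* the confidentiality displacement: uniform angle, uniform distance up to
  2 km (urban) / 5 km (rural), with ⌊1%⌋ of rural clusters eligible for
  10 km; points leaving the domain are redrawn, not clipped, preserving the
  distance distribution;
* m = 22 trials per cluster by default, the conventional households-per-
  cluster count, overridable;
* covariates as Gaussian random fields (white noise convolved with a
  squared-exponential kernel, default 25 km scale) at 1 km resolution,
  standardized to mean 0 / SD 1, aggregated to 5 km by block means;
* outcomes drawn from the model above with ω built on the TRUE locations —
  displacement then acts as a genuine error-in-locations when fitting uses
  reported coordinates.

What it does not emulate: probability-proportional-to-size sampling and
segment selection (the model conditions on locations, so fitting stages are
unaffected), household questionnaires and weights, realistic covariate
semantics, or real administrative geographies (districts are a rectangular
tiling). Passing tests therefore demonstrate correctness of the machinery
and calibration under the stated generative model, not performance on any
particular country's data.

## Numerical choices

* Jitter 10⁻⁸·max(σ²_ω, 1) on covariance diagonals before factorisation;
  non-PD failures after jitter raise with a diagnostic.
* Cell ownership is half-open ([x_left, x_right) in x, top-edge-inclusive
  in y); zonal membership tests the cell center nudged by +10⁻⁹ cells so a
  tiling of districts partitions the cells exactly — no cell is counted
  twice or lost, which the tests assert.
* Rasters are float64/NaN in memory and float32/−9999 GeoTIFF on disk
  (ModelPixelScale + ModelTiepoint tags carry the planar-km transform);
  rounding happens once, at write time.
* CSV output uses a fixed `%.10g` float format; JSON keys are sorted — with
  seeded RNGs this makes entire pipeline runs byte-identical.

## Problem sizes used in the test suite

The replicated studies in the acceptance tests use 15 replicates of n = 300
clusters (3000 MCMC iterations each), 100 replicates of the n = 800
selection oracle, 10⁴ draws per Wilson coverage point, 10⁵ clusters for the
displacement caps, and an end-to-end run with 200–250 clusters — sizes at
which each property is sharp while a full suite completes in minutes on one
CPU. The same quantities at larger n are a matter of runtime only; nothing
in the implementation is specific to these sizes.

## Known limitations

* Dense-covariance inference is O(n³); thousands of clusters need a sparse
  or low-rank engine this package deliberately does not include.
* The exponential covariance is fixed (no Matérn smoothness parameter), as
  is the logit link.
* Spatially blocked cross-validation — arguably better practice for spatial
  models than random folds — is not implemented; random k-fold matches the
  validation design the pipeline reproduces.
* District vector I/O is GeoJSON only.
* No reprojection: inputs must already be in a planar km frame.
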