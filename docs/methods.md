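# Methods

## Model and likelihood

The outcome of one study-record is a pair (reported?, y): whether the study
reports the count of plant-containing samples at all and, if so, the count
out of N samples. The two-part binomial (TPB) likelihood factorizes the
record's contribution as

* unreported: `1 − ψ`
* reported: `ψ · Binomial(y | N, p)`

so the reporting indicator is informative about ψ only, and unreported
records carry no information about p or anything upstream of it. This is a
missing-not-at-random design in which the missingness model is a single
shared Bernoulli probability; it assumes reporting is independent of the
latent frequency itself (a study is equally likely to omit the count whether
plants were common or rare in its samples).

Model 1 estimates a frequency per species with record-level overdispersion:
`logit(p_i) = α_j(i) + τ_i`, `τ_i ~ N(0, θ_j(i)²)`. The dispersion θ_j is
per-species because species differ in range size, number of contributing
studies and methodology spread. Model 2 decomposes the species intercept
into a species-independent intercept, species-level covariates (log body
mass, then phylogenetic eigenvectors) and a species-level residual
`φ_j ~ N(0, ω²)`, and adds 12 record-level covariates.

Priors are weakly informative: Student-t(3, 0, 5) on intercepts and
coefficients, Exponential(1) on the scales ω and θ_j. ψ gets a Uniform(0,1)
prior: it is neither an intercept nor a hyperparameter, and the uniform
choice makes the reduced reporting-only model conjugate
(ψ | data ~ Beta(1+R, 1+M−R) for R reported of M records), which the test
suite uses as a closed-form calibration target for the sampler. The prior
is config-overridable.

## Inference

All parameters are sampled with a No-U-Turn Sampler written for this
package: multiplicative trajectory doubling with a generalized U-turn
criterion, multinomial selection along the trajectory, dual-averaging step
size adaptation toward a 0.8 acceptance statistic, and a diagonal mass
matrix estimated from the middle half of warmup (variance shrunk toward
unit scale at small sample counts). Energy errors above 1000 are recorded
as divergences and reported per chain, never dropped. Log-density gradients
are derived analytically; a fused numba kernel evaluates them
(~10 µs at the study's data size), with a pure-numpy reference path that
the tests compare against the kernel and against finite differences.

Sampling is done on an unconstrained vector: scales enter as logs (with the
Jacobian), ψ through its logit, and both random-effect blocks are
non-centered (τ_i = θ_j z_i, φ_j = ω z_j with standard-normal z). The
non-centering changes sampler geometry only — the density over the original
parameters is unchanged — and is what makes the Exponential-prior
hierarchies tractable when many species have few reported records.

Run settings default to the production configuration: 4 chains, 5,000
iterations with 2,000 warmup for non-imputed fits; 2,000/1,500 for each
imputed replicate, thinned 1/2 before pooling. Convergence is flagged by
rank-normalized split-Rhat (via arviz) against a 1.01 threshold — the
modern reading of "Rhat ≤ 1.0", which is unattainable as a strict bound for
finite chains. Chains run sequentially from independent RNG streams spawned
from one seed, so every fit is exactly reproducible.

## Phylogenetic eigenvectors

Patristic distances are extracted from the Newick tree (dendropy), the
matrix −D²/2 is Gower double-centered and eigendecomposed, and coordinates
are scaled so each column's sum of squares equals its eigenvalue — hence
Euclidean distances over all positive axes reconstruct D exactly for tree
metrics (asserted to 1e−8 in the tests). Numerically negative eigenvalues
are excluded from the relative-eigenvalue denominator and never retained.
Axis signs are arbitrary; each column is flipped so its largest-magnitude
loading is positive, making outputs deterministic. Retention follows the
broken-stick rule in its leading-run form: keep axes 1..k while the
relative eigenvalue exceeds b_k = (1/S)Σ_{i≥k} 1/i, stopping at the first
failure. The axis count can be overridden in config for analyses that fix
it by inspection.

## Imputation of mentioned records

Records that mention plants without a count are known to have y ≥ 1. Two
schemes fill them:

* **random** — frequency drawn uniformly from the grid 0.01, 0.02, …, 1.00;
* **posterior** — the record's own posterior of p under the non-imputed fit
  is binned (width 0.005 for Model 1, 0.01 for Model 2), the bin containing
  zero is dropped, probabilities renormalized, and a bin midpoint sampled.

The imputed count is round-half-up of p·N clamped to [1, N]; the clamp
encodes the mention itself. Binning is per-record by default (p is
record-indexed); a pooled-over-records variant is available behind a
switch. Each of the (default ten) replicates uses its own seed, is fit with
ψ factors dropped from the likelihood — imputed data say nothing about
reporting — and ψ draws are instead resampled from the non-imputed
posterior. Pooling is plain concatenation of equally sized thinned draw
blocks, so the pooled posterior is the uniform mixture of replicate
posteriors; no Rubin-style variance combination is applied.

## Posterior summaries and decisions

MAP is the mode of a Gaussian KDE (Silverman bandwidth) evaluated on a
2,048-point grid over the draw range; EAP is the draw mean. The HDI is the
shortest contiguous window containing ⌈mass·n⌉ sorted draws (ties broken
toward the lower start), default mass 0.89; credible intervals are
equal-tailed quantiles. The ROPE is [−0.1, 0.1] on the logit scale (half of
the conventional small effect). "%HDI in ROPE" counts the fraction of draws
inside the HDI that fall in the ROPE; an interval-length convention is
available behind a switch, and the two agree at the decision-relevant
values 0 and 1. A coefficient is ROPE-significant iff its HDI is disjoint
from the ROPE; the CI rule (95% interval excludes zero) is always reported
alongside, since the two can disagree for borderline effects. Posterior
predictive checks replicate y for reported records from a subsample of
posterior draws and report per-record predictive quantiles plus the share
of observed counts inside their central 95% predictive interval.

## Synthetic data

The generator mirrors the dataset structure the analysis assumes: 24
species on a random coalescent tree (exponential waiting times, strictly
positive branches), 316 records with a heavily skewed records-per-species
distribution (every species at least once), sample sizes log-uniform on
[10, 250], covariates drawn independently over plausible ranges (seasons as
mutually exclusive dummies with a whole-year all-zero option, precipitation
in raw mm and normalized downstream), binomial counts from the Model 2
generative process, Bernoulli(ψ = 0.37) reporting, and a mentioned flag
assigned with probability 0.12 to unreported records whose latent count is
positive (echoing a 23-of-198 mentioned split). Default effect sizes place
baseline occurrence near 0.15 and a body-mass coefficient of −0.8 with
small PV effects.

What the generator does **not** emulate: real felid body masses or
climates, spatial or temporal autocorrelation in covariates, correlation
between covariates and phylogeny, and any dependence of reporting on the
latent frequency. Passing tests therefore demonstrate that the machinery
recovers the truth under the model's own assumptions — not that those
assumptions hold for any particular literature compilation.

## Numerical choices and problem sizes

* p is parameterized through the logit, so binomial terms never evaluate
  log 0; ψ terms use softplus forms stable at extreme logits.
* Degenerate inputs fail loudly: constant vectors cannot be min-max
  normalized, zero-variance columns are reported as undefined correlations,
  all-zero-bin posteriors raise instead of silently renormalizing.
* Log body mass uses the natural log and species designs are uncentered by
  default; both choices only rescale/shift the intercept and are recorded
  in the run manifest.
* The test suite and the acceptance script use reduced problem sizes chosen
  as the package's own smoke configuration: 2 chains and hundreds (not
  thousands) of iterations, 10 recovery replicates, 2–3 imputation
  replicates on small datasets. At those sizes some fits are legitimately
  flagged non-converged by the 1.01 Rhat threshold; the assertions target
  quantities that are stable at that resolution (coverage, closed-form
  posterior moments, determinism).

## Known limitations

* ψ is shared across all records; there is no covariate model for
  reporting.
* The sampler adapts a diagonal mass matrix only; strongly correlated
  posteriors (e.g. intercept vs uncentered covariates) cost deeper
  trajectories rather than failing.
* Pooled (imputed) fits report per-replicate Rhat; there is no across-
  replicate convergence statistic, since replicates target different
  imputed datasets by construction.
* No model comparison (WAIC/LOO), zero-inflated or beta-binomial variants.
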