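# Methods

## Model

Cluster-level vaccination counts are modeled as binomial with a
logit-linear predictor,

    Y_j ~ Binomial(n_j, p_j),    logit(p_j) = α + Σ_z β_z X_{z,j} + ζ_j,

with ζ a zero-mean stationary Gaussian field over projected km
coordinates. The covariance is Matérn,

    C(d) = σ² · 2^{1−ν}/Γ(ν) · (κd)^ν K_ν(κd),    κ = √(8ν)/ρ,

so that the range ρ is the distance at which correlation has decayed to
≈ 0.1 (≈ 0.14 at ν = 1, exactly exp(−2) ≈ 0.135 at ν = ½). ν is fixed
per fit (default 1, the usual two-dimensional default); σ and ρ are
estimated.

The field is represented *exactly* as a dense multivariate normal over
the cluster locations. Sparse GMRF/SPDE machinery is an approximation
device for large problems; at the few-hundred-cluster scale this package
targets, the dense Cholesky is cheap and exact, so we use the model the
covariance function actually defines.

Priors: improper flat on α (no density term); independent N(0,
precision 10⁻⁴) on each β; log-normal hyperpriors on σ and ρ. The
hyperprior location is a data-scale heuristic — median σ = 1, median
ρ = one fifth of the bounding-box diagonal of the data, both with log-SD
1.5 — and is recorded in every `FitResult` for reproducibility.

## Inference engines

**laplace** (default). A nested-Laplace scheme over ψ = (log σ, log ρ):

1. For fixed ψ, the conditional posterior of the latent block
   u = (α, β, ζ) is log-concave; its mode u*(ψ) is found by damped
   Newton iterations (analytic binomial gradient/Hessian), giving the
   Gaussian approximation N(u*, H⁻¹) with H = AᵀWA + Q(ψ).
2. The hyperparameter posterior is explored on a 7×7 grid centred at
   the mode of the Laplace-approximate marginal (found by Nelder–Mead),
   with geometry set by the local curvature (finite differences),
   spacing 0.7 SD per step.
3. Per grid node, Gaussian candidates are oversampled 3×, weighted by
   the exact conditional density over the Gaussian proposal density, and
   resampled. The mean importance weight also re-estimates each node's
   marginal likelihood. This removes most of the Gaussian-approximation
   bias of the latent block — the importance effective-sample-size
   fraction is reported in the diagnostics (typically 0.2–0.8).
4. Final draws mix over nodes proportionally to the corrected weights.

The engine is deterministic given a seed, and a 300-cluster fit with
4,000 stored draws takes seconds.

**mcmc.** Three interleaved moves per iteration: (i) adaptive
random-walk Metropolis on (α, β), with the proposal covariance learned
during burn-in; (ii) elliptical slice sampling on ζ, which is exact
under the Gaussian prior and needs no tuning; (iii) adaptive random-walk
Metropolis on (log σ, log ρ) given ζ. Because β and ζ are confounded
through η = α + Xβ + ζ, a fourth likelihood-preserving "ridge" move
proposes (α, β) += δ together with ζ −= [1 X]δ, accepted on the prior
ratio alone; without it the chain random-walks along the β–ζ ridge and
the β means converge slowly. Scales adapt toward 20–40 % acceptance
during burn-in, which is the first half of a run twice the requested
draw count; no thinning (all post-burn-in draws are stored). The stored
default is 150,000 draws; experiments and tests override this downward.

Cross-checks in the test suite: the two engines agree on posterior means
of α and β within 0.05 on a 50-cluster survey, and the laplace engine
matches a dense numerical-integration posterior on an
intercept-only/no-field problem.

## Prediction

For each retained posterior draw (default: a seeded subsample of 1,000),
ζ is interpolated to new locations by the conditional-Gaussian (kriging)
formulas under that draw's (σ, ρ): mean Σ*Σ⁻¹ζ, covariance
Σ** − Σ*Σ⁻¹Σ*ᵀ. Draws sharing hyperparameter values — the Laplace grid
nodes — share one factorization. Point sets up to 512 are sampled
jointly; larger grids are sampled cellwise from the marginal
conditional, which leaves all cellwise summaries (mean, SD, CrI)
identical but does not preserve cross-cell correlation of the sampled
field. Fixed effects use the *fit-time* standardization constants, the
draw-level linear predictor is inverse-logit transformed, and summaries
are computed on the probability scale (transform per draw, then
summarize — not the transform of the summarized predictor; the two
differ, and the draw-wise version is the posterior of p(s)).
Uncertainty maps are cellwise 95 % CrI widths. Prediction outside the
data bounding box is allowed and logged; cells with missing covariates
become nodata.

## Synthetic data

The simulator mirrors the generative model exactly: uniform cluster
placement in a rectangular extent, deterministic smooth covariate
surfaces (constant / linear gradient / Gaussian bump) rendered both as
rasters and evaluated analytically at cluster points, an exact dense
Matérn field draw (Cholesky with an escalating diagonal jitter ladder
1e-10 → 1e-6 if needed), and binomial counts. It deliberately does
*not* emulate DHS two-stage stratified sampling, urban/rural strata,
survey weights, or GPS displacement — so passing recovery tests show the
estimator is correct under the model's own assumptions, not that it is
robust to real survey-design artifacts.

Reference study conditions (used by the recovery and model-selection
experiments and the reproduction script): a 500 km square, 300 clusters
of 30 children, α = 0, β = (0.6, −0.3) on the raw covariate scale,
σ = 0.8, ρ = 50 km, ν = 1. The two covariates are a west–east linear
gradient spanning ±2 and a Gaussian bump (amplitude 3, width 80 km)
placed off-centre. The bump's width is deliberately different from the
field range so the coefficient is identifiable; a covariate whose only
variation is at the field's own wavelength measures confounding, not
estimator quality. Coefficient recovery is scored on the raw scale by
dividing standardized-scale draws by the design-matrix column SDs.

## Numerical choices

* Distances in km via a single equirectangular projection about the
  study centroid (the Matérn kernel needs metric coordinates).
* Raster sampling is nearest-cell; a point exactly on an interior cell
  boundary goes to the lower index.
* Covariates are z-scored with the n−1 SD; constant columns are centred
  and left unscaled. Rows with any missing covariate are dropped
  listwise with a reported count. An optional log1p pre-transform is
  available for heavy-tailed covariates such as population density
  (default off).
* The collinearity screen flags the later member of any pair with
  |r| ≥ 0.8 but never removes anything itself.
* Cholesky factorizations of Matérn covariance matrices retry with
  diagonal jitter 0 → 1e-10 → 1e-8 → 1e-6 (scaled by the mean diagonal)
  before raising.
* WAIC uses the variance penalty (the p_waic2 variant); points with
  p_waic_i > 0.4 trigger a warning, not an error. Model comparison
  refuses fits whose observation fingerprints differ.
* Display rounding for coverage tables is one decimal, half away from
  zero; pooled cells are computed from summed counts, never from means
  of percentages, so the pooled column is the count-weighted identity.

## Limitations

* One survey year is fitted at a time; there is no spatio-temporal
  joint model.
* No survey design weights; cluster counts are treated as simple
  binomial trials.
* The Laplace engine's hyperparameter grid covers ±2.1 SD of the
  approximate ψ posterior; extremely heavy-tailed hyperparameter
  posteriors (tiny n) are better served by the mcmc engine.
* Kriging over large grids samples cells from marginal conditionals;
  quantities that depend on the joint field across cells (e.g. the
  posterior of a regional *average* of p) would need joint sampling.
* The equirectangular projection is adequate at country scale but not
  for continental extents.
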