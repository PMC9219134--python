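# geocoverage

Bayesian model-based geostatistics for mapping childhood vaccination
coverage from cluster-survey data.

National immunization surveys (DHS-style) record, for each GPS-located
sampling cluster *j*, how many children were examined (*n<sub>j</sub>*) and how many
had received a vaccine (*Y<sub>j</sub>*). Clusters are sparse, so producing a
continuous coverage map requires a spatial model. `geocoverage`
implements the standard model-based-geostatistics approach:

```
Y_j ~ Binomial(n_j, p_j)
logit(p_j) = α + Σ_z β_z X_{z,j} + ζ_j
```

where *X* are environmental/access covariates (temperature,
precipitation, altitude, travel time to the nearest city, distance to
health facilities, distance to water, population density, …) sampled
from rasters at the cluster locations, and ζ is a zero-mean Gaussian
field with Matérn covariance — marginal SD σ, smoothness ν, and range ρ
defined as the distance at which correlation falls to ≈ 0.1
(κ = √(8ν)/ρ). Priors: flat on α, N(0, precision 10⁻⁴) on each β,
weakly-informative log-normals on σ and ρ.

The package covers the full workflow:

* **data_io** — cluster CSV/TSV tables, ESRI ASCII-grid covariate
  rasters, GeoJSON region polygons, nearest-cell extraction, z-scored
  design matrices, a Pearson collinearity screen;
* **synthetic** — survey simulator with the model's exact generative
  structure (uniform clusters, smooth covariate surfaces, exact dense
  Matérn field draw, binomial counts), for recovery experiments;
* **model** — the posterior itself, with two engines: `laplace`
  (nested-Laplace over a hyperparameter grid with importance-corrected
  Gaussian conditionals; fast, deterministic given a seed) and `mcmc`
  (elliptical slice sampling for ζ plus adaptive Metropolis blocks);
* **predict** — kriging interpolation of ζ per posterior draw, logit
  back-transform, cellwise mean/SD/95 % CrI surfaces and CrI-width
  uncertainty maps;
* **selection** — WAIC = −2(lppd − p_waic) and model ranking;
* **trends** — count-weighted coverage tables per region × survey year
  and temporal-change statistics.

## Worked example

Simulate a survey, fit it, and compare against the intercept-only model:

```python
import geocoverage as gc
from geocoverage.synthetic import CovariateSpec, SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(
    seed=42, region_extent=(300.0, 300.0), n_clusters=100,
    n_children_range=(25, 25), true_alpha=0.2, true_betas=(0.6,),
    true_sigma=0.8, true_range=50.0,
    covariate_spec=[CovariateSpec("grad", "linear-gradient",
                                  {"start": -2.0, "stop": 2.0, "axis": "x"})]))
cov = gc.build_design_matrix(ds.records, ds.rasters)
spec = gc.ModelSpec(covariate_names=cov.columns, include_spatial_field=True, nu=1.0)
fit = gc.fit(ds.records, cov, spec, engine="laplace", seed=7, n_draws=4000)
print(gc.summarize(fit).table[["name", "mean", "cri_low", "cri_high", "significant"]])
```

prints

```
     name   mean  cri_low  cri_high  significant
    alpha  0.241   -0.252     0.727        False
beta_grad  0.695    0.271     1.039         True
log_sigma -0.287   -0.592     0.104        False
  log_rho  4.345    3.760     4.961         True
```

The `beta_grad` row is on the standardized-covariate scale; dividing by
the covariate SD (≈ 1.10 here) returns it to the raw scale, giving a
posterior mean ≈ 0.63 with a CrI covering the generating value 0.6. The
effect is flagged significant because its 95 % credible interval
excludes zero, and `exp(log_rho) ≈ 77 km` is the right order for the
generating range ρ = 50 km at this small sample size.

A prediction surface and a WAIC comparison then follow:

```python
surface = gc.predict_surface(fit, ds.rasters, cell_size=20.0, n_pred_draws=1000, seed=9)
null = gc.fit(ds.records, None,
              gc.ModelSpec(include_spatial_field=True, label="intercept-only"),
              seed=7, n_draws=4000)
print(gc.compare_models([fit, null]))
```

```
   model_label    lppd  p_waic   waic  rank
          grad -205.13   36.11 482.49     1
intercept-only -207.40   35.97 486.74     2
```

The covariate model attains the lower WAIC and ranks first.

The same pipeline is scriptable from the shell via the `geocoverage`
CLI (`simulate`, `fit`, `predict`, `compare`, `describe`, `run`).

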