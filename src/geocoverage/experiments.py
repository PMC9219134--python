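"""Canned simulation experiments: parameter recovery, engine agreement,
covariate-model selection.

These define the package's reference study conditions — a 500 km square
with 300 uniformly placed clusters of 30 children each, two smooth
covariates (a west–east gradient and a localized bump), fixed effects
β = (0.6, −0.3) on the raw covariate scale, and a latent Matérn field
with σ = 0.8, ρ = 50 km, ν = 1 — and run the full generate→fit→evaluate
loop on them.  Both the test suite and the reproduction script build on
these functions so the conditions stay in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import data_io, model, selection
from .synthetic import CovariateSpec, SimulationConfig, simulate_dataset

__all__ = [
    "RECOVERY_TRUE_BETAS",
    "recovery_config",
    "RecoveryResult",
    "run_recovery_replicate",
    "run_recovery_study",
    "run_engine_agreement",
]

RECOVERY_TRUE_BETAS = (0.6, -0.3)

_RECOVERY_COVARIATES = [
    CovariateSpec("grad", "linear-gradient", {"start": -2.0, "stop": 2.0, "axis": "x"}),
    CovariateSpec("bump", "gaussian-bump",
                  {"amplitude": 3.0, "width": 80.0, "center_x": 180.0, "center_y": 320.0}),
]


def recovery_config(seed: int) -> SimulationConfig:
    """The reference recovery-study conditions with the given seed."""
    return SimulationConfig(
        seed=seed, region_extent=(500.0, 500.0), n_clusters=300,
        n_children_range=(30, 30), true_alpha=0.0,
        true_betas=RECOVERY_TRUE_BETAS, true_sigma=0.8, true_range=50.0,
        nu=1.0, covariate_spec=_RECOVERY_COVARIATES, cell_size=10.0,
    )


@dataclass
class RecoveryResult:
    """Per-replicate outcomes on the raw (unstandardized) coefficient scale."""

    beta_mean: np.ndarray  # posterior means, raw scale
    beta_cri: np.ndarray  # (z, 2) CrI endpoints, raw scale
    covered: np.ndarray  # bool per coefficient
    abs_err: np.ndarray
    waic_full: float
    waic_null: float

    @property
    def full_model_wins(self) -> bool:
        return self.waic_full < self.waic_null


def run_recovery_replicate(
    sim_seed: int, fit_seed: int, n_draws: int = 4000, fit_null: bool = True
) -> RecoveryResult:
    """Simulate one survey under the reference conditions, fit the full
    spatial model (and optionally the intercept-only comparator), and
    score coefficient recovery against the generating values."""
    ds = simulate_dataset(recovery_config(sim_seed))
    cov = data_io.build_design_matrix(ds.records, ds.rasters)
    true = np.asarray(RECOVERY_TRUE_BETAS)
    spec = model.ModelSpec(covariate_names=cov.columns,
                           include_spatial_field=True, nu=1.0, label="full")
    fr = model.fit(ds.records, cov, spec, engine="laplace",
                   seed=fit_seed, n_draws=n_draws)
    z = len(true)
    means = np.empty(z)
    cris = np.empty((z, 2))
    covered = np.empty(z, dtype=bool)
    for j, name in enumerate(cov.columns):
        raw = fr.param_draws(f"beta_{name}") / cov.sds[j]
        means[j] = raw.mean()
        cris[j] = np.quantile(raw, [0.025, 0.975])
        covered[j] = cris[j, 0] <= true[j] <= cris[j, 1]
    waic_full = selection.waic(fr.pointwise_loglik).waic
    waic_null = np.nan
    if fit_null:
        spec0 = model.ModelSpec(covariate_names=[], include_spatial_field=True,
                                nu=1.0, label="intercept-only")
        f0 = model.fit(ds.records, None, spec0, engine="laplace",
                       seed=fit_seed, n_draws=n_draws)
        waic_null = selection.waic(f0.pointwise_loglik).waic
    return RecoveryResult(beta_mean=means, beta_cri=cris, covered=covered,
                          abs_err=np.abs(means - true),
                          waic_full=waic_full, waic_null=waic_null)


def run_recovery_study(
    seed: int, n_replicates: int = 20, n_draws: int = 4000, fit_null: bool = True
) -> list[RecoveryResult]:
    """Independent replicates of the recovery experiment; seeds are spawned
    deterministically from the master seed."""
    ss = np.random.SeedSequence(seed)
    sim_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_replicates)]
    return [
        run_recovery_replicate(sim_seeds[i], fit_seed=sim_seeds[i] ^ 0x5A5A,
                               n_draws=n_draws, fit_null=fit_null)
        for i in range(n_replicates)
    ]


def run_engine_agreement(seed: int, n_draws: int = 5000) -> dict[str, dict[str, float]]:
    """Fit one 50-cluster simulated survey with both engines; return the
    posterior mean and CrI endpoints of α and β under each."""
    cfg = SimulationConfig(
        seed=seed, region_extent=(300.0, 300.0), n_clusters=50,
        n_children_range=(30, 30), true_alpha=0.3, true_betas=(0.6,),
        true_sigma=0.8, true_range=50.0, nu=1.0,
        covariate_spec=[CovariateSpec("grad", "linear-gradient",
                                      {"start": -2.0, "stop": 2.0, "axis": "x"})],
    )
    ds = simulate_dataset(cfg)
    cov = data_io.build_design_matrix(ds.records, ds.rasters)
    spec = model.ModelSpec(covariate_names=cov.columns,
                           include_spatial_field=True, nu=1.0)
    out: dict[str, dict[str, float]] = {}
    for engine in ("laplace", "mcmc"):
        fr = model.fit(ds.records, cov, spec, engine=engine,
                       seed=seed + 1, n_draws=n_draws)
        stats = {}
        for name in ("alpha", "beta_grad"):
            d = fr.param_draws(name)
            lo, hi = np.quantile(d, [0.025, 0.975])
            stats[name] = {"mean": float(d.mean()), "cri_low": float(lo),
                           "cri_high": float(hi)}
        out[engine] = stats
    return out
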