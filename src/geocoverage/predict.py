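"""Coverage prediction at unsampled locations.

For each retained posterior draw the latent field is interpolated to the
new locations by conditional-Gaussian (kriging) formulas under that draw's
(σ, ρ), the fixed effects are added at each location, and the linear
predictor is back-transformed from the logit to the probability scale.
Cellwise summaries (mean, SD, central 95% interval) are computed over the
transformed draws — the transform is applied per draw, then summarized,
which differs from transforming the summarized linear predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .data_io import CovariateRaster, extract_at_points
from .matern import MaternParams, chol_with_jitter, matern_covariance, pairwise_distances
from .model import FitResult

__all__ = ["KrigeResult", "PredictionSurface", "krige_field", "predict_surface", "uncertainty_surface"]

logger = logging.getLogger(__name__)

#: point sets up to this size are sampled jointly (full conditional
#: covariance); larger sets fall back to cellwise marginal sampling
JOINT_SAMPLING_LIMIT = 512


@dataclass
class KrigeResult:
    """Conditional draws of the latent field at new points."""

    zeta: np.ndarray  # n_selected_draws × n_new
    cond_mean: np.ndarray  # same shape: per-draw conditional means
    cond_sd: np.ndarray  # per-draw marginal conditional SDs
    draw_indices: np.ndarray  # rows of fit.draws used
    extrapolated: np.ndarray  # bool per new point: outside the data bounding box


def _select_draws(fit: FitResult, draw_subset: int, rng: np.random.Generator) -> np.ndarray:
    if draw_subset >= fit.n_draws:
        return np.arange(fit.n_draws)
    return np.sort(rng.choice(fit.n_draws, size=draw_subset, replace=False))


def krige_field(
    fit: FitResult,
    new_points: Sequence[tuple[float, float]],
    draw_subset: int = 1000,
    seed: int = 0,
    joint: bool | None = None,
) -> KrigeResult:
    """Sample ζ at new points from the conditional Gaussian per draw.

    Under each retained draw's (σ, ρ), ζ* | ζ ~ N(Σ*Σ⁻¹ζ, Σ** − Σ*Σ⁻¹Σ*ᵀ).
    With ``joint`` (the default for ≤ 512 points) samples carry the full
    cross-point conditional covariance; otherwise each point is sampled
    from its marginal conditional — cellwise summaries are identical.
    Draws sharing hyperparameter values (the Laplace grid nodes) share one
    factorization.
    """
    pts = np.atleast_2d(np.asarray(new_points, dtype=float))
    n_new = len(pts)
    if joint is None:
        joint = n_new <= JOINT_SAMPLING_LIMIT
    rng = np.random.default_rng(seed)
    idx = _select_draws(fit, draw_subset, rng)

    lo = fit.locations.min(axis=0)
    hi = fit.locations.max(axis=0)
    extrapolated = np.any((pts < lo) | (pts > hi), axis=1)
    if extrapolated.any():
        logger.info("kriging extrapolates beyond the data bounding box at %d/%d points",
                    int(extrapolated.sum()), n_new)

    if not fit.spec.include_spatial_field:
        zeros = np.zeros((len(idx), n_new))
        return KrigeResult(zeros, zeros.copy(), zeros.copy(), idx, extrapolated)

    ls = fit.param_draws("log_sigma")[idx]
    lr = fit.param_draws("log_rho")[idx]
    zeta_obs = fit.zeta_draws[idx]
    d_oo = pairwise_distances(fit.locations)
    d_no = pairwise_distances(pts, fit.locations)
    d_nn = pairwise_distances(pts) if joint else None

    out = np.empty((len(idx), n_new))
    cmean = np.empty_like(out)
    csd = np.empty_like(out)
    psi_key = np.round(np.column_stack([ls, lr]), 12)
    for key in np.unique(psi_key, axis=0):
        rows = np.flatnonzero((psi_key == key).all(axis=1))
        params = MaternParams(float(np.exp(key[0])), float(np.exp(key[1])), fit.spec.nu)
        S_oo = matern_covariance(d_oo, params)
        S_no = matern_covariance(d_no, params)
        L, jit = chol_with_jitter(S_oo)
        W = cho_solve((L, True), S_no.T).T  # n_new × n_obs kriging weights
        mu = zeta_obs[rows] @ W.T  # len(rows) × n_new
        if joint:
            S_nn = matern_covariance(d_nn, params)
            C = S_nn - W @ S_no.T
            C = 0.5 * (C + C.T)
            Lc, _ = chol_with_jitter(C + 1e-12 * np.eye(n_new))
            Z = rng.standard_normal((len(rows), n_new))
            samp = mu + Z @ Lc.T
            var = np.clip(np.diag(C), 0.0, None)
            sd = np.broadcast_to(np.sqrt(var), mu.shape)
        else:
            var = np.clip(params.sigma**2 - np.sum(W * S_no, axis=1), 0.0, None)
            sd = np.broadcast_to(np.sqrt(var), mu.shape)
            samp = mu + rng.standard_normal(mu.shape) * sd
        out[rows] = samp
        cmean[rows] = mu
        csd[rows] = sd
    return KrigeResult(out, cmean, csd, idx, extrapolated)


@dataclass
class PredictionSurface:
    """Gridded posterior coverage with cellwise uncertainty."""

    grid: CovariateRaster  # geometry template; values unused
    mean_p: np.ndarray
    sd_p: np.ndarray
    cri_low_p: np.ndarray
    cri_high_p: np.ndarray
    n_draws_used: int


def predict_surface(
    fit: FitResult,
    rasters: Sequence[CovariateRaster],
    cell_size: float,
    n_pred_draws: int = 1000,
    seed: int = 0,
) -> PredictionSurface:
    """Posterior coverage surface p(s) = invlogit(α + X(s)β + ζ*(s)).

    Covariates are sampled at grid-cell centers and standardized with the
    FIT-TIME means/SDs stored in the fit.  Cells with any missing
    covariate become nodata (NaN).
    """
    by_name = {r.name: r for r in rasters}
    missing = [c for c in fit.cov_columns if c not in by_name]
    if missing:
        raise ValueError(f"rasters missing for fitted covariates: {missing}")

    if rasters:
        xmin, ymin, xmax, ymax = rasters[0].extent
    else:  # intercept-only: grid over the data bounding box
        xmin, ymin = fit.locations.min(axis=0)
        xmax, ymax = fit.locations.max(axis=0)
    n_cols = max(1, int(round((xmax - xmin) / cell_size)))
    n_rows = max(1, int(round((ymax - ymin) / cell_size)))
    grid = CovariateRaster(
        name="prediction", origin_x=xmin, origin_y=ymin, cell_size=cell_size,
        values=np.zeros((n_rows, n_cols)),
    )
    Xc, Yc = grid.cell_centers()
    pts = np.column_stack([Xc.ravel(), Yc.ravel()])

    z = len(fit.cov_columns)
    if z:
        raw = np.column_stack([extract_at_points(by_name[c], pts) for c in fit.cov_columns])
        valid = ~np.isnan(raw).any(axis=1)
        Xs = (raw[valid] - fit.cov_means) / fit.cov_sds
    else:
        valid = np.ones(len(pts), dtype=bool)
        Xs = np.empty((len(pts), 0))

    kr = krige_field(fit, pts[valid], draw_subset=n_pred_draws, seed=seed, joint=False)
    idx = kr.draw_indices
    alpha = fit.param_draws("alpha")[idx][:, None]
    if z:
        beta = np.column_stack([fit.param_draws(f"beta_{c}")[idx] for c in fit.cov_columns])
        eta = alpha + beta @ Xs.T + kr.zeta
    else:
        eta = alpha + kr.zeta
    p = expit(eta)  # n_used × n_valid

    shape = (n_rows, n_cols)
    def fill(vec):
        full = np.full(len(pts), np.nan)
        full[valid] = vec
        return full.reshape(shape)

    qlo, qhi = np.quantile(p, [0.025, 0.975], axis=0)
    return PredictionSurface(
        grid=grid,
        mean_p=fill(p.mean(axis=0)),
        sd_p=fill(p.std(axis=0, ddof=1)),
        cri_low_p=fill(qlo),
        cri_high_p=fill(qhi),
        n_draws_used=len(idx),
    )


def uncertainty_surface(surface: PredictionSurface) -> CovariateRaster:
    """Cellwise 95% credible-interval width (high − low)."""
    width = surface.cri_high_p - surface.cri_low_p
    g = surface.grid
    return CovariateRaster(
        name="cri_width", origin_x=g.origin_x, origin_y=g.origin_y,
        cell_size=g.cell_size, values=width,
    )
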