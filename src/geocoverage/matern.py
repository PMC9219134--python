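"""Matérn correlation/covariance for the latent spatial field.

Parameterization: marginal SD σ, smoothness ν, and range ρ defined as the
distance at which correlation has decayed to ≈ 0.1, via the scaling
κ = √(8ν)/ρ.  With ν = 0.5 the kernel reduces exactly to exp(−2d/ρ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma, kv


@dataclass(frozen=True)
class MaternParams:
    """Hyperparameters of the Matérn field: σ (marginal SD), ρ (range in
    km, correlation ≈ 0.1 at d = ρ), ν (smoothness, fixed per fit)."""

    sigma: float
    range_rho: float
    nu: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0 or self.range_rho <= 0 or self.nu <= 0:
            raise ValueError("sigma, range_rho and nu must all be > 0")


class CovarianceError(RuntimeError):
    """Covariance matrix not positive definite after the jitter ladder."""


#: successive diagonal jitters tried before giving up
JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)


def matern_correlation(d, params: MaternParams) -> np.ndarray:
    """Matérn correlation at distance(s) d ≥ 0 (km).

    corr(d) = 2^{1−ν}/Γ(ν) · (κd)^ν · K_ν(κd),  κ = √(8ν)/ρ; corr(0) = 1.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    nu = params.nu
    kappa = np.sqrt(8.0 * nu) / params.range_rho
    kd = kappa * d
    out = np.ones_like(kd)
    pos = kd > 0
    kdp = kd[pos]
    out[pos] = (2.0 ** (1.0 - nu) / gamma(nu)) * kdp**nu * kv(nu, kdp)
    # K_nu underflows to 0 for very large kd; that limit is correct
    out[pos] = np.nan_to_num(out[pos], nan=0.0)
    return out if out.ndim else float(out)


def matern_covariance(d, params: MaternParams) -> np.ndarray:
    """σ² × correlation."""
    return params.sigma**2 * matern_correlation(d, params)


def pairwise_distances(points_a: np.ndarray, points_b: np.ndarray | None = None) -> np.ndarray:
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = a if points_b is None else np.atleast_2d(np.asarray(points_b, dtype=float))
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def covariance_matrix(points: np.ndarray, params: MaternParams) -> np.ndarray:
    return matern_covariance(pairwise_distances(points), params)


def chol_with_jitter(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor, escalating diagonal jitter if needed.

    Jitter is scaled by the mean diagonal.  Returns (L, jitter_used);
    raises CovarianceError listing the ladder if every rung fails.
    """
    scale = float(np.mean(np.diag(cov))) or 1.0
    for jit in JITTER_LADDER:
        try:
            L = np.linalg.cholesky(cov + jit * scale * np.eye(cov.shape[0]))
            return L, jit
        except np.linalg.LinAlgError:
            continue
    raise CovarianceError(
        f"covariance not positive definite after jitter ladder {JITTER_LADDER}"
    )
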