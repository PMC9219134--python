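"""Bayesian binomial spatial regression with a latent Matérn field.

The model: per survey cluster j with n_j children of whom Y_j are
vaccinated,

    Y_j ~ Binomial(n_j, p_j),
    logit(p_j) = α + Σ_z β_z X_{z,j} + ζ_j,

where ζ is a zero-mean Gaussian field with Matérn covariance (marginal SD
σ, range ρ, smoothness ν).  Priors: improper flat on the intercept α,
N(0, precision 1e-4) on each coefficient β, and weakly-informative
log-normal hyperpriors on σ and ρ centred on data-scale heuristics.

Two inference engines share the same posterior:

* ``laplace`` — a nested-Laplace scheme: for each node of a grid over
  (log σ, log ρ), the conditional posterior of the latent block
  (α, β, ζ) is replaced by its Gaussian (Laplace) approximation at the
  mode found by Newton iterations; nodes are weighted by the approximate
  marginal likelihood and posterior draws are composed by mixing over
  nodes.  Fast and deterministic given a seed.
* ``mcmc`` — elliptical slice sampling for ζ (exact under the Gaussian
  prior, tuning-free) interleaved with adaptive random-walk Metropolis
  blocks for (α, β) and (log σ, log ρ).  Burn-in is half the run.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from .data_io import ClusterRecord, CovariateMatrix
from .matern import MaternParams, chol_with_jitter, covariance_matrix

__all__ = [
    "HyperPrior",
    "ModelSpec",
    "SpatialField",
    "ModelData",
    "FitResult",
    "PosteriorSummary",
    "binomial_loglik",
    "log_posterior",
    "fit",
    "summarize",
    "default_hyperprior",
]

DEFAULT_N_DRAWS = 150_000  # posterior samples stored by default


@dataclass(frozen=True)
class HyperPrior:
    """Independent log-normal priors on σ and ρ (parameters of log values)."""

    log_sigma_mean: float = 0.0
    log_sigma_sd: float = 1.5
    log_rho_mean: float = 4.0
    log_rho_sd: float = 1.5

    def logpdf(self, log_sigma: float, log_rho: float) -> float:
        out = -0.5 * ((log_sigma - self.log_sigma_mean) / self.log_sigma_sd) ** 2
        out += -0.5 * ((log_rho - self.log_rho_mean) / self.log_rho_sd) ** 2
        out -= np.log(2 * np.pi * self.log_sigma_sd * self.log_rho_sd)
        return float(out)


def default_hyperprior(locations: np.ndarray) -> HyperPrior:
    """σ prior median 1; ρ prior median = 1/5 of the bounding-box diagonal."""
    locs = np.atleast_2d(locations)
    span = locs.max(axis=0) - locs.min(axis=0)
    diag = float(np.hypot(*span)) or 1.0
    return HyperPrior(log_sigma_mean=0.0, log_rho_mean=float(np.log(diag / 5.0)))


@dataclass
class ModelSpec:
    """What to fit: covariate set, spatial field on/off, priors."""

    covariate_names: list[str] = field(default_factory=list)
    include_spatial_field: bool = True
    nu: float = 1.0
    prior_beta_precision: float = 1e-4
    hyperprior: HyperPrior | None = None  # None -> data-scale default
    label: str = ""

    def __post_init__(self):
        if self.prior_beta_precision <= 0:
            raise ValueError("prior_beta_precision must be > 0")


@dataclass
class SpatialField:
    """Latent field values ζ_j at a set of locations."""

    locations: np.ndarray
    zeta: np.ndarray
    params: MaternParams

    def __post_init__(self):
        if len(self.zeta) != len(self.locations):
            raise ValueError("zeta and locations lengths differ")


@dataclass
class ModelData:
    """Arrays the likelihood needs: successes, trials, design, locations."""

    y: np.ndarray
    n_trials: np.ndarray
    X: np.ndarray  # n × z, standardized
    locations: np.ndarray  # n × 2 km

    @classmethod
    def from_records(
        cls, records: Sequence[ClusterRecord], cov: CovariateMatrix | None = None
    ) -> "ModelData":
        recs = list(records)
        if cov is not None and cov.row_index is not None:
            recs = [recs[i] for i in cov.row_index]
        y = np.array([r.n_vaccinated for r in recs], dtype=float)
        t = np.array([r.n_children for r in recs], dtype=float)
        locs = np.array([(r.x, r.y) for r in recs], dtype=float)
        X = cov.X if cov is not None else np.empty((len(recs), 0))
        return cls(y=y, n_trials=t, X=np.asarray(X, dtype=float), locations=locs)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def z(self) -> int:
        return self.X.shape[1]

    def data_hash(self) -> str:
        """Fingerprint of the observations (not the covariate set), so that
        candidate models on identical rows share a hash."""
        h = hashlib.sha256()
        for arr in (self.y, self.n_trials, self.locations):
            h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# likelihood and posterior density


def binomial_loglik(eta, records) -> tuple[float, np.ndarray]:
    """Binomial log-likelihood at linear predictors η (logit scale).

    ``records`` is either a sequence of ClusterRecord or a pair of arrays
    (successes, trials).  Returns (total, pointwise) with the binomial
    coefficient included; computed via n·logaddexp(0, η) for stability at
    extreme η.
    """
    eta = np.asarray(eta, dtype=float)
    if isinstance(records, tuple):
        y, t = (np.asarray(a, dtype=float) for a in records)
    else:
        y = np.array([r.n_vaccinated for r in records], dtype=float)
        t = np.array([r.n_children for r in records], dtype=float)
    if eta.shape[-1] != len(y):
        raise ValueError(f"eta length {eta.shape[-1]} != number of clusters {len(y)}")
    log_binom = gammaln(t + 1) - gammaln(y + 1) - gammaln(t - y + 1)
    pointwise = log_binom + y * eta - t * np.logaddexp(0.0, eta)
    return float(pointwise.sum(axis=-1)) if eta.ndim == 1 else pointwise.sum(axis=-1), pointwise


def _split_theta(theta: np.ndarray, z: int, spatial: bool):
    theta = np.asarray(theta, dtype=float)
    alpha = theta[0]
    beta = theta[1 : 1 + z]
    if spatial:
        log_sigma, log_rho = theta[1 + z], theta[2 + z]
        zeta = theta[3 + z :]
        return alpha, beta, log_sigma, log_rho, zeta
    return alpha, beta, None, None, np.zeros(0)


def log_posterior(theta: np.ndarray, data: ModelData, spec: ModelSpec) -> float:
    """Unnormalized log posterior density at the full parameter vector.

    Layout of ``theta``: [α, β_1..β_z, log σ, log ρ, ζ_1..ζ_n] (the two
    hyperparameters and ζ are absent when the spec has no spatial field).
    """
    alpha, beta, ls, lr, zeta = _split_theta(theta, data.z, spec.include_spatial_field)
    expected = 1 + data.z + (2 + data.n if spec.include_spatial_field else 0)
    if len(theta) != expected:
        raise ValueError(f"theta has length {len(theta)}, expected {expected}")
    eta = alpha + (data.X @ beta if data.z else 0.0) + (zeta if len(zeta) else 0.0)
    total, _ = binomial_loglik(eta, (data.y, data.n_trials))
    lp = total
    # beta prior: N(0, precision b)
    b = spec.prior_beta_precision
    lp += 0.5 * data.z * np.log(b / (2 * np.pi)) - 0.5 * b * float(beta @ beta)
    # alpha: improper flat, no term
    if spec.include_spatial_field:
        params = MaternParams(float(np.exp(ls)), float(np.exp(lr)), spec.nu)
        cov = covariance_matrix(data.locations, params)
        L, _ = chol_with_jitter(cov)
        w = solve_triangular(L, zeta, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        lp += -0.5 * (w @ w) - 0.5 * logdet - 0.5 * data.n * np.log(2 * np.pi)
        hp = spec.hyperprior or default_hyperprior(data.locations)
        lp += hp.logpdf(float(ls), float(lr))
    return float(lp)


# ---------------------------------------------------------------------------
# fit results and summaries


@dataclass
class FitResult:
    """Posterior draws plus everything needed to predict and compare."""

    param_names: list[str]
    draws: np.ndarray  # n_draws × n_params  (α, β…, [log σ, log ρ])
    zeta_draws: np.ndarray  # n_draws × n  (empty if no spatial field)
    pointwise_loglik: np.ndarray  # n_draws × n
    spec: ModelSpec
    data_hash: str
    locations: np.ndarray
    cov_columns: list[str]
    cov_means: np.ndarray
    cov_sds: np.ndarray
    hyperprior: HyperPrior | None
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None
    engine: str = ""

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def model_label(self) -> str:
        return self.spec.label or ("+".join(self.spec.covariate_names) or "intercept-only")

    def param_draws(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def save(self, prefix) -> None:
        """Write <prefix>.json (metadata + summary) and <prefix>.npz (draws)."""
        import json

        summ = summarize(self) if self.n_draws >= 100 else None
        meta = {
            "param_names": self.param_names,
            "data_hash": self.data_hash,
            "engine": self.engine,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "model_label": self.model_label,
            "spec": {
                "covariate_names": self.spec.covariate_names,
                "include_spatial_field": self.spec.include_spatial_field,
                "nu": self.spec.nu,
                "prior_beta_precision": self.spec.prior_beta_precision,
                "label": self.spec.label,
            },
            "hyperprior": None
            if self.hyperprior is None
            else {
                "log_sigma_mean": self.hyperprior.log_sigma_mean,
                "log_sigma_sd": self.hyperprior.log_sigma_sd,
                "log_rho_mean": self.hyperprior.log_rho_mean,
                "log_rho_sd": self.hyperprior.log_rho_sd,
            },
            "cov_columns": self.cov_columns,
            "diagnostics": {k: v for k, v in self.diagnostics.items() if np.isscalar(v)},
            "summary": None if summ is None else summ.table.to_dict(orient="records"),
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=float)
        np.savez_compressed(
            f"{prefix}.npz",
            draws=self.draws,
            zeta_draws=self.zeta_draws,
            pointwise_loglik=self.pointwise_loglik,
            locations=self.locations,
            cov_means=self.cov_means,
            cov_sds=self.cov_sds,
        )

    @classmethod
    def load(cls, prefix) -> "FitResult":
        import json

        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        arrs = np.load(f"{prefix}.npz")
        hp = meta["hyperprior"]
        return cls(
            param_names=meta["param_names"],
            draws=arrs["draws"],
            zeta_draws=arrs["zeta_draws"],
            pointwise_loglik=arrs["pointwise_loglik"],
            spec=ModelSpec(**meta["spec"], hyperprior=None),
            data_hash=meta["data_hash"],
            locations=arrs["locations"],
            cov_columns=meta["cov_columns"],
            cov_means=arrs["cov_means"],
            cov_sds=arrs["cov_sds"],
            hyperprior=None if hp is None else HyperPrior(**hp),
            seed=meta["seed"],
            engine=meta["engine"],
        )


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, central 95% CrI, odds ratios, and the
    CrI-excludes-zero significance flag."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def summarize(fit_result: FitResult) -> PosteriorSummary:
    """Posterior mean and empirical 2.5/97.5% quantiles per parameter.

    A parameter is flagged significant when its 95% CrI excludes zero.
    Odds ratios are exp of the coefficient draws summarized the same way.
    """
    if fit_result.n_draws < 100:
        raise ValueError("need at least 100 draws to summarize")
    rows = []
    for i, name in enumerate(fit_result.param_names):
        d = fit_result.draws[:, i]
        lo, hi = np.quantile(d, [0.025, 0.975])
        ed = np.exp(d)
        olo, ohi = np.quantile(ed, [0.025, 0.975])
        rows.append(
            {
                "name": name,
                "mean": float(d.mean()),
                "cri_low": float(lo),
                "cri_high": float(hi),
                "odds_ratio": float(ed.mean()),
                "or_cri_low": float(olo),
                "or_cri_high": float(ohi),
                "significant": bool(not (lo <= 0.0 <= hi)),
            }
        )
    return PosteriorSummary(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# shared pieces for the engines


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    n, z = X.shape
    if z == 0:
        return
    full = np.column_stack([np.ones(n), X])
    r = np.linalg.qr(full, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * diag.max()
    if bad.any():
        cols = [(["intercept"] + list(names))[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {cols}")


def _latent_design(data: ModelData, spatial: bool) -> np.ndarray:
    """A with η = A u, u = (α, β[, ζ])."""
    blocks = [np.ones((data.n, 1))]
    if data.z:
        blocks.append(data.X)
    if spatial:
        blocks.append(np.eye(data.n))
    return np.concatenate(blocks, axis=1)


def _field_precision(data: ModelData, params: MaternParams):
    """(Q_ζ, log|Σ|) from the dense Matérn covariance at the data locations."""
    cov = covariance_matrix(data.locations, params)
    L, _ = chol_with_jitter(cov)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    inv_l = solve_triangular(L, np.eye(data.n), lower=True)
    return inv_l.T @ inv_l, logdet


class _NewtonError(RuntimeError):
    pass


def _newton_mode(y, t, A, Q, c_prior, u0=None, max_iter=100, tol=1e-9):
    """Mode and Cholesky of the negative Hessian of the latent conditional.

    Maximizes g(u) = binomial loglik(Au) − ½ uᵀQu + c_prior by damped
    Newton; returns (u*, L_H lower-Cholesky of H = AᵀWA + Q, g(u*)).
    """
    m = A.shape[1]
    u = np.zeros(m) if u0 is None else u0.copy()

    def g(uv):
        eta = A @ uv
        total, _ = binomial_loglik(eta, (y, t))
        return total - 0.5 * float(uv @ Q @ uv) + c_prior

    g_u = g(u)
    trace = []
    for it in range(max_iter):
        eta = A @ u
        p = expit(eta)
        w = t * p * (1 - p)
        grad = A.T @ (y - t * p) - Q @ u
        H = (A.T * w) @ A + Q
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(m)
            cf = cho_factor(H, lower=True)
        step = cho_solve(cf, grad)
        # damped step: halve until improvement
        lam, ok = 1.0, False
        for _ in range(30):
            u_new = u + lam * step
            g_new = g(u_new)
            if g_new >= g_u - 1e-12:
                ok = True
                break
            lam *= 0.5
        trace.append((it, float(np.abs(grad).max()), lam))
        if not ok:
            break
        moved = np.abs(lam * step).max()
        u, g_u = u_new, g_new
        if np.abs(grad).max() < tol * (1 + abs(g_u)) or moved < 1e-12:
            L = np.linalg.cholesky(H)
            return u, L, g_u, it + 1
    raise _NewtonError(f"Newton did not converge; trace tail: {trace[-5:]}")


def _prior_blocks(data: ModelData, spec: ModelSpec, params: MaternParams | None):
    """Latent prior precision Q and the prior's log normalizing constant."""
    spatial = params is not None
    m = 1 + data.z + (data.n if spatial else 0)
    Q = np.zeros((m, m))
    b = spec.prior_beta_precision
    for j in range(data.z):
        Q[1 + j, 1 + j] = b
    c = 0.5 * data.z * np.log(b / (2 * np.pi))
    if spatial:
        Qz, logdet = _field_precision(data, params)
        Q[1 + data.z :, 1 + data.z :] = Qz
        c += -0.5 * logdet - 0.5 * data.n * np.log(2 * np.pi)
    return Q, c


# ---------------------------------------------------------------------------
# engine: nested Laplace over a hyperparameter grid


def _laplace_fit(data: ModelData, spec: ModelSpec, seed: int, n_draws: int,
                 grid_half: int = 3, grid_step_sd: float = 0.7) -> FitResult:
    rng = np.random.default_rng(seed)
    A = _latent_design(data, spec.include_spatial_field)
    m = A.shape[1]
    hp = spec.hyperprior or default_hyperprior(data.locations)
    diag_count = {"newton_iters": 0, "psi_evals": 0}
    warm: dict = {"u": None}

    if not spec.include_spatial_field:
        Q, c = _prior_blocks(data, spec, None)
        u_star, L, _, iters = _newton_mode(data.y, data.n_trials, A, Q, c)
        Z = rng.standard_normal((n_draws, m))
        U = u_star + solve_triangular(L.T, Z.T, lower=False).T
        draws = U[:, : 1 + data.z]
        names = ["alpha"] + [f"beta_{c_}" for c_ in spec.covariate_names]
        eta = U @ A.T
        _, pw = binomial_loglik(eta, (data.y, data.n_trials))
        return FitResult(
            param_names=names, draws=draws, zeta_draws=np.empty((n_draws, 0)),
            pointwise_loglik=pw, spec=spec, data_hash=data.data_hash(),
            locations=data.locations, cov_columns=list(spec.covariate_names),
            cov_means=np.zeros(data.z), cov_sds=np.ones(data.z),
            hyperprior=None, diagnostics={"newton_iters": iters}, seed=seed,
            engine="laplace",
        )

    def inner(psi):
        """Laplace approximation of log p(y | ψ) + log hyperprior."""
        params = MaternParams(float(np.exp(psi[0])), float(np.exp(psi[1])), spec.nu)
        Q, c = _prior_blocks(data, spec, params)
        u_star, L, g_star, iters = _newton_mode(
            data.y, data.n_trials, A, Q, c, u0=warm["u"]
        )
        warm["u"] = u_star
        diag_count["newton_iters"] += iters
        diag_count["psi_evals"] += 1
        logdet_H = 2.0 * np.log(np.diag(L)).sum()
        log_marg = g_star + 0.5 * m * np.log(2 * np.pi) - 0.5 * logdet_H
        return log_marg + hp.logpdf(psi[0], psi[1]), u_star, L

    # hyperparameter mode
    x0 = np.array([hp.log_sigma_mean, hp.log_rho_mean])
    res = minimize(lambda p: -inner(p)[0], x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    psi_hat = res.x

    # local curvature -> grid geometry
    h = 0.1
    f0 = -res.fun
    fpp = np.zeros((2, 2))
    e = np.eye(2)
    fp = {}
    for i in range(2):
        for s in (-1, 1):
            fp[(i, s)] = inner(psi_hat + s * h * e[i])[0]
        fpp[i, i] = (fp[(i, 1)] - 2 * f0 + fp[(i, -1)]) / h**2
    fpm = inner(psi_hat + h * (e[0] + e[1]))[0]
    fmm = inner(psi_hat - h * (e[0] + e[1]))[0]
    fpp[0, 1] = fpp[1, 0] = (
        fpm - fp[(0, 1)] - fp[(1, 1)] + 2 * f0 - fp[(0, -1)] - fp[(1, -1)] + fmm
    ) / (2 * h**2)
    H_psi = -fpp
    try:
        evals, evecs = np.linalg.eigh(H_psi)
        if np.any(evals <= 0):
            raise np.linalg.LinAlgError
        sds = 1.0 / np.sqrt(evals)
    except np.linalg.LinAlgError:  # flat/indefinite curvature: fixed fallback
        evecs, sds = np.eye(2), np.array([0.5, 0.5])

    offsets = np.arange(-grid_half, grid_half + 1) * grid_step_sd
    nodes, logw, modes, chols, Qs, cs = [], [], [], [], [], []
    for a in offsets:
        for b_ in offsets:
            psi = psi_hat + evecs @ (np.array([a, b_]) * sds)
            params = MaternParams(float(np.exp(psi[0])), float(np.exp(psi[1])), spec.nu)
            Q, c = _prior_blocks(data, spec, params)
            lw, u_star, L = inner(psi)
            nodes.append(psi)
            logw.append(lw)
            modes.append(u_star)
            chols.append(L)
            Qs.append(Q)
            cs.append(c + hp.logpdf(psi[0], psi[1]))
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    keep = w > 1e-6
    kept = np.flatnonzero(keep)
    nodes = [nodes[i] for i in kept]
    modes = [modes[i] for i in kept]
    chols = [chols[i] for i in kept]
    Qs = [Qs[i] for i in kept]
    cs = [cs[i] for i in kept]
    w = w[keep] / w[keep].sum()

    # Importance correction of the Gaussian node approximations: oversample
    # Gaussian candidates per node, weight by the exact conditional density
    # ratio, correct the node marginal likelihoods by the mean weight, then
    # resample.  This removes most of the Laplace bias of the latent block.
    oversample = 3
    cand, cand_lw, cand_lml = [], [], []
    log_binom_const = float(np.sum(
        gammaln(data.n_trials + 1) - gammaln(data.y + 1)
        - gammaln(data.n_trials - data.y + 1)
    ))
    for k in range(len(nodes)):
        n_cand = max(int(oversample * n_draws * w[k]), 64)
        Z = rng.standard_normal((n_cand, m))
        Uk = modes[k] + solve_triangular(chols[k].T, Z.T, lower=False).T
        eta = Uk @ A.T
        ll = (log_binom_const + data.y @ eta.T
              - (data.n_trials[None, :] * np.logaddexp(0.0, eta)).sum(axis=1))
        quad = np.einsum("ij,ij->i", Uk @ Qs[k], Uk)
        g_vals = ll - 0.5 * quad + cs[k]
        half_logdet_H = float(np.log(np.diag(chols[k])).sum())
        logq = -0.5 * (Z**2).sum(axis=1) - 0.5 * m * np.log(2 * np.pi) + half_logdet_H
        lw_k = g_vals - logq
        cand.append(Uk)
        cand_lw.append(lw_k)
        # corrected log marginal (incl. hyperprior): log mean importance weight
        cand_lml.append(float(np.logaddexp.reduce(lw_k) - np.log(n_cand)))
    lml = np.array(cand_lml)
    w = np.exp(lml - lml.max())
    w /= w.sum()

    counts = rng.multinomial(n_draws, w)
    U = np.empty((n_draws, m))
    psi_draws = np.empty((n_draws, 2))
    is_ess = 0.0
    pos = 0
    for k, cnt in enumerate(counts):
        if cnt == 0:
            continue
        lw_k = cand_lw[k] - cand_lw[k].max()
        wk = np.exp(lw_k)
        wk /= wk.sum()
        is_ess += w[k] * (1.0 / np.sum(wk**2)) / len(wk)
        pick = rng.choice(len(wk), size=cnt, replace=True, p=wk)
        U[pos : pos + cnt] = cand[k][pick]
        psi_draws[pos : pos + cnt] = nodes[k]
        pos += cnt
    perm = rng.permutation(n_draws)
    U, psi_draws = U[perm], psi_draws[perm]

    names = ["alpha"] + [f"beta_{c_}" for c_ in spec.covariate_names] + ["log_sigma", "log_rho"]
    draws = np.column_stack([U[:, : 1 + data.z], psi_draws])
    zeta_draws = U[:, 1 + data.z :]
    eta = U @ A.T
    _, pw = binomial_loglik(eta, (data.y, data.n_trials))
    diagnostics = {
        **diag_count,
        "psi_mode_log_sigma": float(psi_hat[0]),
        "psi_mode_log_rho": float(psi_hat[1]),
        "n_grid_nodes_kept": int(keep.sum()),
        "importance_ess_fraction": float(is_ess),
    }
    return FitResult(
        param_names=names, draws=draws, zeta_draws=zeta_draws, pointwise_loglik=pw,
        spec=spec, data_hash=data.data_hash(), locations=data.locations,
        cov_columns=list(spec.covariate_names), cov_means=np.zeros(data.z),
        cov_sds=np.ones(data.z), hyperprior=hp, diagnostics=diagnostics,
        seed=seed, engine="laplace",
    )


# ---------------------------------------------------------------------------
# engine: MCMC (elliptical slice sampling + adaptive Metropolis blocks)


def _mcmc_fit(data: ModelData, spec: ModelSpec, seed: int, n_draws: int) -> FitResult:
    rng = np.random.default_rng(seed)
    spatial = spec.include_spatial_field
    hp = spec.hyperprior or default_hyperprior(data.locations)
    n, z = data.n, data.z
    y, t, X = data.y, data.n_trials, data.X

    def loglik(alpha, beta, zeta):
        eta = alpha + (X @ beta if z else 0.0) + zeta
        total, _ = binomial_loglik(eta, (y, t))
        return total

    # state
    p0 = (y.sum() + 0.5) / (t.sum() + 1.0)
    alpha = float(np.log(p0 / (1 - p0)))
    beta = np.zeros(z)
    zeta = np.zeros(n)
    log_sigma, log_rho = hp.log_sigma_mean, hp.log_rho_mean

    def field_chol(ls, lr):
        params = MaternParams(float(np.exp(ls)), float(np.exp(lr)), spec.nu)
        L, _ = chol_with_jitter(covariance_matrix(data.locations, params))
        return L

    if spatial:
        L_field = field_chol(log_sigma, log_rho)

    def field_logpdf(zv, L):
        wv = solve_triangular(L, zv, lower=True)
        return -0.5 * (wv @ wv) - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2 * np.pi)

    total_iter = 2 * n_draws  # first half = burn-in
    burn = n_draws
    d_fix = 1 + z
    scale_fix, scale_hyp, scale_ridge = 0.1, 0.3, 0.3
    cov_fix = np.eye(d_fix)
    acc_fix = acc_hyp = acc_ridge = 0
    win_fix = win_hyp = win_ridge = 0
    fix_history = np.empty((burn, d_fix))
    ll_cur = loglik(alpha, beta, zeta)
    b_prec = spec.prior_beta_precision

    draws = np.empty((n_draws, d_fix + (2 if spatial else 0)))
    zeta_store = np.empty((n_draws, n if spatial else 0))

    L_prop = np.linalg.cholesky(cov_fix)
    for it in range(total_iter):
        # --- block 1: (alpha, beta) adaptive RWM
        cur = np.concatenate([[alpha], beta])
        prop = cur + scale_fix * (L_prop @ rng.standard_normal(d_fix))
        ll_prop = loglik(prop[0], prop[1:], zeta)
        lp_cur = -0.5 * b_prec * float(beta @ beta)
        lp_prop = -0.5 * b_prec * float(prop[1:] @ prop[1:])
        if np.log(rng.uniform()) < (ll_prop + lp_prop) - (ll_cur + lp_cur):
            alpha, beta = float(prop[0]), prop[1:].copy()
            ll_cur = ll_prop
            acc_fix += 1
            win_fix += 1

        if spatial:
            # --- block 2: zeta by elliptical slice sampling (always accepts)
            nu_vec = L_field @ rng.standard_normal(n)
            log_u = ll_cur + np.log(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            phi_min, phi_max = phi - 2 * np.pi, phi
            while True:
                zeta_prop = zeta * np.cos(phi) + nu_vec * np.sin(phi)
                ll_prop = loglik(alpha, beta, zeta_prop)
                if ll_prop > log_u:
                    zeta, ll_cur = zeta_prop, ll_prop
                    break
                if phi < 0:
                    phi_min = phi
                else:
                    phi_max = phi
                phi = rng.uniform(phi_min, phi_max)

            # --- block 2b: likelihood-preserving ridge move. β and ζ are
            # confounded through η = α + Xβ + ζ; propose (α,β) += δ together
            # with ζ −= [1 X]δ so η is unchanged and acceptance depends on
            # the priors alone.  This walks along the ridge ESS cannot.
            delta = scale_ridge * rng.standard_normal(d_fix)
            shift = delta[0] + (X @ delta[1:] if z else 0.0)
            zeta_prop = zeta - shift
            beta_prop = beta + delta[1:]
            num = field_logpdf(zeta_prop, L_field) - 0.5 * b_prec * float(beta_prop @ beta_prop)
            den = field_logpdf(zeta, L_field) - 0.5 * b_prec * float(beta @ beta)
            if np.log(rng.uniform()) < num - den:
                alpha = float(alpha + delta[0])
                beta = beta_prop
                zeta = zeta_prop
                acc_ridge += 1
                win_ridge += 1

            # --- block 3: (log sigma, log rho) adaptive RWM given zeta
            prop_psi = np.array([log_sigma, log_rho]) + scale_hyp * rng.standard_normal(2)
            L_new = field_chol(prop_psi[0], prop_psi[1])
            num = field_logpdf(zeta, L_new) + hp.logpdf(prop_psi[0], prop_psi[1])
            den = field_logpdf(zeta, L_field) + hp.logpdf(log_sigma, log_rho)
            if np.log(rng.uniform()) < num - den:
                log_sigma, log_rho = float(prop_psi[0]), float(prop_psi[1])
                L_field = L_new
                acc_hyp += 1
                win_hyp += 1

        # --- adaptation during burn-in
        if it < burn:
            fix_history[it] = np.concatenate([[alpha], beta])
            if (it + 1) % 50 == 0:
                r_fix = win_fix / 50.0
                scale_fix *= np.exp(1.0 * (r_fix - 0.3))
                win_fix = 0
                if spatial:
                    r_hyp = win_hyp / 50.0
                    scale_hyp *= np.exp(1.0 * (r_hyp - 0.3))
                    win_hyp = 0
                    r_ridge = win_ridge / 50.0
                    scale_ridge *= np.exp(1.0 * (r_ridge - 0.3))
                    win_ridge = 0
                if it + 1 >= burn // 2:
                    emp = np.cov(fix_history[burn // 4 : it + 1].T).reshape(d_fix, d_fix)
                    L_prop = np.linalg.cholesky(emp + 1e-8 * np.eye(d_fix))
        else:
            k = it - burn
            draws[k, :d_fix] = np.concatenate([[alpha], beta])
            if spatial:
                draws[k, d_fix:] = (log_sigma, log_rho)
                zeta_store[k] = zeta

    names = ["alpha"] + [f"beta_{c_}" for c_ in spec.covariate_names]
    if spatial:
        names += ["log_sigma", "log_rho"]
    eta_draws = draws[:, [0]] + (draws[:, 1 : 1 + z] @ X.T if z else 0.0)
    if spatial:
        eta_draws = eta_draws + zeta_store
    else:
        eta_draws = np.broadcast_to(eta_draws, (n_draws, n)).copy()
    _, pw = binomial_loglik(eta_draws, (y, t))
    acc_rate_fix = acc_fix / total_iter
    diagnostics = {
        "accept_rate_fixed": float(acc_rate_fix),
        "accept_rate_hyper": float(acc_hyp / total_iter) if spatial else np.nan,
        "accept_rate_ridge": float(acc_ridge / total_iter) if spatial else np.nan,
        "burn_in": burn,
    }
    if not 0.1 <= acc_rate_fix <= 0.6:
        warnings.warn(f"fixed-effect block acceptance rate {acc_rate_fix:.2f} outside [0.1, 0.6]")
    return FitResult(
        param_names=names, draws=draws,
        zeta_draws=zeta_store if spatial else np.empty((n_draws, 0)),
        pointwise_loglik=pw, spec=spec, data_hash=data.data_hash(),
        locations=data.locations, cov_columns=list(spec.covariate_names),
        cov_means=np.zeros(z), cov_sds=np.ones(z),
        hyperprior=hp if spatial else None, diagnostics=diagnostics,
        seed=seed, engine="mcmc",
    )


# ---------------------------------------------------------------------------
# public fit entry point


def fit(
    records: Sequence[ClusterRecord],
    cov: CovariateMatrix | None,
    spec: ModelSpec,
    engine: str = "laplace",
    seed: int = 0,
    n_draws: int = DEFAULT_N_DRAWS,
) -> FitResult:
    """Fit the spatial binomial model and return posterior draws.

    ``cov`` carries the standardized design matrix (None for an
    intercept-only model).  ``engine`` selects ``laplace`` (nested-Laplace
    grid, the default workhorse) or ``mcmc``.  The stored standardization
    constants travel with the result so that prediction applies the
    fit-time scaling.
    """
    data = ModelData.from_records(records, cov)
    if data.n < data.z + 2:
        raise ValueError(f"need at least z+2={data.z + 2} clusters, got {data.n}")
    _check_design(data.X, spec.covariate_names)
    if cov is not None and list(cov.columns) != list(spec.covariate_names):
        raise ValueError(
            f"covariate names {cov.columns} do not match spec {spec.covariate_names}"
        )
    if spec.include_spatial_field and spec.hyperprior is None:
        spec = ModelSpec(
            covariate_names=spec.covariate_names,
            include_spatial_field=True, nu=spec.nu,
            prior_beta_precision=spec.prior_beta_precision,
            hyperprior=default_hyperprior(data.locations), label=spec.label,
        )
    if engine == "laplace":
        out = _laplace_fit(data, spec, seed, n_draws)
    elif engine == "mcmc":
        out = _mcmc_fit(data, spec, seed, n_draws)
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'laplace' or 'mcmc'")
    if cov is not None:
        out.cov_means = cov.means
        out.cov_sds = cov.sds
    if not np.all(np.isfinite(out.draws)):
        raise RuntimeError("non-finite values in posterior draws")
    return out
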