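"""Model comparison by the widely applicable information criterion (WAIC).

WAIC = −2 (lppd − p_waic), computed from the matrix of pointwise
log-likelihoods over posterior draws: lppd_i is the log of the posterior
mean of the pointwise likelihood (via log-sum-exp) and the penalty p_waic
is the variance-based variant (sample variance of the pointwise
log-likelihood over draws).  Lower WAIC is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import FitResult

__all__ = ["WaicResult", "waic", "compare_models"]


@dataclass
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p_waic: np.ndarray
    model_label: str = ""

    def __post_init__(self):
        assert abs(self.waic - (-2.0 * (self.lppd - self.p_waic))) < 1e-10


def waic(pointwise_loglik: np.ndarray, model_label: str = "") -> WaicResult:
    """WAIC from an (n_draws × n_points) pointwise log-likelihood matrix.

    Points whose individual penalty exceeds 0.4 are flagged with a warning
    (the usual heuristic that the variance estimate is unreliable there).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    n_high = int((p_i > 0.4).sum())
    if n_high:
        warnings.warn(f"waic: {n_high} point(s) with p_waic_i > 0.4; estimate may be unreliable")
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(
        lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic),
        pointwise_lppd=lppd_i, pointwise_p_waic=p_i, model_label=model_label,
    )


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank candidate fits of the *same* data by WAIC (ascending = best first).

    Refuses to compare fits whose data fingerprints differ — WAIC values
    are only comparable on identical observations.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError(f"fits are not on identical data (hashes {sorted(hashes)})")
    rows = []
    for f in fits:
        r = waic(f.pointwise_loglik, model_label=f.model_label)
        rows.append({"model_label": r.model_label, "lppd": r.lppd,
                     "p_waic": r.p_waic, "waic": r.waic})
    table = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
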