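"""Bayesian linear ensemble averaging (BLEA) for metric-vs-speed trends.

Each resampled dataset contributes a Bayesian linear regression of a
metric on speed (design ``x = (v, 1)``, prior ``w ~ N(0, alpha^{-1} I)``,
noise precision ``beta``), with ``alpha`` and ``beta`` set by evidence
(marginal-likelihood) maximization.  The per-dataset Gaussian posteriors
are combined by Bayesian model averaging into a mixture, collapsed to a
single Gaussian by moment matching: the ensemble covariance is the mean
of the covariances plus the between-dataset scatter of the means, so
pooling more resamples of the *same* data does not shrink uncertainty
toward zero.

Direction statistics: the probability of direction ``p_d`` of a slope
difference is the posterior mass of its most probable sign;
``p = 2 (1 - p_d)`` is the two-sided analogue of a p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "BLRPosterior",
    "EnsemblePosterior",
    "fit_blr",
    "ensemble",
    "predictive_interval",
    "slope_test",
    "speed_avg_test",
    "metric_speed_table",
    "blea_from_table",
]


@dataclass
class BLRPosterior:
    """Gaussian posterior over (slope, intercept) for one dataset."""

    m_w: np.ndarray  # posterior mean, (2,)
    S_w: np.ndarray  # posterior covariance, (2, 2)
    alpha: float
    beta: float
    r2: float
    converged: bool = True


@dataclass
class EnsemblePosterior:
    """Moment-matched Gaussian collapse of the posterior mixture."""

    m_w: np.ndarray
    S_w: np.ndarray
    noise_var: float  # predictive noise: mean of beta_s^{-1}
    B: int

    @property
    def slope_mean(self) -> float:
        return float(self.m_w[0])

    @property
    def slope_var(self) -> float:
        return float(self.S_w[0, 0])


def fit_blr(
    speeds: np.ndarray,
    values: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> BLRPosterior:
    """Bayesian linear regression with evidence-maximized hyperparameters.

    Fixed-point iteration: ``gamma = sum lam_i / (alpha + lam_i)`` with
    ``lam_i`` the eigenvalues of ``beta X^T X``; ``alpha = gamma / m^T m``;
    ``beta = (n - gamma) / SSE``.
    """
    v = np.asarray(speeds, dtype=float).ravel()
    t = np.asarray(values, dtype=float).ravel()
    if v.size != t.size or v.size < 3:
        raise ValueError("need at least 3 aligned (speed, value) rows")
    X = np.column_stack([v, np.ones_like(v)])
    n = len(t)
    XtX = X.T @ X
    Xtt = X.T @ t
    # initialize the fixed point from the least-squares solution; starting
    # far from it (e.g. alpha = 1 with a large metric offset) can trap the
    # iteration in a degenerate all-noise optimum
    m_ols, *_ = np.linalg.lstsq(X, t, rcond=None)
    sse_ols = float(np.sum((t - X @ m_ols) ** 2))
    scale = float(m_ols @ m_ols) + 1e-12
    alpha = 2.0 / scale
    beta = n / max(sse_ols, 1e-10 * scale)
    evals0 = np.linalg.eigvalsh(XtX)
    converged = False
    for _ in range(max_iter):
        S_inv = alpha * np.eye(2) + beta * XtX
        S = np.linalg.inv(S_inv)
        m = beta * S @ Xtt
        lam = beta * evals0
        gamma = float(np.sum(lam / (alpha + lam)))
        mtm = float(m @ m)
        alpha_new = gamma / mtm if mtm > 0 else alpha
        sse = float(np.sum((t - X @ m) ** 2))
        beta_new = (n - gamma) / sse if sse > 0 else beta
        rel = abs(alpha_new - alpha) / max(alpha, 1e-300) + abs(
            beta_new - beta
        ) / max(beta, 1e-300)
        alpha, beta = alpha_new, beta_new
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("evidence iteration did not converge; returning last iterate")
    S = np.linalg.inv(alpha * np.eye(2) + beta * XtX)
    m = beta * S @ Xtt
    sst = float(np.sum((t - t.mean()) ** 2))
    sse = float(np.sum((t - X @ m) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return BLRPosterior(m_w=m, S_w=S, alpha=alpha, beta=beta, r2=r2, converged=converged)


def ensemble(posteriors: list[BLRPosterior]) -> EnsemblePosterior:
    """Moment-matched Gaussian collapse of per-dataset posteriors."""
    if not posteriors:
        raise ValueError("empty posterior list")
    B = len(posteriors)
    means = np.stack([p.m_w for p in posteriors])
    m_w = means.mean(axis=0)
    covs = np.stack([p.S_w for p in posteriors]).mean(axis=0)
    d = means - m_w[None, :]
    scatter = d.T @ d / B
    noise = float(np.mean([1.0 / p.beta for p in posteriors]))
    return EnsemblePosterior(m_w=m_w, S_w=covs + scatter, noise_var=noise, B=B)


def predictive_interval(
    ens: EnsemblePosterior, v_q: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Gaussian predictive interval of the metric at a query speed."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.array([v_q, 1.0])
    mean = float(ens.m_w @ x)
    var = float(x @ ens.S_w @ x) + ens.noise_var / ens.B
    z = norm.ppf(0.5 + level / 2.0)
    sd = np.sqrt(max(var, 0.0))
    return mean, mean - z * sd, mean + z * sd


def _direction_stats(
    d_mean: float, d_var: float, sided: str
) -> tuple[float, float]:
    sd = np.sqrt(max(d_var, 0.0))
    if sd == 0:
        p_gt = 1.0 if d_mean > 0 else (0.5 if d_mean == 0 else 0.0)
    else:
        p_gt = float(1.0 - norm.cdf(-d_mean / sd))
    p_d = max(p_gt, 1.0 - p_gt)
    if sided == "two-sided":
        p = 2.0 * (1.0 - p_d)
    elif sided == "greater":
        p = 1.0 - p_gt
    elif sided == "less":
        p = p_gt
    else:
        raise ValueError("sided must be 'two-sided', 'greater' or 'less'")
    return p_d, float(np.clip(p, 0.0, 1.0))


def slope_test(
    ens_a: EnsemblePosterior, ens_b: EnsemblePosterior, sided: str = "two-sided"
) -> tuple[float, float]:
    """Probability of direction and p-value for slope(a) - slope(b).

    ``sided='greater'`` tests the alternative slope(a) > slope(b).
    """
    d_mean = ens_a.slope_mean - ens_b.slope_mean
    d_var = ens_a.slope_var + ens_b.slope_var
    return _direction_stats(d_mean, d_var, sided)


def slope_sign_test(ens: EnsemblePosterior, sided: str = "two-sided"):
    """Direction statistics of a single ensemble's slope against zero."""
    return _direction_stats(ens.slope_mean, ens.slope_var, sided)


def speed_avg_test(
    values_a: np.ndarray, values_b: np.ndarray, sided: str = "two-sided"
) -> tuple[float, float]:
    """Compare per-dataset speed-averaged metrics between two conditions.

    Each group's values are fitted by a Gaussian (maximum likelihood);
    the difference of the two Gaussian means is tested by direction.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    va, vb = a.var(ddof=0), b.var(ddof=0)
    if va == 0 or vb == 0:
        raise ValueError("zero-variance group; Gaussian fit degenerate")
    d_mean = a.mean() - b.mean()
    d_var = va / a.size + vb / b.size
    return _direction_stats(d_mean, d_var, sided)


# ---------------------------------------------------------------------------
# tabular plumbing
# ---------------------------------------------------------------------------


def metric_speed_table(rows) -> pd.DataFrame:
    """Normalize (dataset_id, speed, metric, value) rows to a DataFrame."""
    df = pd.DataFrame(rows, columns=["dataset_id", "speed", "metric", "value"])
    dup = df.duplicated(subset=["dataset_id", "speed", "metric"])
    if dup.any():
        raise ValueError("duplicate (dataset, speed, metric) rows")
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("non-finite metric values")
    return df


def blea_from_table(df: pd.DataFrame, metric: str) -> EnsemblePosterior:
    """Fit one BLR per dataset_id for a metric and collapse the ensemble."""
    sub = df[df["metric"] == metric]
    posts = [
        fit_blr(g["speed"].to_numpy(), g["value"].to_numpy())
        for _, g in sub.groupby("dataset_id")
    ]
    return ensemble(posts)
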