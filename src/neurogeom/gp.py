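"""Sparse Gaussian-process regression for smooth population mean surfaces.

All neurons share one kernel over the label space,

``k(x, x') = s_f * prod_d k_d(x_d, x_d') + c``

where ``k_d`` is a unit squared-exponential per non-circular label
dimension and a periodic (sine-of-half-angle) squared exponential per
circular dimension, ``c`` is an additive constant and ``s_f`` the signal
variance.  Observation noise is homoscedastic with variance ``s_n``.

For small datasets the exact GP marginal likelihood is used.  Larger
datasets use the collapsed variational evidence bound of an inducing-point
approximation (inducing locations drawn as a random subset of the training
labels and held fixed; hyperparameters optimized by L-BFGS-B on a
subsample of the data, then the predictive equations use every point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

_JITTER = 1e-8


@dataclass
class KernelParams:
    """Log-scale kernel hyperparameters."""

    log_signal: float  # log s_f
    log_lengthscales: np.ndarray  # one per label dim
    log_constant: float  # log c
    log_noise: float  # log s_n

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.log_signal], self.log_lengthscales, [self.log_constant, self.log_noise]]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray, n_dims: int) -> "KernelParams":
        return cls(
            log_signal=float(v[0]),
            log_lengthscales=np.asarray(v[1 : 1 + n_dims], dtype=float),
            log_constant=float(v[1 + n_dims]),
            log_noise=float(v[2 + n_dims]),
        )


def _kernel_cross(
    X1: np.ndarray,
    X2: np.ndarray,
    params: KernelParams,
    circular: np.ndarray,
    periods: np.ndarray,
) -> np.ndarray:
    """Evaluate the shared product kernel between two label batches."""
    s_f = np.exp(params.log_signal)
    c = np.exp(params.log_constant)
    ls = np.exp(params.log_lengthscales)
    q = np.zeros((X1.shape[0], X2.shape[0]))
    for d in range(X1.shape[1]):
        diff = X1[:, d][:, None] - X2[:, d][None, :]
        if circular[d]:
            diff = np.sin(np.pi * diff / periods[d])
        q += (diff / ls[d]) ** 2
    return s_f * np.exp(-0.5 * q) + c


@dataclass
class GPMeanModel:
    """Fitted multi-output GP for the (standardized) mean surface."""

    params: KernelParams
    circular: np.ndarray
    periods: np.ndarray
    out_mean: np.ndarray  # per-neuron standardization mean
    out_sd: np.ndarray  # per-neuron standardization sd (kept neurons)
    keep: np.ndarray  # boolean mask of neurons retained by the GP
    Z: np.ndarray  # inducing (or training) locations, (K, M)
    alpha: np.ndarray  # weights such that mean_tilde(X*) = K(X*, Z) @ alpha
    var_state: dict = field(default_factory=dict)  # terms for posterior sd
    label_range: np.ndarray | None = None
    evidence: float = float("nan")

    @property
    def n_outputs(self) -> int:
        return self.out_mean.size

    def predict(
        self, Xq: np.ndarray, return_sd: bool = False
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        """Posterior mean (un-standardized) at query labels, optionally
        with the shared posterior sd of the latent function (standardized
        units scaled per neuron)."""
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if Xq.shape[1] != self.Z.shape[1]:
            raise ValueError(
                f"query has {Xq.shape[1]} label dims, model expects {self.Z.shape[1]}"
            )
        Kqz = _kernel_cross(Xq, self.Z, self.params, self.circular, self.periods)
        mean_t = Kqz @ self.alpha  # (T, kept)
        out = np.empty((Xq.shape[0], self.n_outputs))
        out[:, :] = self.out_mean[None, :]
        out[:, self.keep] += mean_t * self.out_sd[None, self.keep]
        if not return_sd:
            return out
        # latent posterior variance, shared across outputs
        s_f = np.exp(self.params.log_signal)
        c = np.exp(self.params.log_constant)
        kqq = s_f + c
        if self.var_state.get("exact", False):
            Lf = self.var_state["chol"]
            v = solve_triangular(Lf, Kqz.T, lower=True)
            var = kqq - np.sum(v**2, axis=0)
        else:
            Lm = self.var_state["chol_kmm"]
            Lb = self.var_state["chol_B"]
            v1 = solve_triangular(Lm, Kqz.T, lower=True)
            v2 = solve_triangular(Lb, Kqz.T, lower=True)
            var = kqq - np.sum(v1**2, axis=0) + np.sum(v2**2, axis=0)
        sd_lat = np.sqrt(np.clip(var, 0.0, None))
        sd = np.zeros((Xq.shape[0], self.n_outputs))
        sd[:, self.keep] = sd_lat[:, None] * self.out_sd[None, self.keep]
        return out, sd


def _exact_evidence(v, X, Y, circular, periods):
    p = KernelParams.from_vector(v, X.shape[1])
    T, N = Y.shape
    K = _kernel_cross(X, X, p, circular, periods)
    K[np.diag_indices_from(K)] += np.exp(p.log_noise) + _JITTER
    try:
        Lf = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(Lf)))
    A = solve_triangular(Lf, Y, lower=True)
    quad = np.sum(A**2)
    return 0.5 * (N * logdet + quad + N * T * np.log(2 * np.pi))


def _titsias_bound(v, X, Y, Z, circular, periods):
    """Negative collapsed evidence bound of the inducing-point GP."""
    p = KernelParams.from_vector(v, X.shape[1])
    T, N = Y.shape
    s = np.exp(p.log_noise)
    Kmm = _kernel_cross(Z, Z, p, circular, periods)
    Kmm[np.diag_indices_from(Kmm)] += _JITTER * (1.0 + np.trace(Kmm) / len(Z))
    Ktm = _kernel_cross(X, Z, p, circular, periods)
    try:
        Lm = cholesky(Kmm, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    A = solve_triangular(Lm, Ktm.T, lower=True) / np.sqrt(s)  # (K, T)
    B = A @ A.T
    B[np.diag_indices_from(B)] += 1.0
    try:
        Lb = cholesky(B, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(Lb))) + T * np.log(s)
    AY = A @ Y  # (K, N)
    C = solve_triangular(Lb, AY, lower=True)
    quad = (np.sum(Y**2) - np.sum(C**2)) / s
    kdiag = np.exp(p.log_signal) + np.exp(p.log_constant)
    trace_term = (T * kdiag - s * np.trace(B - np.eye(len(Z)))) / s
    return 0.5 * (N * logdet + quad + N * T * np.log(2 * np.pi) + N * trace_term)


def fit_mean_gp(
    data,
    n_inducing: int = 200,
    max_iter: int = 60,
    seed: int = 0,
    hyper_subsample: int = 2000,
    exact_threshold: int = 600,
) -> GPMeanModel:
    """Fit the shared-kernel GP mean surface of a labeled dataset.

    Each neuron is standardized to zero mean and unit variance before
    fitting; zero-variance neurons are dropped from the GP (their constant
    value is still predicted).  Uses the exact GP when ``T`` is at most
    ``exact_threshold``, otherwise the inducing-point approximation with
    ``n_inducing`` inducing locations.
    """
    X = np.asarray(data.labels, dtype=float)
    Y_raw = np.asarray(data.states, dtype=float)
    T = X.shape[0]
    if T == 0:
        raise ValueError("empty dataset")
    circular = np.array([m.circular for m in data.label_meta])
    periods = np.array(
        [m.period if m.period is not None else np.nan for m in data.label_meta]
    )

    out_mean = Y_raw.mean(axis=0)
    out_sd = Y_raw.std(axis=0)
    keep = out_sd > 0
    if not np.all(keep):
        logger.warning(
            "dropping %d zero-variance neuron(s) from the GP mean fit",
            int(np.sum(~keep)),
        )
    if not np.any(keep):
        raise ValueError("all neurons have zero variance")
    Y = (Y_raw[:, keep] - out_mean[keep]) / out_sd[keep]

    label_range = X.max(axis=0) - X.min(axis=0)
    label_range[circular] = periods[circular]
    label_range = np.where(label_range > 0, label_range, 1.0)
    init = KernelParams(
        log_signal=0.0,
        log_lengthscales=np.log(0.2 * label_range),
        log_constant=np.log(0.1),
        log_noise=np.log(0.1),
    )
    rng = np.random.default_rng(seed)

    exact = T <= max(exact_threshold, n_inducing)
    if exact:
        Z = X
        sub = np.arange(T)
        if T > hyper_subsample:
            sub = rng.choice(T, hyper_subsample, replace=False)
        obj = lambda v: _exact_evidence(v, X[sub], Y[sub], circular, periods)
    else:
        Z = X[rng.choice(T, n_inducing, replace=False)].copy()
        sub = np.arange(T)
        if T > hyper_subsample:
            sub = rng.choice(T, hyper_subsample, replace=False)
        obj = lambda v: _titsias_bound(v, X[sub], Y[sub], Z, circular, periods)

    res = minimize(
        obj,
        init.to_vector(),
        method="L-BFGS-B",
        bounds=[(-8.0, 8.0)] * (3 + X.shape[1]),
        options={"maxiter": max_iter},
    )
    params = KernelParams.from_vector(res.x, X.shape[1])
    s = np.exp(params.log_noise)

    if exact:
        K = _kernel_cross(X, X, params, circular, periods)
        K[np.diag_indices_from(K)] += s + _JITTER
        Lf = cholesky(K, lower=True)
        alpha = cho_solve((Lf, True), Y)
        var_state = {"exact": True, "chol": Lf}
    else:
        Kmm = _kernel_cross(Z, Z, params, circular, periods)
        Kmm[np.diag_indices_from(Kmm)] += _JITTER * (1.0 + np.trace(Kmm) / len(Z))
        Ktm = _kernel_cross(X, Z, params, circular, periods)
        Lm = cholesky(Kmm, lower=True)
        B = Kmm + Ktm.T @ Ktm / s
        B[np.diag_indices_from(B)] += _JITTER
        Lb_full = cholesky(B, lower=True)
        # alpha maps K(X*, Z) to the predictive mean: B^{-1} Kmt Y / s
        alpha = cho_solve((Lb_full, True), Ktm.T @ Y) / s
        # posterior variance terms: Kmm^{-1} and B^{-1} quadratics
        var_state = {"exact": False, "chol_kmm": Lm, "chol_B": Lb_full}

    model = GPMeanModel(
        params=params,
        circular=circular,
        periods=periods,
        out_mean=out_mean,
        out_sd=out_sd,
        keep=keep,
        Z=Z,
        alpha=alpha,
        var_state=var_state,
        label_range=label_range,
        evidence=-float(res.fun),
    )
    return model


def predict_mean(model: GPMeanModel, Xq, return_sd: bool = False):
    """Functional wrapper around :meth:`GPMeanModel.predict`."""
    return model.predict(Xq, return_sd=return_sd)
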