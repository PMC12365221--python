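"""GKR: Gaussian-process mean plus kernel-regressed noise covariance.

The estimator models labeled neural states as

``r(x) = mu(x) + N(0, Sigma(x))``

with a smooth mean surface ``mu`` (fitted by the GP in :mod:`neurogeom.gp`)
and a smooth label-dependent covariance ``Sigma``.  The covariance at a
query label is a normalized kernel-weighted average of the per-point
residual outer products (gram matrices)

``Sigma(x) = sum_i k_L(x, x_i) (r_i - mu(x_i))(r_i - mu(x_i))^T + eta I``

where the weight kernel ``k_L(x, x') = kappa exp(-0.5 (x-x')^T L L^T
(x-x'))`` has a learnable upper-triangular precision factor ``L``.  ``L``
is trained by maximizing the Gaussian log-likelihood of held-out
(validation) points whose covariance is predicted from the train split;
evaluating the likelihood on the training points themselves would drive
``Sigma(x_i)`` to the rank-one gram matrix ``C(x_i)``, hence the split.

:class:`GKRSModel` replaces the Gaussian assumption with residual
resampling: neighbors' residuals are drawn with kernel weights whose
bandwidth follows Silverman's rule of thumb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset
from .gp import GPMeanModel, fit_mean_gp

logger = logging.getLogger(__name__)

__all__ = [
    "CovKernelModel",
    "GKRModel",
    "GKRSModel",
    "fit_cov_kernel",
    "predict_cov",
    "fit_gkr",
    "gkr_loglik",
    "fit_gkrs",
    "gkrs_moments",
    "gkrs_resample",
]


def _wrap_diffs(diffs: np.ndarray, circular: np.ndarray, periods: np.ndarray):
    """Minimal wrapped difference on circular label dims (optional)."""
    for d in np.nonzero(circular)[0]:
        p = periods[d]
        diffs[..., d] = (diffs[..., d] + p / 2) % p - p / 2
    return diffs


def _weights(
    Xq: np.ndarray,
    Xi: np.ndarray,
    L: np.ndarray,
    scale: np.ndarray | None = None,
    circular: np.ndarray | None = None,
    periods: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized weight matrix k_L(x_q, x_i); rows sum to one.

    ``L`` acts on range-normalized label differences (``scale`` divides
    each dimension) so its optimization is well conditioned when labels
    have very different units.  Falls back to uniform weights (with a
    warning) for queries whose kernel mass underflows entirely.
    """
    D = Xq[:, None, :] - Xi[None, :, :]
    if circular is not None and np.any(circular):
        D = _wrap_diffs(D, circular, periods)
    if scale is not None:
        D = D / scale[None, None, :]
    P = L @ L.T
    q = np.einsum("qim,mn,qin->qi", D, P, D)
    q -= q.min(axis=1, keepdims=True)  # stabilize the exponential
    W = np.exp(-0.5 * q)
    tot = W.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(tot[:, 0]) | (tot[:, 0] <= 0)
    if np.any(bad):
        logger.warning(
            "%d query point(s) with underflowing weights; using uniform weights",
            int(bad.sum()),
        )
        W[bad] = 1.0
        tot[bad] = Xi.shape[0]
    return W / tot


@dataclass
class CovKernelModel:
    """Kernel-regression covariance model over residual gram matrices."""

    Xi: np.ndarray  # residual-bank labels (T, M)
    resid: np.ndarray  # residuals eps_i = r_i - mu(x_i), (T, N)
    L: np.ndarray  # upper-triangular precision factor (M, M)
    eta: float = 1e-6
    scale: np.ndarray | None = None  # label-range normalization per dim
    circular: np.ndarray | None = None
    periods: np.ndarray | None = None
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def weights(self, Xq: np.ndarray) -> np.ndarray:
        return _weights(
            np.atleast_2d(Xq), self.Xi, self.L, self.scale, self.circular, self.periods
        )

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        """Covariance matrices at query labels; (Q, N, N), symmetric PSD."""
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        W = self.weights(Xq)
        G = self.resid[:, :, None] * self.resid[:, None, :]  # (T, N, N)
        S = np.einsum("qi,iab->qab", W, G)
        S += self.eta * np.eye(self.resid.shape[1])[None]
        S = 0.5 * (S + np.swapaxes(S, 1, 2))
        return S


def _nll_and_grad(
    ltri: np.ndarray,
    tri_idx: tuple[np.ndarray, np.ndarray],
    Dtv: np.ndarray,
    G_flat: np.ndarray,
    resid_val: np.ndarray,
    eta: float,
):
    """Validation negative log-likelihood of Eq-style loss and its gradient
    with respect to the upper-triangular entries of L.

    Dtv: (V, Ttr, M) label differences validation - train
    G_flat: (Ttr, N*N) flattened train gram matrices
    resid_val: (V, N) validation residuals
    """
    M = Dtv.shape[2]
    N = resid_val.shape[1]
    L = np.zeros((M, M))
    L[tri_idx] = ltri
    P = L @ L.T
    q = np.einsum("vim,mn,vin->vi", Dtv, P, Dtv)
    q -= q.min(axis=1, keepdims=True)
    U = np.exp(-0.5 * q)
    csum = U.sum(axis=1, keepdims=True)
    W = U / csum  # (V, Ttr)

    Sig = (W @ G_flat).reshape(-1, N, N)
    Sig += eta * np.eye(N)[None]
    # batched cholesky; any failure -> large loss
    try:
        chol = np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(ltri)
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    sol = np.linalg.solve(Sig, resid_val[:, :, None])[:, :, 0]
    quad = np.einsum("vn,vn->v", resid_val, sol)
    nll = float(np.sum(logdet + quad))

    # gradient: dnll/dSigma_v = Sigma^{-1} - sol sol^T
    inv = np.linalg.inv(Sig)
    Pmat = inv - sol[:, :, None] * sol[:, None, :]  # (V, N, N)
    # A_vi = eps_i^T P_v eps_i = G_flat @ P_flat
    A = G_flat @ Pmat.reshape(-1, N * N).T  # (Ttr, V)
    A = A.T  # (V, Ttr)
    rowdot = np.einsum("vi,vi->v", A, W)
    dldw = A  # dnll/dW_vi
    # W = U / csum  => dnll/dU_vi = (A_vi - sum_j A_vj W_vj) / csum_v
    dldu = (dldw - rowdot[:, None]) / csum
    # U = exp(-q/2) => dnll/dq_vi = -0.5 * U * dldu
    dldq = -0.5 * U * dldu
    # q = d^T L L^T d => dq/dL = 2 (d d^T) L
    Gm = np.einsum("vi,vim,vin->mn", dldq, Dtv, Dtv)
    gradL = 2.0 * Gm @ L
    return nll, gradL[tri_idx]


def fit_cov_kernel(
    data: LabeledDataset,
    mean_model: GPMeanModel,
    batch_size: int = 3000,
    train_frac: float = 0.66,
    epochs: int = 30,
    lr: float = 5e-2,
    steps_per_batch: int = 20,
    seed: int = 0,
    eta: float = 1e-6,
    wrap_circular: bool = False,
) -> CovKernelModel:
    """Fit the weight-kernel precision factor ``L`` by validated likelihood.

    Residuals are computed once against the fitted mean.  Data are split
    into batches of ``batch_size``; inside each batch a fresh train /
    validation split (``train_frac`` : rest) is drawn each epoch, the
    covariance at the validation points is the weighted train-gram average,
    and ``steps_per_batch`` Adam steps on the upper-triangular entries of
    ``L`` descend the validation Gaussian negative log-likelihood.  After
    training, every data point joins the residual bank used for
    prediction.
    """
    X = np.asarray(data.labels, dtype=float)
    mu = mean_model.predict(X)
    resid = np.asarray(data.states, dtype=float) - mu
    T, M = X.shape[0], X.shape[1]
    N = resid.shape[1]

    circular = np.array([m.circular for m in data.label_meta]) if wrap_circular else None
    periods = (
        np.array([m.period if m.period is not None else np.nan for m in data.label_meta])
        if wrap_circular
        else None
    )

    # distances are range-normalized; L starts at the identity there,
    # i.e. an initial kernel width of one label range per dimension
    label_range = X.max(axis=0) - X.min(axis=0)
    label_range = np.where(label_range > 0, label_range, 1.0)
    tri_idx = np.triu_indices(M)
    L0 = np.eye(M)
    ltri = L0[tri_idx].astype(float)

    rng = np.random.default_rng(seed)
    n_batches = max(1, int(np.ceil(T / batch_size)))
    bounds_splits = np.array_split(rng.permutation(T), n_batches)
    # merge a tiny trailing batch into its predecessor
    if len(bounds_splits) > 1 and len(bounds_splits[-1]) < 10:
        bounds_splits[-2] = np.concatenate(bounds_splits[-2:])
        bounds_splits = bounds_splits[:-1]

    mstate = np.zeros_like(ltri)
    vstate = np.zeros_like(ltri)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    losses = []
    for _ in range(epochs):
        epoch_loss = 0.0
        for batch in bounds_splits:
            perm = rng.permutation(batch)
            n_tr = max(2, int(round(train_frac * len(perm))))
            tr, va = perm[:n_tr], perm[n_tr:]
            if len(va) < 2:
                continue
            Dtv = X[va][:, None, :] - X[tr][None, :, :]
            if circular is not None and np.any(circular):
                Dtv = _wrap_diffs(Dtv, circular, periods)
            Dtv = Dtv / label_range[None, None, :]
            G_flat = (resid[tr][:, :, None] * resid[tr][:, None, :]).reshape(
                len(tr), -1
            )
            for _inner in range(steps_per_batch):
                nll, g = _nll_and_grad(ltri, tri_idx, Dtv, G_flat, resid[va], eta)
                if not np.isfinite(nll):
                    raise FloatingPointError(
                        f"non-finite covariance-training loss at step {step}; "
                        f"L={ltri}, lr={lr}"
                    )
                step += 1
                mstate = b1 * mstate + (1 - b1) * g
                vstate = b2 * vstate + (1 - b2) * g**2
                mhat = mstate / (1 - b1**step)
                vhat = vstate / (1 - b2**step)
                ltri = ltri - lr * mhat / (np.sqrt(vhat) + adam_eps)
            epoch_loss += nll
        losses.append(epoch_loss)

    L = np.zeros((M, M))
    L[tri_idx] = ltri
    return CovKernelModel(
        Xi=X.copy(),
        resid=resid,
        L=L,
        eta=eta,
        scale=label_range,
        circular=circular,
        periods=periods,
        loss_trace=np.asarray(losses),
    )


def predict_cov(model: CovKernelModel, Xq) -> np.ndarray:
    """Covariance matrices at query labels (functional wrapper)."""
    return model.predict(Xq)


@dataclass
class GKRModel:
    """Fitted statistical manifold: smooth mean and smooth covariance."""

    mean: GPMeanModel
    cov: CovKernelModel
    diagonal_only: bool = False

    def predict_mean(self, Xq) -> np.ndarray:
        return self.mean.predict(Xq)

    def predict_cov(self, Xq) -> np.ndarray:
        S = self.cov.predict(Xq)
        if self.diagonal_only:
            D = np.zeros_like(S)
            idx = np.arange(S.shape[1])
            D[:, idx, idx] = S[:, idx, idx]
            return D
        return S

    def predict(self, Xq) -> tuple[np.ndarray, np.ndarray]:
        return self.predict_mean(Xq), self.predict_cov(Xq)

    def save(self, path) -> None:
        """Serialize the fitted manifold (kernel state, residual bank) to NPZ."""
        m = self.mean
        np.savez_compressed(
            path,
            gp_params=m.params.to_vector(),
            gp_circular=m.circular,
            gp_periods=m.periods,
            gp_out_mean=m.out_mean,
            gp_out_sd=m.out_sd,
            gp_keep=m.keep,
            gp_Z=m.Z,
            gp_alpha=m.alpha,
            gp_exact=np.array(bool(m.var_state.get("exact", False))),
            gp_chol=m.var_state.get("chol", m.var_state.get("chol_B")),
            gp_chol_kmm=m.var_state.get("chol_kmm", np.empty((0, 0))),
            cov_Xi=self.cov.Xi,
            cov_resid=self.cov.resid,
            cov_L=self.cov.L,
            cov_eta=np.array(self.cov.eta),
            cov_scale=self.cov.scale if self.cov.scale is not None else np.empty(0),
            diagonal_only=np.array(self.diagonal_only),
        )

    @classmethod
    def load(cls, path) -> "GKRModel":
        from .gp import GPMeanModel, KernelParams

        with np.load(path, allow_pickle=False) as z:
            n_dims = z["gp_Z"].shape[1]
            exact = bool(z["gp_exact"])
            var_state = (
                {"exact": True, "chol": z["gp_chol"]}
                if exact
                else {
                    "exact": False,
                    "chol_B": z["gp_chol"],
                    "chol_kmm": z["gp_chol_kmm"],
                }
            )
            mean = GPMeanModel(
                params=KernelParams.from_vector(z["gp_params"], n_dims),
                circular=z["gp_circular"],
                periods=z["gp_periods"],
                out_mean=z["gp_out_mean"],
                out_sd=z["gp_out_sd"],
                keep=z["gp_keep"],
                Z=z["gp_Z"],
                alpha=z["gp_alpha"],
                var_state=var_state,
            )
            scale = z["cov_scale"]
            cov = CovKernelModel(
                Xi=z["cov_Xi"],
                resid=z["cov_resid"],
                L=z["cov_L"],
                eta=float(z["cov_eta"]),
                scale=scale if scale.size else None,
            )
            return cls(mean=mean, cov=cov, diagonal_only=bool(z["diagonal_only"]))


def fit_gkr(
    data: LabeledDataset,
    n_inducing: int = 200,
    epochs: int = 30,
    batch_size: int = 3000,
    lr: float = 5e-2,
    steps_per_batch: int = 20,
    seed: int = 0,
    eta: float = 1e-6,
    **gp_kwargs,
) -> GKRModel:
    """Convenience two-step fit: GP mean then covariance kernel."""
    mean = fit_mean_gp(data, n_inducing=n_inducing, seed=seed, **gp_kwargs)
    cov = fit_cov_kernel(
        data,
        mean,
        batch_size=batch_size,
        epochs=epochs,
        lr=lr,
        steps_per_batch=steps_per_batch,
        seed=seed + 1,
        eta=eta,
    )
    return GKRModel(mean=mean, cov=cov)


def gkr_loglik(model: GKRModel, data: LabeledDataset) -> float:
    """Total Gaussian log-density of the dataset under the fitted manifold."""
    mu, S = model.predict(data.labels)
    resid = data.states - mu
    chol = np.linalg.cholesky(S)
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    sol = np.linalg.solve(S, resid[:, :, None])[:, :, 0]
    quad = np.einsum("tn,tn->t", resid, sol)
    N = data.n_neurons
    return float(np.sum(-0.5 * (logdet + quad + N * np.log(2 * np.pi))))


# ---------------------------------------------------------------------------
# GKR-S: normality-free residual resampling
# ---------------------------------------------------------------------------


def silverman_bandwidths(labels: np.ndarray) -> np.ndarray:
    """Per-dimension kernel bandwidths sqrt(Sigma_jj) by Silverman's rule:
    ``(4 / (d + 1))^(1/(d+4)) * n^(-1/(d+4)) * sigma_j``."""
    labels = np.atleast_2d(labels)
    n, d = labels.shape
    sd = labels.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise ValueError("constant label column: bandwidth undefined")
    return (4.0 / (d + 1)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4)) * sd


@dataclass
class GKRSModel:
    """GP mean plus kernel-weighted residual resampling."""

    mean: GPMeanModel
    Xi: np.ndarray
    resid: np.ndarray
    bandwidths: np.ndarray  # sqrt(Sigma_jj) per label dim
    weight_floor: float = 1e-6

    def _atom_weights(self, x_q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x_q = np.asarray(x_q, dtype=float).ravel()
        z = (self.Xi - x_q[None, :]) / self.bandwidths[None, :]
        q = np.sum(z**2, axis=1)
        w = np.exp(-0.5 * (q - q.min()))
        w = w / w.sum()
        keep = w >= self.weight_floor
        if not np.any(keep):
            logger.warning("all kernel weights below floor; nearest-neighbor fallback")
            keep = np.zeros_like(keep)
            keep[np.argmin(q)] = True
        w = w[keep]
        return w / w.sum(), np.nonzero(keep)[0]


def fit_gkrs(data: LabeledDataset, mean_model: GPMeanModel) -> GKRSModel:
    """Build the GKR-S residual bank with Silverman bandwidths."""
    X = np.asarray(data.labels, dtype=float)
    resid = np.asarray(data.states, dtype=float) - mean_model.predict(X)
    return GKRSModel(
        mean=mean_model,
        Xi=X,
        resid=resid,
        bandwidths=silverman_bandwidths(X),
    )


def gkrs_moments(
    model: GKRSModel, x_q, eta: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic mean and covariance of the resampling distribution.

    mean = mu(x_q) + sum_i k_i eps_i;
    cov  = sum_i k_i eps_i eps_i^T   (the weighted residual mean is
    treated as negligible), plus optional eta jitter for invertibility.
    """
    w, idx = model._atom_weights(x_q)
    eps = model.resid[idx]
    mean = model.mean.predict(np.atleast_2d(x_q))[0] + w @ eps
    cov = np.einsum("i,ia,ib->ab", w, eps, eps)
    if eta:
        cov = cov + eta * np.eye(cov.shape[0])
    return mean, cov


def gkrs_resample(
    model: GKRSModel, x_q, n_draws: int, seed: int = 0
) -> np.ndarray:
    """Draw pseudo-samples at a query label by residual resampling."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    w, idx = model._atom_weights(x_q)
    rng = np.random.default_rng(seed)
    picks = rng.choice(idx, size=n_draws, p=w)
    mu = model.mean.predict(np.atleast_2d(x_q))[0]
    return mu[None, :] + model.resid[picks]
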