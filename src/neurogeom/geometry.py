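"""Information-geometric metrics of a fitted statistical manifold.

Given any model exposing ``predict_mean`` / ``predict_cov`` (a
:class:`~neurogeom.gkr.GKRModel`, an IFGC-diagonalized copy, or a
ground-truth wrapper), these routines compute:

* tangent frames (Jacobian of the mean surface w.r.t. selected labels),
* speed-slice-manifold radius,
* lattice area spanned by the two spatial tangent vectors,
* the Riemannian metric ``J^T J``,
* the linear Fisher information ``J^T Sigma^{-1} J`` and its trace,
* total (``tr Sigma``) and tangent-projected noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TangentFrame",
    "tangent_frame",
    "ssm_radius",
    "lattice_area",
    "fisher_information",
    "noise_traces",
    "riemannian_metric",
    "make_ifgc",
]


@dataclass
class TangentFrame:
    """Jacobian columns of the mean surface at one query label."""

    x_q: np.ndarray
    J: np.ndarray  # (N, n_dims)
    dims: tuple[int, ...]
    h: np.ndarray  # finite-difference step per selected dim


def tangent_frame(
    model,
    x_q,
    dims: tuple[int, ...] = (0, 1),
    h: float | np.ndarray = 1e-3,
    bounds: np.ndarray | None = None,
) -> TangentFrame:
    """Central-difference Jacobian of the mean surface.

    Near a hard domain boundary (when ``bounds`` is given) the stencil
    degrades to a one-sided difference with a warning.
    """
    x_q = np.asarray(x_q, dtype=float).ravel()
    h = np.broadcast_to(np.asarray(h, dtype=float), (len(dims),)).copy()
    if np.any(h <= 0):
        raise ValueError("finite-difference step must be positive")
    cols = []
    for j, d in enumerate(dims):
        lo = x_q.copy()
        hi = x_q.copy()
        lo[d] -= h[j]
        hi[d] += h[j]
        span = 2 * h[j]
        if bounds is not None:
            if lo[d] < bounds[d, 0]:
                logger.warning("query within h of lower bound; one-sided difference")
                lo[d] = x_q[d]
                span = h[j]
            if hi[d] > bounds[d, 1]:
                logger.warning("query within h of upper bound; one-sided difference")
                hi[d] = x_q[d]
                span = hi[d] - lo[d]
        mu = model.predict_mean(np.vstack([hi, lo]))
        cols.append((mu[0] - mu[1]) / span)
    return TangentFrame(x_q=x_q, J=np.column_stack(cols), dims=tuple(dims), h=h)


def tangent_frames(
    model,
    Xq: np.ndarray,
    dims: tuple[int, ...] = (0, 1),
    h: float | np.ndarray = 1e-3,
) -> np.ndarray:
    """Vectorized central-difference Jacobians; returns (Q, N, n_dims)."""
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    h = np.broadcast_to(np.asarray(h, dtype=float), (len(dims),))
    out = []
    for j, d in enumerate(dims):
        hi = Xq.copy()
        lo = Xq.copy()
        hi[:, d] += h[j]
        lo[:, d] -= h[j]
        out.append((model.predict_mean(hi) - model.predict_mean(lo)) / (2 * h[j]))
    return np.stack(out, axis=-1)


def ssm_radius(
    model,
    v: float,
    bounds: np.ndarray,
    n_points: int = 500,
    seed: int = 0,
    speed_dim: int = 2,
    spatial_dims: tuple[int, int] = (0, 1),
) -> float:
    """Speed-slice-manifold radius at speed ``v``.

    Samples ``n_points`` spatial locations uniformly over ``bounds``
    (rows indexed by spatial dim), evaluates the mean surface at fixed
    speed, and returns the mean Euclidean distance to the centroid.
    """
    rng = np.random.default_rng(seed)
    M = int(max(max(spatial_dims), speed_dim)) + 1
    Xq = np.zeros((n_points, M))
    for d in spatial_dims:
        Xq[:, d] = rng.uniform(bounds[d, 0], bounds[d, 1], n_points)
    Xq[:, speed_dim] = v
    mu = model.predict_mean(Xq)
    center = mu.mean(axis=0)
    return float(np.mean(np.linalg.norm(mu - center, axis=1)))


def lattice_area(frame: TangentFrame | np.ndarray) -> float:
    """Parallelogram area ``sqrt(a^2 b^2 - (a.b)^2)`` of a 2-column frame."""
    J = frame.J if isinstance(frame, TangentFrame) else np.asarray(frame)
    if J.shape[1] != 2:
        raise ValueError("lattice area requires exactly two tangent vectors")
    a, b = J[:, 0], J[:, 1]
    val = (a @ a) * (b @ b) - (a @ b) ** 2
    return float(np.sqrt(max(val, 0.0)))


def fisher_information(
    frame: TangentFrame | np.ndarray, Sigma: np.ndarray
) -> tuple[np.ndarray, float]:
    """Linear Fisher matrix ``J^T Sigma^{-1} J`` and its trace."""
    J = frame.J if isinstance(frame, TangentFrame) else np.asarray(frame)
    sol = np.linalg.solve(Sigma, J)
    I = J.T @ sol
    I = 0.5 * (I + I.T)
    return I, float(np.trace(I))


def noise_traces(
    frame: TangentFrame | np.ndarray,
    Sigma: np.ndarray,
    orthonormal: bool = False,
) -> tuple[float, float]:
    """Total noise ``tr Sigma`` and tangent-projected noise
    ``tr(U^T Sigma U)``.

    By default ``U`` is the column-normalized Jacobian (each tangent vector
    scaled to unit length but not orthogonalized); with
    ``orthonormal=True`` an orthonormal basis of the tangent plane is used
    instead, which guarantees projected <= total.
    """
    J = frame.J if isinstance(frame, TangentFrame) else np.asarray(frame)
    norms = np.linalg.norm(J, axis=0)
    ok = norms > 0
    if not np.all(ok):
        logger.warning("dropping %d zero-length tangent column(s)", int((~ok).sum()))
    J = J[:, ok]
    norms = norms[ok]
    total = float(np.trace(Sigma))
    if J.shape[1] == 0:
        return total, 0.0
    if orthonormal:
        U, _ = np.linalg.qr(J)
    else:
        U = J / norms[None, :]
    proj = float(np.trace(U.T @ Sigma @ U))
    return total, proj


def riemannian_metric(frame: TangentFrame | np.ndarray) -> np.ndarray:
    """Induced metric ``J^T J`` of the mean surface."""
    J = frame.J if isinstance(frame, TangentFrame) else np.asarray(frame)
    return J.T @ J


def make_ifgc(model):
    """Counterfactual independent-firing model: same mean, diagonal Sigma.

    Returns a copy of the model with every predicted covariance replaced
    by its diagonal — the population a trial-shuffle within condition
    would produce (marginals preserved, cell-to-cell covariance removed).
    """
    from .gkr import GKRModel

    if isinstance(model, GKRModel):
        return GKRModel(mean=model.mean, cov=model.cov, diagonal_only=True)

    class _DiagWrapper:
        diagonal_only = True

        def __init__(self, base):
            self._base = base

        def predict_mean(self, Xq):
            return self._base.predict_mean(Xq)

        def predict_cov(self, Xq):
            S = np.asarray(self._base.predict_cov(Xq))
            D = np.zeros_like(S)
            idx = np.arange(S.shape[-1])
            D[..., idx, idx] = S[..., idx, idx]
            return D

        def predict(self, Xq):
            return self.predict_mean(Xq), self.predict_cov(Xq)

    return _DiagWrapper(model)
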