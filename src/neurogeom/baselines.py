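"""Reference estimators: label-space bin averaging and Ledoit-Wolf shrinkage.

Bin averaging partitions the label range into a regular grid and uses the
per-bin sample mean and sample covariance.  The Ledoit-Wolf variant
shrinks each bin's sample covariance toward a scaled identity,
``(1 - lambda) S + lambda (tr S / N) I``, with the shrinkage intensity
``lambda`` from the standard Ledoit-Wolf procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage

from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["BinnedEstimate", "fit_binned", "relative_error"]


@dataclass
class BinnedEstimate:
    """Per-bin sample moments over a regular label-space grid."""

    edges: list[np.ndarray]  # bin edges per label dim
    means: np.ndarray  # (n_bins_total, N); NaN where empty
    covs: np.ndarray  # (n_bins_total, N, N); NaN where undefined
    counts: np.ndarray  # (n_bins_total,)
    shrinkage: str = "none"  # "none" | "lw"
    lambdas: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    def _bin_of(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(Xq)
        idx = np.zeros(Xq.shape[0], dtype=int)
        stride = 1
        for d in reversed(range(len(self.edges))):
            e = self.edges[d]
            k = np.clip(np.searchsorted(e, Xq[:, d], side="right") - 1, 0, len(e) - 2)
            idx += k * stride
            stride *= len(e) - 1
        return idx

    def predict(
        self, Xq: np.ndarray, nearest_fallback: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mean and covariance of the bin containing each query.

        Queries landing in empty (or covariance-undefined) bins either
        raise, or are redirected to the nearest defined bin when
        ``nearest_fallback`` (logged).
        """
        Xq = np.atleast_2d(Xq)
        idx = self._bin_of(Xq)
        undefined = ~np.isfinite(self.covs[idx, 0, 0])
        if np.any(undefined):
            if not nearest_fallback:
                raise ValueError(
                    f"{int(undefined.sum())} queries fall in bins with no "
                    "defined covariance"
                )
            logger.warning(
                "%d query point(s) in empty/undefined bins; using nearest "
                "occupied bin",
                int(undefined.sum()),
            )
            centers = self._bin_centers()
            ok = np.isfinite(self.covs[:, 0, 0])
            ok_idx = np.nonzero(ok)[0]
            for q in np.nonzero(undefined)[0]:
                d2 = np.sum((centers[ok_idx] - Xq[q][None, :]) ** 2, axis=1)
                idx[q] = ok_idx[np.argmin(d2)]
        return self.means[idx], self.covs[idx]

    def _bin_centers(self) -> np.ndarray:
        mids = [0.5 * (e[:-1] + e[1:]) for e in self.edges]
        grids = np.meshgrid(*mids, indexing="ij")
        return np.column_stack([g.ravel() for g in grids])


def fit_binned(
    data: LabeledDataset,
    bins_per_dim: int | tuple[int, ...] = 20,
    shrinkage: str = "none",
    label_bounds: np.ndarray | None = None,
) -> BinnedEstimate:
    """Fit per-bin sample means and covariances on a regular label grid."""
    if shrinkage not in ("none", "lw"):
        raise ValueError("shrinkage must be 'none' or 'lw'")
    X = np.asarray(data.labels, dtype=float)
    R = np.asarray(data.states, dtype=float)
    M = X.shape[1]
    if np.isscalar(bins_per_dim):
        bins_per_dim = (int(bins_per_dim),) * M
    if label_bounds is None:
        label_bounds = np.column_stack([X.min(axis=0), X.max(axis=0)])
    edges = [
        np.linspace(label_bounds[d, 0], label_bounds[d, 1], bins_per_dim[d] + 1)
        for d in range(M)
    ]
    n_total = int(np.prod([len(e) - 1 for e in edges]))
    N = R.shape[1]
    means = np.full((n_total, N), np.nan)
    covs = np.full((n_total, N, N), np.nan)
    counts = np.zeros(n_total, dtype=int)
    lambdas = np.full(n_total, np.nan)

    est = BinnedEstimate(edges, means, covs, counts, shrinkage, lambdas)
    idx = est._bin_of(X)
    for b in np.unique(idx):
        rows = np.nonzero(idx == b)[0]
        counts[b] = len(rows)
        means[b] = R[rows].mean(axis=0)
        if len(rows) >= 2:
            S = np.cov(R[rows], rowvar=False, ddof=0)
            S = np.atleast_2d(S)
            if shrinkage == "lw":
                lam = float(ledoit_wolf_shrinkage(R[rows], assume_centered=False))
                lambdas[b] = lam
                S = (1 - lam) * S + lam * (np.trace(S) / N) * np.eye(N)
            covs[b] = S
    if not np.any(counts > 0):
        raise ValueError("no occupied bins")
    return est


def relative_error(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Mean relative Frobenius error ``||M_hat - M||_F / ||M||_F`` over a
    batch of query quantities (vectors or matrices).

    Queries with zero-norm truth are excluded (with a warning).
    """
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("shape mismatch between estimates and truths")
    flat_e = estimates.reshape(estimates.shape[0], -1)
    flat_t = truths.reshape(truths.shape[0], -1)
    denom = np.linalg.norm(flat_t, axis=1)
    ok = denom > 0
    if not np.all(ok):
        logger.warning("%d zero-norm ground-truth entries excluded", int((~ok).sum()))
    if not np.any(ok):
        raise ValueError("all ground-truth norms are zero")
    err = np.linalg.norm(flat_e[ok] - flat_t[ok], axis=1) / denom[ok]
    return float(err.mean())
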