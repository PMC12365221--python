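"""Barcode pipeline: cloud condensation, shuffle thresholds, Betti counts.

The practical recipe for deciding whether a manifold sampled from a
fitted model is, e.g., toroidal: sample a cloud of mean-surface points,
project to a few principal components, condense with k-means, compute the
Rips barcode, and count bars longer than a data-driven threshold.  The
threshold is the maximum finite bar length observed after independently
rolling (circularly shifting) each column of the state matrix — a
shuffle that preserves each neuron's marginal sequence but destroys the
joint geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .rips import enclosing_radius, rips_barcode

__all__ = [
    "Barcode",
    "condense_cloud",
    "barcode",
    "shuffle_threshold",
    "betti",
    "toroidal_signature",
]


@dataclass
class Barcode:
    """Persistence intervals per dimension with thresholding metadata."""

    intervals: dict[int, np.ndarray]
    cap: float  # filtration cap used (enclosing radius by default)
    threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def bar_lengths(self, dim: int) -> np.ndarray:
        """Bar lengths with infinite deaths truncated at the cap."""
        iv = self.intervals.get(dim, np.empty((0, 2)))
        if len(iv) == 0:
            return np.empty(0)
        death = np.minimum(iv[:, 1], self.cap)
        return death - iv[:, 0]

    def max_finite_length(self) -> float:
        """Longest finite-death bar over all dimensions (0 if none)."""
        best = 0.0
        for iv in self.intervals.values():
            if len(iv) == 0:
                continue
            fin = iv[np.isfinite(iv[:, 1])]
            if len(fin):
                best = max(best, float(np.max(fin[:, 1] - fin[:, 0])))
        return best


def condense_cloud(
    points: np.ndarray,
    n_pcs: int = 6,
    kmeans_k: int | None = 1200,
    seed: int = 0,
) -> np.ndarray:
    """PCA projection followed by optional k-means condensation.

    ``kmeans_k=None`` (or a value at least the cloud size) skips k-means,
    as appropriate for grids of a few hundred predictions.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    n_pcs_eff = min(n_pcs, d)
    if n < n_pcs_eff:
        raise ValueError(f"need at least {n_pcs_eff} points for {n_pcs_eff} PCs")
    Z = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(points)
    if kmeans_k is None or kmeans_k >= n:
        return Z
    km = KMeans(n_clusters=kmeans_k, n_init=10, random_state=seed)
    km.fit(Z)
    return km.cluster_centers_


def barcode(
    points: np.ndarray, sparse_eps: float = 0.2, max_dim: int = 2
) -> Barcode:
    """Rips barcode of a cloud (threshold unset)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    from scipy.spatial.distance import pdist, squareform

    cap = enclosing_radius(squareform(pdist(points)))
    intervals = rips_barcode(points, max_dim=max_dim, sparse_eps=sparse_eps)
    return Barcode(
        intervals=intervals,
        cap=cap,
        meta={"n_points": len(points), "sparse_eps": sparse_eps, "max_dim": max_dim},
    )


def shuffle_threshold(
    point_table: np.ndarray,
    repeats: int = 20,
    seed: int = 0,
    n_pcs: int | None = 6,
    kmeans_k: int | None = None,
    sparse_eps: float = 0.2,
    max_dim: int = 2,
) -> float:
    """Bar-length threshold from column-rolled shuffles of the state table.

    Per repeat, each column of the table is circularly shifted by an
    independent random offset; the shuffled table goes through the same
    condense-and-barcode recipe, and the maximum finite bar length over
    all dimensions is collected.  The threshold is the maximum over
    repeats.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    table = np.asarray(point_table, dtype=float)
    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(repeats):
        shuf = np.column_stack(
            [np.roll(table[:, c], rng.integers(len(table))) for c in range(table.shape[1])]
        )
        cloud = shuf
        if n_pcs is not None:
            cloud = condense_cloud(
                shuf, n_pcs=n_pcs, kmeans_k=kmeans_k, seed=int(rng.integers(2**31 - 1))
            )
        bc = barcode(cloud, sparse_eps=sparse_eps, max_dim=max_dim)
        best = max(best, bc.max_finite_length())
    return best


def betti(bc: Barcode, threshold: float | None = None) -> tuple[int, int, int]:
    """Count bars longer than the threshold per dimension.

    Infinite-death bars count with length capped at the barcode's cap
    (so the essential connected component always registers once the
    threshold is below the cap).
    """
    thr = bc.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no threshold set on barcode and none supplied")
    out = []
    for d in (0, 1, 2):
        out.append(int(np.sum(bc.bar_lengths(d) > thr)))
    return tuple(out)


def toroidal_signature(
    points: np.ndarray,
    seed: int = 0,
    n_pcs: int = 6,
    kmeans_k: int | None = 150,
    repeats: int = 20,
    sparse_eps: float = 0.2,
) -> tuple[tuple[int, int, int], Barcode]:
    """Full recipe: condense, barcode, shuffle threshold, Betti counts.

    Returns the (beta0, beta1, beta2) counts and the thresholded barcode;
    a toroidal cloud yields (1, 2, 1).
    """
    cloud = condense_cloud(points, n_pcs=n_pcs, kmeans_k=kmeans_k, seed=seed)
    bc = barcode(cloud, sparse_eps=sparse_eps)
    bc.threshold = shuffle_threshold(
        points,
        repeats=repeats,
        seed=seed + 1,
        n_pcs=n_pcs,
        kmeans_k=kmeans_k,
        sparse_eps=sparse_eps,
    )
    return betti(bc), bc
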