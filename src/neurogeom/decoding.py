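"""Spatial coding accuracy (SCA) and its Fisher-information upper bound.

SCA measures how well a linear classifier separates neural states sampled
from two nearby spatial boxes.  Per speed bin, random location centers are
drawn; each center spawns two square boxes displaced by ``+/- delta_l``
along a random direction; in-box states are class-balanced, split into
train/test, and a linear classifier's test accuracy is averaged over
valid centers.

The theoretical ceiling for any linear read-out of two Gaussian classes
with shared covariance is ``Phi(sqrt(dmu^T Sigma^{-1} dmu) / 2)``; for
symmetric boxes around a center this becomes
``Phi(sqrt(dx^T I dx))`` with ``I`` the linear Fisher matrix, averaged
over the random displacement direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.svm import LinearSVC

from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SCAConfig",
    "SCAResult",
    "sca",
    "ifgc_shuffle_sca",
    "optimal_accuracy",
    "sca_upper_bound",
]


@dataclass(frozen=True)
class SCAConfig:
    """Geometry and classifier settings for the two-box task."""

    delta_l: float = 5.0  # half the box-center separation
    box_edge: float = 10.0
    n_locations: int = 300
    min_points: int = 50
    test_frac: float = 0.33
    classifier: str = "logistic"  # logistic | svm | perceptron
    C: float = 1.0
    speed_bin: float = 5.0
    speed_range: tuple[float, float] = (5.0, 45.0)
    spatial_labels: tuple[str, str] = ("x", "y")
    speed_label: str = "speed"

    def __post_init__(self) -> None:
        if self.delta_l <= 0:
            raise ValueError("delta_l must be positive")
        if not 0 < self.test_frac < 1:
            raise ValueError("test_frac must be in (0, 1)")
        if self.min_points < 4:
            raise ValueError("min_points must allow at least 2 points per class")


@dataclass
class SCAResult:
    """Per-speed-bin accuracies of the two-box classification task."""

    speed_bins: np.ndarray  # left edges
    accuracy: np.ndarray  # NaN where no valid center
    n_valid: np.ndarray
    per_location: list = field(default_factory=list)
    shuffled: bool = False


def _make_classifier(cfg: SCAConfig, seed: int):
    if cfg.classifier == "logistic":
        return LogisticRegression(C=cfg.C, max_iter=1000, random_state=seed)
    if cfg.classifier == "svm":
        return LinearSVC(C=cfg.C, max_iter=5000, random_state=seed)
    if cfg.classifier == "perceptron":
        return Perceptron(random_state=seed)
    raise ValueError(f"unknown classifier {cfg.classifier!r}")


def _two_box_accuracy(states, pos, center, direction, cfg, rng, shuffle):
    """Train/test accuracy for one location; NaN if too little data."""
    half = cfg.box_edge / 2.0
    acc_sets = []
    for sign in (-1.0, 1.0):
        c = center + sign * cfg.delta_l * direction
        inside = np.all((pos >= c - half) & (pos < c + half), axis=1)
        acc_sets.append(np.nonzero(inside)[0])
    n = min(len(acc_sets[0]), len(acc_sets[1]))
    if n == 0 or len(acc_sets[0]) + len(acc_sets[1]) < cfg.min_points:
        return np.nan
    rows = []
    for s in acc_sets:
        rows.append(rng.choice(s, size=n, replace=False) if len(s) > n else s)
    Xa, Xb = states[rows[0]], states[rows[1]]
    if shuffle:
        # permute each neuron independently within each box: marginals
        # preserved, cell-to-cell correlation destroyed
        Xa = np.column_stack([rng.permutation(Xa[:, j]) for j in range(Xa.shape[1])])
        Xb = np.column_stack([rng.permutation(Xb[:, j]) for j in range(Xb.shape[1])])
    Xall = np.vstack([Xa, Xb])
    y = np.repeat([0, 1], n)
    perm = rng.permutation(len(y))
    Xall, y = Xall[perm], y[perm]
    n_test = max(1, int(round(cfg.test_frac * len(y))))
    Xtr, ytr = Xall[n_test:], y[n_test:]
    Xte, yte = Xall[:n_test], y[:n_test]
    if len(np.unique(ytr)) < 2 or len(ytr) < 2:
        return np.nan
    clf = _make_classifier(cfg, int(rng.integers(2**31 - 1)))
    clf.fit(Xtr, ytr)
    return float(clf.score(Xte, yte))


def sca(
    data: LabeledDataset,
    config: SCAConfig | None = None,
    seed: int = 0,
    _shuffle: bool = False,
) -> SCAResult:
    """Spatial coding accuracy per speed bin."""
    cfg = config or SCAConfig()
    rng = np.random.default_rng(seed)
    pos = np.column_stack([data.label(n) for n in cfg.spatial_labels])
    speed = data.label(cfg.speed_label)
    lo, hi = cfg.speed_range
    edges = np.arange(lo, hi, cfg.speed_bin)
    acc = np.full(len(edges), np.nan)
    n_valid = np.zeros(len(edges), dtype=int)
    per_loc = []
    pmin, pmax = pos.min(axis=0), pos.max(axis=0)
    for bi, v0 in enumerate(edges):
        rows = (speed >= v0) & (speed < v0 + cfg.speed_bin)
        loc_accs = []
        if np.any(rows):
            S, P = data.states[rows], pos[rows]
            for _ in range(cfg.n_locations):
                center = rng.uniform(pmin, pmax)
                ang = rng.uniform(0, 2 * np.pi)
                direction = np.array([np.cos(ang), np.sin(ang)])
                a = _two_box_accuracy(S, P, center, direction, cfg, rng, _shuffle)
                if np.isfinite(a):
                    loc_accs.append(a)
        if loc_accs:
            acc[bi] = float(np.mean(loc_accs))
            n_valid[bi] = len(loc_accs)
        else:
            logger.warning("no valid centers in speed bin [%g, %g)", v0, v0 + cfg.speed_bin)
        per_loc.append(np.asarray(loc_accs))
    return SCAResult(
        speed_bins=edges,
        accuracy=acc,
        n_valid=n_valid,
        per_location=per_loc,
        shuffled=_shuffle,
    )


def ifgc_shuffle_sca(
    data: LabeledDataset, config: SCAConfig | None = None, seed: int = 0
) -> SCAResult:
    """SCA after within-box trial shuffling of each neuron (IFGC variant)."""
    return sca(data, config, seed, _shuffle=True)


def optimal_accuracy(mu1, mu2, Sigma) -> float:
    """Bayes-optimal linear accuracy for two equal-prior Gaussian classes:
    ``Phi(sqrt(dmu^T Sigma^{-1} dmu) / 2)``."""
    dmu = np.asarray(mu2, dtype=float) - np.asarray(mu1, dtype=float)
    d2 = float(dmu @ np.linalg.solve(Sigma, dmu))
    return float(norm.cdf(np.sqrt(max(d2, 0.0)) / 2.0))


def sca_upper_bound(
    I: np.ndarray, delta_l: float, n_mc: int = 10_000, seed: int = 0
) -> float:
    """Direction-averaged Fisher bound on the two-box accuracy.

    Monte-Carlo average over isotropic displacement directions (Gaussian
    draws rescaled to length ``delta_l``) of
    ``Phi(sqrt(dx^T I dx))``; lies in [0.5, 1].
    """
    I = np.asarray(I, dtype=float)
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    w = np.linalg.eigvalsh(0.5 * (I + I.T))
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("Fisher matrix must be positive semi-definite")
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_mc, I.shape[0]))
    d *= delta_l / np.linalg.norm(d, axis=1, keepdims=True)
    q = np.einsum("ti,ij,tj->t", d, I, d)
    return float(np.mean(norm.cdf(np.sqrt(np.clip(q, 0.0, None)))))
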