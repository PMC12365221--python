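"""Synthetic fixtures with known ground-truth statistical manifolds.

Four generators are provided:

* a 1-D ring population (von Mises tuning curves over a circular label),
* a 2-D bump population (Gaussian receptive fields on ``[-1, 1]^2``),
* an independent Poisson speed-gain (IPSG) grid-cell simulator, and
* a two-neuron correlated-noise toy.

The ring and bump models draw Gaussian states around a smooth mean
``mu(x)`` with a structured, label-dependent covariance
``Sigma(x) = L L^T`` where ``L_ij = (alpha * mu_i(x) + nu) * exp(-gamma
|i - j|)``: ``alpha`` scales signal-dependent noise, ``nu`` is a constant
noise floor and ``gamma`` sets how quickly cross-neuron correlations decay
with "distance" between neuron indices.  Because the true ``(mu, Sigma)``
are analytic, these fixtures support exact estimator benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset, LabelMeta

__all__ = [
    "TuningModelSpec",
    "IPSGSpec",
    "TwoNeuronSpec",
    "build_tuning_model",
    "true_moments",
    "sample_dataset",
    "simulate_ipsg",
    "ipsg_analytic",
    "two_neuron_fisher",
]

# covariance parameters (alpha, nu, gamma) per model family
_RING_COV = (0.2, 0.05, 1.0)
_BUMP_COV = (0.5, 0.1, 1.0)


@dataclass(frozen=True)
class TuningModelSpec:
    """Ground-truth tuning model for the ring (1-D) or bump (2-D) family."""

    kind: str  # "ring1d" | "bump2d"
    n_neurons: int
    sigma: float  # tuning width
    gains: np.ndarray  # ring: per-neuron gain g_i; bump: width scale lambda_i
    centers: np.ndarray  # preferred label value per neuron
    cov_params: tuple[float, float, float]  # (alpha, nu, gamma)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ring1d", "bump2d"):
            raise ValueError(f"unknown tuning model kind {self.kind!r}")
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.sigma <= 0:
            raise ValueError("tuning width sigma must be positive")
        alpha, nu, gamma = self.cov_params
        if nu < 0 or gamma < 0:
            raise ValueError("nu and gamma must be non-negative")
        if self.kind == "bump2d" and np.any(np.abs(self.centers) > 1):
            raise ValueError("bump2d centers must lie in [-1, 1]^2")

    @property
    def label_meta(self) -> tuple[LabelMeta, ...]:
        if self.kind == "ring1d":
            return (LabelMeta("theta", circular=True, period=2 * np.pi, units="rad"),)
        return (LabelMeta("x"), LabelMeta("y"))

    @property
    def label_bounds(self) -> np.ndarray:
        """(M, 2) array of [low, high] per label dimension."""
        if self.kind == "ring1d":
            return np.array([[0.0, 2 * np.pi]])
        return np.array([[-1.0, 1.0], [-1.0, 1.0]])


def build_tuning_model(
    kind: str,
    n_neurons: int = 10,
    seed: int = 0,
    sigma: float = 0.3,
    cov_params: tuple[float, float, float] | None = None,
) -> TuningModelSpec:
    """Draw a random tuning model of the requested family.

    The ring model places centers deterministically at ``z_i = 2 pi i / N``
    with random gains ``g_i ~ U(0.5, 1.5)``; the bump model draws centers
    uniformly on ``[-1, 1]^2`` with random width scales
    ``lambda_i ~ U(0.5, 1.5)``.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "ring1d":
        centers = 2 * np.pi * np.arange(n_neurons) / n_neurons
        gains = rng.uniform(0.5, 1.5, n_neurons)
        cov = _RING_COV if cov_params is None else cov_params
    elif kind == "bump2d":
        centers = rng.uniform(-1.0, 1.0, size=(n_neurons, 2))
        gains = rng.uniform(0.5, 1.5, n_neurons)
        cov = _BUMP_COV if cov_params is None else cov_params
    else:
        raise ValueError(f"unknown tuning model kind {kind!r}")
    return TuningModelSpec(
        kind=kind,
        n_neurons=n_neurons,
        sigma=sigma,
        gains=gains,
        centers=centers,
        cov_params=tuple(cov),
        rng_seed=seed,
    )


def _tuning_mean(spec: TuningModelSpec, x: np.ndarray) -> np.ndarray:
    """Mean vector mu(x) for a batch of labels; returns (T, N)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.kind == "ring1d":
        # von Mises tuning normalized to peak = gain
        kappa = 1.0 / spec.sigma**2
        d = x[:, 0][:, None] - spec.centers[None, :]
        return spec.gains[None, :] * np.exp(kappa * (np.cos(d) - 1.0))
    # bump2d: isotropic Gaussian receptive fields, width sigma * lambda_i
    if x.shape[1] != 2:
        raise ValueError("bump2d expects 2-D labels")
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("bump2d labels must lie in [-1, 1]^2")
    d2 = np.sum((x[:, None, :] - spec.centers[None, :, :]) ** 2, axis=-1)
    widths = (spec.sigma * spec.gains) ** 2
    return np.exp(-d2 / (2.0 * widths[None, :]))


def true_moments(spec: TuningModelSpec, x) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth mean and covariance at one label value.

    Returns ``(mu, Sigma)`` with ``Sigma = L L^T`` and
    ``L_ij = (alpha mu_i + nu) exp(-gamma |i - j|)``; symmetric PSD by
    construction.
    """
    mu = _tuning_mean(spec, x)[0]
    alpha, nu, gamma = spec.cov_params
    idx = np.arange(spec.n_neurons)
    decay = np.exp(-gamma * np.abs(idx[:, None] - idx[None, :]))
    L = (alpha * mu + nu)[:, None] * decay
    return mu, L @ L.T


def true_moments_batch(spec: TuningModelSpec, X) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`true_moments` over a (T, M) label batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mus = _tuning_mean(spec, X)
    alpha, nu, gamma = spec.cov_params
    idx = np.arange(spec.n_neurons)
    decay = np.exp(-gamma * np.abs(idx[:, None] - idx[None, :]))
    Ls = (alpha * mus + nu)[:, :, None] * decay[None, :, :]
    return mus, np.einsum("tik,tjk->tij", Ls, Ls)


def sample_dataset(
    spec: TuningModelSpec, n_points: int = 300, seed: int | None = None
) -> LabeledDataset:
    """Draw a synthetic dataset of ``n_points`` labeled Gaussian states.

    Labels are uniform over the model's domain (half-open ``[0, 2 pi)`` for
    the ring); each state is a draw from ``N(mu(x), Sigma(x))``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    b = spec.label_bounds
    X = rng.uniform(b[:, 0], b[:, 1], size=(n_points, b.shape[0]))
    mus, covs = true_moments_batch(spec, X)
    # one multivariate normal draw per row via cholesky of each covariance
    eps = rng.standard_normal((n_points, spec.n_neurons))
    chol = np.linalg.cholesky(covs + 1e-12 * np.eye(spec.n_neurons))
    states = mus + np.einsum("tij,tj->ti", chol, eps)
    return LabeledDataset(
        states=states,
        labels=X,
        label_meta=spec.label_meta,
        provenance={
            "generator": spec.kind,
            "seed": int(spec.rng_seed if seed is None else seed),
            "n_points": int(n_points),
            "cov_params": list(spec.cov_params),
        },
    )


# ---------------------------------------------------------------------------
# IPSG grid cells
# ---------------------------------------------------------------------------


def _default_lattice_dirs() -> np.ndarray:
    ang = np.deg2rad([0.0, 60.0, 120.0])
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


@dataclass(frozen=True)
class IPSGSpec:
    """Independent Poisson speed-gain grid-cell population.

    Each cell fires independently with Poisson counts of mean
    ``f(v) * M_i(x) * dt`` where ``M_i`` is a three-cosine hexagonal rate
    map with random phases and ``f(v) = g_max (1 - exp(-v / v_scale))`` is
    a shared saturating speed gain.
    """

    n_cells: int = 10
    spatial_period: float = np.pi
    phases: np.ndarray | None = None  # (n_cells, 3) in [0, 2 pi)
    offset: float = 4.0
    g_max: float = 20.0
    v_scale: float = 10.0
    dt: float = 1.0
    field_bounds: tuple[float, float] = (-np.pi, np.pi)
    speed_range: tuple[float, float] = (0.0, 40.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.spatial_period <= 0 or self.dt <= 0:
            raise ValueError("spatial_period and dt must be positive")
        # the three cosines sum to at least -3; the offset must keep the
        # rate map non-negative everywhere
        if self.offset < 3.0:
            raise ValueError(
                "offset must be >= 3 so the hexagonal rate map stays non-negative"
            )
        if self.phases is not None and np.asarray(self.phases).shape != (
            self.n_cells,
            3,
        ):
            raise ValueError("phases must have shape (n_cells, 3)")

    def resolved_phases(self) -> np.ndarray:
        if self.phases is not None:
            return np.asarray(self.phases, dtype=float)
        rng = np.random.default_rng(self.rng_seed)
        return rng.uniform(0.0, 2 * np.pi, size=(self.n_cells, 3))

    def rate_map(self, X: np.ndarray) -> np.ndarray:
        """Spatial rate maps M_i(x) for a (T, 2) batch; returns (T, n_cells)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = _default_lattice_dirs()  # (3, 2)
        proj = X @ K.T  # (T, 3)
        ph = self.resolved_phases()  # (n, 3)
        arg = (2 * np.pi / self.spatial_period) * proj[:, None, :] + ph[None, :, :]
        return np.cos(arg).sum(axis=-1) + self.offset

    def speed_gain(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return self.g_max - self.g_max * np.exp(-v / self.v_scale)


def simulate_ipsg(
    spec: IPSGSpec, n_points: int = 10_000, seed: int | None = None
) -> LabeledDataset:
    """Simulate labeled Poisson spike counts from an IPSG population.

    Positions are uniform over the field, speeds uniform over the speed
    range; each count is Poisson with mean ``f(v) M_i(x) dt``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    lo, hi = spec.field_bounds
    X = rng.uniform(lo, hi, size=(n_points, 2))
    v = rng.uniform(*spec.speed_range, size=n_points)
    rates = spec.speed_gain(v)[:, None] * spec.rate_map(X)
    if np.any(rates < -1e-12):
        raise ValueError("negative Poisson rate; increase the rate-map offset")
    counts = rng.poisson(np.clip(rates, 0.0, None) * spec.dt).astype(float)
    labels = np.column_stack([X, v])
    meta = (LabelMeta("x"), LabelMeta("y"), LabelMeta("speed"))
    return LabeledDataset(
        states=counts,
        labels=labels,
        label_meta=meta,
        provenance={
            "generator": "ipsg",
            "seed": int(spec.rng_seed if seed is None else seed),
            "n_points": int(n_points),
            "dt": spec.dt,
        },
    )


def ipsg_analytic(
    spec: IPSGSpec, v_grid, n_grid: int = 200
) -> dict[str, np.ndarray]:
    """Closed-form speed dependence of manifold size, noise and Fisher.

    Numerical quadrature on a regular ``n_grid x n_grid`` spatial grid of:

    * manifold radius ``R(v)``: spatial average of the distance of the mean
      rate vector to its spatial centroid,
    * total noise ``sigma^2(v)``: spatial average of the summed Poisson
      variances ``f(v) M_i(x) / dt``,
    * total Fisher ``I(v)``: spatial average of
      ``f(v) ||grad M_i||^2 / M_i`` summed over cells.

    All three are non-decreasing in ``v`` whenever the speed gain is.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("v_grid must be non-empty")
    if np.any(v_grid < 0):
        raise ValueError("speeds must be non-negative")
    lo, hi = spec.field_bounds
    xs = np.linspace(lo, hi, n_grid)
    XX, YY = np.meshgrid(xs, xs, indexing="ij")
    P = np.column_stack([XX.ravel(), YY.ravel()])
    M = spec.rate_map(P)  # (G, n)
    Mbar = M.mean(axis=0)

    # spatial gradient of each cosine component, analytic
    K = _default_lattice_dirs()
    ph = spec.resolved_phases()
    w = 2 * np.pi / spec.spatial_period
    arg = w * (P @ K.T)[:, None, :] + ph[None, :, :]  # (G, n, 3)
    # grad M_i = -w * sum_a sin(arg_a) k^a ; squared norm summed over x,y
    sin_a = np.sin(arg)
    gx = -w * np.einsum("gna,a->gn", sin_a, K[:, 0])
    gy = -w * np.einsum("gna,a->gn", sin_a, K[:, 1])
    grad2 = gx**2 + gy**2

    f = spec.speed_gain(v_grid)
    radius = np.array(
        [np.mean(np.sqrt(np.sum((fv * (M - Mbar)) ** 2, axis=1))) for fv in f]
    )
    total_noise = f * Mbar.sum() / spec.dt
    fisher_per_rate = np.mean(np.sum(grad2 / np.clip(M, 1e-12, None), axis=1))
    total_fisher = f * fisher_per_rate * spec.dt
    return {
        "v": v_grid,
        "radius": radius,
        "total_noise": total_noise,
        "total_fisher": total_fisher,
    }


# ---------------------------------------------------------------------------
# two-neuron correlated-noise toy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoNeuronSpec:
    """Two neurons, two classes, correlated Gaussian noise."""

    mu1: tuple[float, float] = (1.0, 0.0)
    mu2: tuple[float, float] = (0.0, 1.0)
    rho: float = 0.0
    n_per_class: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("noise correlation must satisfy |rho| < 1")

    @property
    def cov(self) -> np.ndarray:
        return np.array([[1.0, self.rho], [self.rho, 1.0]])

    def sample(self, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Draw (states, class labels in {0, 1}) balanced samples."""
        rng = np.random.default_rng(self.rng_seed if seed is None else seed)
        chol = np.linalg.cholesky(self.cov)
        n = self.n_per_class
        eps = rng.standard_normal((2 * n, 2)) @ chol.T
        states = np.vstack(
            [np.asarray(self.mu1) + eps[:n], np.asarray(self.mu2) + eps[n:]]
        )
        y = np.repeat([0, 1], n)
        return states, y


def two_neuron_fisher(spec: TwoNeuronSpec) -> float:
    """Linear Fisher information ``(dmu)^T Sigma^{-1} (dmu)`` of the toy.

    For the default class means (1,0) and (0,1) this equals
    ``2 / (1 - rho)``: positive noise correlation pushes noise off the
    discrimination axis and helps, negative correlation hurts.
    """
    dmu = np.asarray(spec.mu2, dtype=float) - np.asarray(spec.mu1, dtype=float)
    return float(dmu @ np.linalg.solve(spec.cov, dmu))
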