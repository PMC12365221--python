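"""Spike recordings to labeled rate datasets, rate maps, gridness, resampling.

The preprocessing chain for open-field recordings:

1. bin spike times (10 ms), convert to rates, smooth temporally (20 ms sd);
2. interpolate positions to bin centers and compute speed by central
   differences;
3. score each cell's spatial rate map for hexagonal (grid) structure and
   drop low-gridness cells and out-of-range speeds;
4. resample into speed-balanced replicate datasets so that slow and fast
   running are equally represented;
5. optionally scan the dataset for departures from Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.stats import shapiro
from sklearn.decomposition import PCA

from .dataset import LabeledDataset, spatial_meta

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeRecording",
    "RateMap",
    "SampledDatasetSet",
    "spikes_to_dataset",
    "rate_map",
    "gridness",
    "filter_dataset",
    "balanced_resample",
    "normality_scan",
]


@dataclass
class SpikeRecording:
    """Per-cell spike times plus a 2-D position trace."""

    spike_times: list  # list of 1-D arrays, seconds
    pos_times: np.ndarray  # (P,) seconds
    positions: np.ndarray  # (P, 2) cm
    arena: tuple[float, float] = (150.0, 150.0)

    def __post_init__(self) -> None:
        self.pos_times = np.asarray(self.pos_times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.positions.shape != (len(self.pos_times), 2):
            raise ValueError("positions must be (P, 2) aligned with pos_times")

    def save(self, path) -> None:
        """Write to NPZ: ``spikes_<i>`` arrays plus ``pos_times``/``positions``."""
        arrays = {
            f"spikes_{i}": np.asarray(st, dtype=float)
            for i, st in enumerate(self.spike_times)
        }
        np.savez_compressed(
            path,
            pos_times=self.pos_times,
            positions=self.positions,
            arena=np.asarray(self.arena, dtype=float),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SpikeRecording":
        """Read the NPZ layout written by :meth:`save` (per-cell spike-time
        arrays named ``spikes_<i>`` plus a tracking trace)."""
        with np.load(path, allow_pickle=False) as z:
            keys = sorted(
                (k for k in z.files if k.startswith("spikes_")),
                key=lambda k: int(k.split("_")[1]),
            )
            return cls(
                spike_times=[z[k] for k in keys],
                pos_times=z["pos_times"],
                positions=z["positions"],
                arena=tuple(z["arena"]) if "arena" in z.files else (150.0, 150.0),
            )


def spikes_to_dataset(
    rec: SpikeRecording,
    bin_s: float = 0.010,
    smooth_sd_s: float = 0.020,
    max_gap_s: float = 0.5,
) -> LabeledDataset:
    """Convert a spike recording into a labeled firing-rate dataset.

    Spikes are counted in ``bin_s`` bins, divided by the bin width, and
    smoothed with a temporal Gaussian (sd ``smooth_sd_s``).  Positions are
    linearly interpolated to bin centers; speed is the L2 norm of the
    central difference ``(p_{i+1} - p_{i-1}) / (2 * bin_s)``.  Bins inside
    tracking gaps longer than ``max_gap_s`` are dropped.
    """
    if len(rec.spike_times) == 0:
        raise ValueError("recording has no cells")
    t0 = float(rec.pos_times[0])
    t1 = float(rec.pos_times[-1])
    if t1 <= t0:
        raise ValueError("position trace must span a positive duration")
    edges = np.arange(t0, t1 + bin_s, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.empty((len(centers), len(rec.spike_times)))
    for ci, st in enumerate(rec.spike_times):
        counts, _ = np.histogram(np.asarray(st, dtype=float), bins=edges)
        rates[:, ci] = counts / bin_s
    sigma_bins = smooth_sd_s / bin_s
    rates = ndimage.gaussian_filter1d(rates, sigma=sigma_bins, axis=0)

    pos = np.column_stack(
        [np.interp(centers, rec.pos_times, rec.positions[:, d]) for d in (0, 1)]
    )
    vel = np.zeros_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2.0 * bin_s)
    vel[0] = vel[1]
    vel[-1] = vel[-2]
    speed = np.linalg.norm(vel, axis=1)

    # flag bins falling inside tracking gaps
    gap_idx = np.nonzero(np.diff(rec.pos_times) > max_gap_s)[0]
    ok = np.ones(len(centers), dtype=bool)
    for g in gap_idx:
        ok &= ~((centers > rec.pos_times[g]) & (centers < rec.pos_times[g + 1]))
    if not np.all(ok):
        logger.warning("dropping %d bins inside tracking gaps", int(np.sum(~ok)))
    labels = np.column_stack([pos, speed])[ok]
    return LabeledDataset(
        states=rates[ok],
        labels=labels,
        label_meta=spatial_meta(),
        provenance={"source": "spikes", "bin_s": bin_s, "smooth_sd_s": smooth_sd_s},
    )


@dataclass
class RateMap:
    """Occupancy-corrected spatial firing-rate map of one cell."""

    rates: np.ndarray  # (nx, ny) Hz
    bin_cm: float
    mask: np.ndarray  # visited-bin mask before smoothing
    extent: tuple[float, float, float, float] = (0.0, 150.0, 0.0, 150.0)


def rate_map(
    data: LabeledDataset,
    cell: int,
    spatial_bin: float = 3.0,
    smooth_sd: float = 8.25,
    arena: tuple[float, float] | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> RateMap:
    """Occupancy-corrected rate map on a regular spatial grid.

    Mean rates are histogrammed per bin (unvisited bins zero), then both
    the rate image and the visited mask are blurred with a Gaussian
    (``smooth_sd`` cm) and their ratio is the corrected map — this removes
    the bias that plain smoothing would leak into poorly visited regions.
    """
    x = data.label("x")
    y = data.label("y")
    r = data.states[:, cell]
    if arena is None:
        arena = (x.max() - origin[0], y.max() - origin[1])
    nx = max(1, int(np.ceil(arena[0] / spatial_bin)))
    ny = max(1, int(np.ceil(arena[1] / spatial_bin)))
    xe = origin[0] + np.arange(nx + 1) * spatial_bin
    ye = origin[1] + np.arange(ny + 1) * spatial_bin
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    sums, _, _ = np.histogram2d(x, y, bins=(xe, ye), weights=r)
    if not np.any(counts > 0):
        raise ValueError("no visited spatial bins")
    mask = (counts > 0).astype(float)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    sig = smooth_sd / spatial_bin
    sm_rate = ndimage.gaussian_filter(mean, sigma=sig)
    sm_mask = ndimage.gaussian_filter(mask, sigma=sig)
    corrected = np.where(sm_mask > 1e-12, sm_rate / np.maximum(sm_mask, 1e-12), 0.0)
    return RateMap(
        rates=corrected,
        bin_cm=spatial_bin,
        mask=mask,
        extent=(xe[0], xe[-1], ye[0], ye[-1]),
    )


def _annulus_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    outer = min(h, w) / 2.0
    inner = np.sqrt(0.15) * outer  # inner area = 15% of outer circle
    return (rr <= outer) & (rr >= inner)


def _pearson_autocorrelogram(img: np.ndarray) -> np.ndarray:
    """Spatial autocorrelogram with a Pearson correlation at every lag.

    Each lag's value is the correlation coefficient of the overlapping
    pixels, so decreasing overlap at large lags does not taper the map.
    Returned cropped to half-lag range, odd-sized with the zero lag at
    the exact center (so rotations pivot about it).
    """
    ones = np.ones_like(img)

    def F(a, b):
        return signal.correlate(a, b, mode="full", method="fft")

    n_ov = F(ones, ones)
    s1, s2 = F(img, ones), F(ones, img)
    s11, s22 = F(img**2, ones), F(ones, img**2)
    s12 = F(img, img)
    num = s12 - s1 * s2 / n_ov
    den = np.sqrt(
        np.maximum(s11 - s1**2 / n_ov, 0.0) * np.maximum(s22 - s2**2 / n_ov, 0.0)
    )
    out = np.where(den > 1e-10 * img.size, num / np.maximum(den, 1e-12), 0.0)
    c = img.shape[0] - 1
    r = img.shape[0] // 2
    return out[c - r : c + r + 1, c - r : c + r + 1]


def gridness(rmap: RateMap, pad_cm: float = 0.0) -> float:
    """Hexagonality score of a rate map's spatial autocorrelogram.

    The autocorrelogram (Pearson correlation per spatial lag) is masked
    to an annulus (outer circle diameter = map edge, inner area 15% of
    the outer) and correlated with its rotations; the score is the mean
    correlation at 60/120 degrees minus the mean at 30/90/150 degrees.
    Positive values indicate hexagonal structure, negative values square
    or stripe structure.  ``pad_cm`` optionally ramp-pads the map to zero
    before autocorrelating (useful for maps with fields cut off at the
    arena wall); the per-lag normalization makes it unnecessary for
    well-covered maps.
    """
    m = np.asarray(rmap.rates, dtype=float)
    if m.shape[0] < 5 or m.shape[1] < 5:
        raise ValueError("rate map too small for gridness")
    if np.allclose(m, m.flat[0]):
        logger.warning("constant rate map: gridness undefined, returning nan")
        return float("nan")
    if pad_cm > 0:
        pad = int(round(pad_cm / rmap.bin_cm))
        m = np.pad(m, pad, mode="linear_ramp", end_values=0.0)
    ac = _pearson_autocorrelogram(m)
    ann = _annulus_mask(ac.shape)
    masked = np.where(ann, ac, 0.0)

    def corr_at(angle: float) -> float:
        rot = ndimage.rotate(masked, angle, reshape=False, order=1)
        a, b = masked[ann], rot[ann]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    peaks = np.mean([corr_at(60.0), corr_at(120.0)])
    valleys = np.mean([corr_at(30.0), corr_at(90.0), corr_at(150.0)])
    return float(peaks - valleys)


def filter_dataset(
    data: LabeledDataset,
    speed_range: tuple[float, float] = (5.0, 45.0),
    gridness_min: float = 0.1,
    cell_gridness: np.ndarray | None = None,
) -> LabeledDataset:
    """Drop out-of-range speeds (closed-open ``[lo, hi)``) and, when
    per-cell gridness scores are supplied, low-gridness cells."""
    speed = data.label("speed")
    rows = (speed >= speed_range[0]) & (speed < speed_range[1])
    states = data.states[rows]
    keep_cells = np.ones(data.n_neurons, dtype=bool)
    if cell_gridness is not None:
        keep_cells = np.asarray(cell_gridness, dtype=float) >= gridness_min
        if not np.any(keep_cells):
            raise ValueError("all cells fall below the gridness threshold")
        states = states[:, keep_cells]
    prov = dict(data.provenance)
    prov["speed_range"] = list(speed_range)
    prov["n_cells_dropped"] = int(np.sum(~keep_cells))
    return LabeledDataset(
        states=states,
        labels=data.labels[rows],
        label_meta=data.label_meta,
        provenance=prov,
    )


@dataclass
class SampledDatasetSet:
    """Speed-balanced resamples of a parent dataset (index lists)."""

    parent: LabeledDataset
    index_lists: list  # B arrays of row indices
    bin_edges: np.ndarray
    K: int
    shuffled: bool = False

    @property
    def B(self) -> int:
        return len(self.index_lists)

    def dataset(self, s: int) -> LabeledDataset:
        return self.parent.subset(self.index_lists[s])


def balanced_resample(
    data: LabeledDataset,
    speed_bin: float = 5.0,
    speed_range: tuple[float, float] = (5.0, 45.0),
    B: int = 50,
    cap: int = 10_000,
    seed: int = 0,
    shuffle: bool = False,
) -> SampledDatasetSet:
    """Draw ``B`` replicate datasets with equal counts per speed bin.

    ``K = min(smallest bin count, cap)`` rows are sampled without
    replacement from every speed bin for each replicate.  With
    ``shuffle=True`` the label rows are first permuted relative to the
    states (label-timestamp permutation), destroying the state-label
    relationship while preserving both marginals.
    """
    rng = np.random.default_rng(seed)
    parent = data
    if shuffle:
        perm = rng.permutation(data.n_points)
        parent = LabeledDataset(
            states=data.states,
            labels=data.labels[perm],
            label_meta=data.label_meta,
            provenance={**data.provenance, "label_shuffled": True},
        )
    speed = parent.label("speed")
    edges = np.arange(speed_range[0], speed_range[1] + 1e-9, speed_bin)
    bin_rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows = np.nonzero((speed >= lo) & (speed < hi))[0]
        if len(rows) == 0:
            raise ValueError(f"empty speed bin [{lo}, {hi})")
        bin_rows.append(rows)
    K = min(min(len(r) for r in bin_rows), cap)
    index_lists = []
    for _ in range(B):
        picks = [rng.choice(rows, size=K, replace=False) for rows in bin_rows]
        index_lists.append(np.concatenate(picks))
    return SampledDatasetSet(
        parent=parent,
        index_lists=index_lists,
        bin_edges=edges,
        K=K,
        shuffled=shuffle,
    )


def normality_scan(
    data: LabeledDataset,
    n_cubes: int = 300,
    cube_edges: tuple[float, ...] = (10.0, 10.0, 10.0),
    n_pcs: int = 20,
    alpha: float = 0.05,
    min_points: int = 20,
    seed: int = 0,
) -> dict:
    """Fraction of label-space cubes whose states reject normality.

    Cube centers are sampled uniformly over the label range; states in
    each cube are projected onto their first ``n_pcs`` principal
    components, one random component is tested (Shapiro-Wilk), and cubes
    with fewer than ``min_points`` states are skipped and counted
    separately.
    """
    rng = np.random.default_rng(seed)
    X = data.labels
    lo, hi = X.min(axis=0), X.max(axis=0)
    half = 0.5 * np.asarray(cube_edges, dtype=float)
    n_reject = 0
    n_tested = 0
    n_skipped = 0
    for _ in range(n_cubes):
        c = rng.uniform(lo, hi)
        inside = np.all(np.abs(X - c[None, :]) <= half[None, :], axis=1)
        pts = data.states[inside]
        if len(pts) < min_points:
            n_skipped += 1
            continue
        k = min(n_pcs, pts.shape[1], len(pts) - 1)
        Z = PCA(n_components=k, random_state=int(rng.integers(2**31 - 1))).fit_transform(
            pts
        )
        col = int(rng.integers(k))
        _, p = shapiro(Z[:, col])
        n_tested += 1
        if p < alpha:
            n_reject += 1
    return {
        "fraction_non_normal": n_reject / n_tested if n_tested else float("nan"),
        "n_tested": n_tested,
        "n_skipped": n_skipped,
        "alpha": alpha,
    }
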