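import numpy as np
import pytest

from neurogeom.dataset import LabeledDataset, spatial_meta
from neurogeom.preprocess import (
    RateMap,
    SpikeRecording,
    balanced_resample,
    filter_dataset,
    gridness,
    normality_scan,
    rate_map,
    spikes_to_dataset,
)
from neurogeom.synthdata import IPSGSpec


def _walk_recording(duration=100.0, rate=10.0, seed=0):
    rng = np.random.default_rng(seed)
    n_spk = rng.poisson(rate * duration)
    spikes = np.sort(rng.uniform(0, duration, n_spk))
    t = np.arange(0, duration + 0.1, 0.1)
    pos = np.cumsum(rng.normal(0, 1.0, (len(t), 2)), axis=0) % 150
    return SpikeRecording([spikes], t, pos)


class TestSpikesToDataset:
    def test_homogeneous_poisson_rate_recovered(self):
        rec = _walk_recording(duration=100.0, rate=10.0)
        ds = spikes_to_dataset(rec)
        assert abs(ds.states[:, 0].mean() - 10.0) / 10.0 < 0.05

    def test_no_spikes_all_zero(self):
        rec = _walk_recording()
        rec = SpikeRecording([np.array([])], rec.pos_times, rec.positions)
        ds = spikes_to_dataset(rec)
        assert np.all(ds.states == 0)

    def test_stationary_animal_speed_zero(self):
        t = np.arange(0, 10.1, 0.1)
        pos = np.full((len(t), 2), 75.0)
        rec = SpikeRecording([np.array([1.0, 2.0])], t, pos)
        ds = spikes_to_dataset(rec)
        assert np.allclose(ds.label("speed"), 0.0)

    def test_constant_velocity_speed(self):
        t = np.arange(0, 10.1, 0.1)
        pos = np.column_stack([3.0 * t, 4.0 * t])  # |v| = 5 cm/s
        rec = SpikeRecording([np.array([1.0])], t, pos)
        ds = spikes_to_dataset(rec)
        interior = ds.label("speed")[5:-5]
        assert np.allclose(interior, 5.0, atol=1e-6)


class TestRateMap:
    def test_uniform_rate_full_coverage_is_flat(self):
        rng = np.random.default_rng(0)
        T = 40_000
        labels = np.column_stack(
            [rng.uniform(0, 150, T), rng.uniform(0, 150, T), rng.uniform(5, 45, T)]
        )
        states = np.full((T, 1), 7.0)
        ds = LabeledDataset(states, labels, spatial_meta())
        rm = rate_map(ds, 0, arena=(150.0, 150.0))
        assert rm.rates.shape == (50, 50)
        assert np.allclose(rm.rates, 7.0, atol=1e-6)

    def test_mask_correction_unbiased_in_visited_half(self):
        rng = np.random.default_rng(1)
        T = 30_000
        # animal never visits x > 75; true rate constant
        labels = np.column_stack(
            [rng.uniform(0, 75, T), rng.uniform(0, 150, T), rng.uniform(5, 45, T)]
        )
        ds = LabeledDataset(np.full((T, 1), 4.0), labels, spatial_meta())
        rm = rate_map(ds, 0, arena=(150.0, 150.0))
        from scipy import ndimage

        # naive smoothing of the zero-filled map decays near the coverage edge
        counts, _, _ = np.histogram2d(
            labels[:, 0], labels[:, 1], bins=(np.arange(0, 153, 3),) * 2
        )
        naive = ndimage.gaussian_filter(
            np.where(counts > 0, 4.0, 0.0), sigma=8.25 / 3
        )
        edge_band = slice(20, 25)  # just inside x = 75 cm
        assert np.all(np.abs(rm.rates[edge_band, 10:40] - 4.0) < 0.05)
        assert naive[edge_band, 10:40].mean() < 3.9  # naive map is biased there

    def test_empty_dataset_rejected(self):
        ds = LabeledDataset(
            np.ones((5, 1)),
            np.column_stack([np.full(5, -10.0), np.full(5, -10.0), np.ones(5)]),
            spatial_meta(),
        )
        with pytest.raises(ValueError):
            rate_map(ds, 0, arena=(150.0, 150.0), origin=(0.0, 0.0))


def _map_from_field(field_fn, n=50, bin_cm=3.0):
    xs = (np.arange(n) + 0.5) * bin_cm
    XX, YY = np.meshgrid(xs, xs, indexing="ij")
    return RateMap(rates=field_fn(XX, YY), bin_cm=bin_cm, mask=np.ones((n, n)))


class TestGridness:
    def test_hexagonal_field_scores_high(self):
        spec = IPSGSpec(n_cells=1, rng_seed=0, spatial_period=50.0)
        def field(X, Y):
            m = spec.rate_map(np.column_stack([X.ravel(), Y.ravel()]))[:, 0]
            m = m.reshape(X.shape)
            return m - m.min()  # rate-map-like: near-zero background

        rm = _map_from_field(field)
        assert gridness(rm) > 0.5

    def test_square_lattice_scores_negative(self):
        L = 50.0
        rm = _map_from_field(
            lambda X, Y: np.cos(2 * np.pi * X / L) + np.cos(2 * np.pi * Y / L) + 2
        )
        assert gridness(rm) < 0

    def test_radial_blob_scores_near_zero(self):
        rm = _map_from_field(
            lambda X, Y: np.exp(-((X - 75) ** 2 + (Y - 75) ** 2) / (2 * 30**2))
        )
        assert abs(gridness(rm)) < 0.3

    def test_hexagonal_beats_square(self):
        spec = IPSGSpec(n_cells=1, rng_seed=0, spatial_period=50.0)
        def field(X, Y):
            m = spec.rate_map(np.column_stack([X.ravel(), Y.ravel()]))[:, 0]
            m = m.reshape(X.shape)
            return m - m.min()

        hex_rm = _map_from_field(field)
        sq_rm = _map_from_field(
            lambda X, Y: np.cos(2 * np.pi * X / 50) + np.cos(2 * np.pi * Y / 50) + 2
        )
        assert gridness(hex_rm) > gridness(sq_rm)

    def test_constant_map_flagged(self):
        rm = _map_from_field(lambda X, Y: np.ones_like(X))
        assert np.isnan(gridness(rm))


class TestFilterAndResample:
    def _ds(self, T=2000, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.column_stack(
            [rng.uniform(0, 150, T), rng.uniform(0, 150, T), rng.uniform(0, 50, T)]
        )
        return LabeledDataset(rng.poisson(5, (T, 6)).astype(float), labels, spatial_meta())

    def test_speed_boundaries_closed_open(self):
        ds = self._ds()
        ds.labels[0, 2] = 4.9
        ds.labels[1, 2] = 5.0
        ds.labels[2, 2] = 45.0
        out = filter_dataset(ds)
        assert not np.any(np.isclose(out.label("speed"), 4.9))
        assert np.any(out.label("speed") == 5.0)
        assert not np.any(out.label("speed") == 45.0)

    def test_low_gridness_cells_dropped(self):
        ds = self._ds()
        g = np.array([0.5, 0.05, 0.3, 0.09, 0.8, 0.1])
        out = filter_dataset(ds, cell_gridness=g)
        assert out.n_neurons == 4  # 0.05 and 0.09 removed; 0.1 retained

    def test_in_range_identity(self):
        ds = self._ds()
        rows = (ds.label("speed") >= 5) & (ds.label("speed") < 45)
        out = filter_dataset(ds)
        assert np.array_equal(out.states, ds.states[rows])

    def test_balanced_counts_and_no_duplicates(self):
        ds = self._ds(T=5000, seed=1)
        sset = balanced_resample(ds, B=5, seed=0)
        speeds = sset.parent.label("speed")
        for s in range(5):
            idx = sset.index_lists[s]
            assert len(np.unique(idx)) == len(idx)
            counts = [
                np.sum(
                    (speeds[idx] >= lo) & (speeds[idx] < lo + 5.0)
                )
                for lo in np.arange(5.0, 45.0, 5.0)
            ]
            assert len(set(counts)) == 1 and counts[0] == sset.K
        assert len(sset.index_lists[0]) == 8 * sset.K

    def test_cap_rule(self):
        ds = self._ds(T=4000, seed=2)
        assert balanced_resample(ds, B=1, cap=10, seed=0).K == 10
        big = balanced_resample(ds, B=1, cap=10_000, seed=0)
        speeds = ds.label("speed")
        min_bin = min(
            np.sum((speeds >= lo) & (speeds < lo + 5)) for lo in np.arange(5, 45, 5)
        )
        assert big.K == min_bin

    def test_empty_bin_raises(self):
        ds = self._ds(T=300, seed=3)
        ds.labels[:, 2] = np.clip(ds.labels[:, 2], 12.0, None)  # empty [5,10)
        with pytest.raises(ValueError, match=r"\[5"):
            balanced_resample(ds, B=1, seed=0)

    def test_shuffle_permutes_labels_not_states(self):
        ds = self._ds(T=3000, seed=4)
        sset = balanced_resample(ds, B=1, seed=0, shuffle=True)
        assert np.array_equal(sset.parent.states, ds.states)
        assert not np.array_equal(sset.parent.labels, ds.labels)
        assert np.array_equal(
            np.sort(sset.parent.labels[:, 2]), np.sort(ds.labels[:, 2])
        )


class TestNormalityScan:
    def _labels(self, T, rng):
        return np.column_stack(
            [rng.uniform(0, 100, T), rng.uniform(0, 100, T), rng.uniform(5, 45, T)]
        )

    def test_gaussian_data_calibrated(self):
        rng = np.random.default_rng(0)
        T = 6000
        states = rng.standard_normal((T, 8))
        ds = LabeledDataset(states, self._labels(T, rng), spatial_meta())
        out = normality_scan(ds, n_cubes=120, cube_edges=(20, 20, 10), seed=1)
        assert out["n_tested"] > 50
        # type-I rate near alpha, within a generous binomial band
        assert out["fraction_non_normal"] < 0.15

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(2)
        T = 6000
        states = rng.standard_t(df=2, size=(T, 8))
        ds = LabeledDataset(states, self._labels(T, rng), spatial_meta())
        out = normality_scan(ds, n_cubes=120, cube_edges=(20, 20, 10), seed=3)
        assert out["fraction_non_normal"] > 0.3

    def test_zero_cubes_is_empty_result(self):
        rng = np.random.default_rng(4)
        ds = LabeledDataset(
            rng.standard_normal((100, 3)), self._labels(100, rng), spatial_meta()
        )
        out = normality_scan(ds, n_cubes=0)
        assert out["n_tested"] == 0 and np.isnan(out["fraction_non_normal"])


class TestRecordingIO:
    def test_npz_roundtrip(self, tmp_path):
        rec = _walk_recording(duration=20.0, rate=5.0, seed=9)
        rec2 = SpikeRecording(
            rec.spike_times + [np.array([0.5, 1.5])], rec.pos_times, rec.positions
        )
        p = tmp_path / "rec.npz"
        rec2.save(p)
        back = SpikeRecording.load(p)
        assert len(back.spike_times) == 2
        for a, b in zip(back.spike_times, rec2.spike_times):
            assert np.array_equal(a, b)
        assert np.array_equal(back.positions, rec2.positions)
        ds_a = spikes_to_dataset(rec2)
        ds_b = spikes_to_dataset(back)
        assert np.array_equal(ds_a.states, ds_b.states)
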