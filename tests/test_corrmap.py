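import numpy as np
import pytest

from ca3net.corrmap import (DegenerateTrainError, EmptyMapError,
                            accumulate_map, cross_section, estimate_cluster_sd,
                            local_map, normalized_xcorr, peak_correlation)
from ca3net.geometry import SectionGrid
from ca3net.sources import SpikeRaster


def brute_force_xcorr(x, y, max_lag):
    """Direct O(N^2) evaluation of the overlap-normalized formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my, sx, sy = x.mean(), y.mean(), x.std(), y.std()
    out = np.empty(2 * max_lag + 1)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        total = 0.0
        L = 0
        for m in range(n):
            k = m + lag
            if 0 <= k < n:
                total += (x[m] - mx) * (y[k] - my)
                L += 1
        out[i] = total / (sx * sy * L) if L >= 2 else np.nan
    return out


class TestNormalizedXcorr:
    def test_matches_brute_force_on_random_pairs(self, rng):
        """FFT implementation agrees with the direct evaluation of the
        printed formula to 1e-12 on 100 random binary train pairs."""
        for _ in range(100):
            n = int(rng.integers(20, 120))
            x = (rng.random(n) < 0.2).astype(float)
            y = (rng.random(n) < 0.2).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            max_lag = int(rng.integers(1, n - 1))
            got = normalized_xcorr(x, y, max_lag).values
            want = brute_force_xcorr(x, y, max_lag)
            np.testing.assert_allclose(got, want, atol=1e-12, equal_nan=True)

    def test_autocorrelation_unity_at_zero_lag(self, rng):
        x = (rng.random(500) < 0.1).astype(float)
        r = normalized_xcorr(x, x, 10)
        assert r.values[r.lags == 0][0] == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_example(self):
        r = normalized_xcorr(np.array([1, 0, 0, 0], float),
                             np.array([0, 1, 0, 0], float), 2)
        assert r.values[r.lags == 1][0] == pytest.approx(11.0 / 9.0, rel=1e-12)

    def test_constant_train_rejected(self):
        with pytest.raises(DegenerateTrainError):
            normalized_xcorr(np.zeros(50), np.ones(50), 5)

    def test_shift_theorem(self, rng):
        """Delaying y by k bins moves the correlation peak by exactly k."""
        x = (rng.random(400) < 0.15).astype(float)
        k = 7
        y = np.roll(x, k)
        r = normalized_xcorr(x, y, 20)
        assert r.lags[np.nanargmax(r.values)] == k

    def test_antisymmetry_of_arguments(self, rng):
        x = (rng.random(100) < 0.3).astype(float)
        y = (rng.random(100) < 0.3).astype(float)
        rxy = normalized_xcorr(x, y, 9).values
        ryx = normalized_xcorr(y, x, 9).values
        np.testing.assert_allclose(rxy, ryx[::-1], atol=1e-12)


def _coincident_pair_raster():
    times = np.arange(10.5, 4000, 50.0)
    trains = [times.copy(), times.copy()]
    positions = np.array([[1.0, 0.5], [1.25, 0.5]])
    return SpikeRaster(trains, 4000.0), positions


class TestAccumulateMap:
    def test_single_pair_coincident(self):
        raster, pos = _coincident_pair_raster()
        cmap = accumulate_map(raster, pos, max_lag_ms=20.0)
        # displacement +0.25 mm -> bin floor(2.5)=2; reverse -> floor(-2.5)=-3
        i_fwd = cmap.long_offset + 2
        i_rev = cmap.long_offset - 3
        j0 = cmap.trans_offset
        t0 = cmap.max_lag
        assert cmap.values[i_fwd, j0, t0] == pytest.approx(1.0, rel=1e-9)
        assert cmap.values[i_rev, j0, t0] == pytest.approx(1.0, rel=1e-9)
        assert cmap.n_pairs == 2

    def test_point_symmetry(self, rng):
        n = 12
        trains = [np.sort(rng.uniform(0, 2000, 15)) for _ in range(n)]
        pos = np.column_stack([rng.uniform(0, 8, n), rng.uniform(0, 2, n)])
        raster = SpikeRaster(trains, 2000.0)
        cmap = accumulate_map(raster, pos, max_lag_ms=15.0)
        d = pos[1] - pos[0]
        res = cmap.spatial_res_mm
        bl_f = int(np.floor(d[0] / res)) + cmap.long_offset
        bt_f = int(np.floor(d[1] / res)) + cmap.trans_offset
        bl_r = int(np.floor(-d[0] / res)) + cmap.long_offset
        bt_r = int(np.floor(-d[1] / res)) + cmap.trans_offset
        np.testing.assert_allclose(cmap.values[bl_f, bt_f, :],
                                   cmap.values[bl_r, bt_r, ::-1],
                                   atol=1e-12, equal_nan=True)

    def test_silent_neurons_dropped(self, rng):
        trains = [np.sort(rng.uniform(0, 1000, 10)), np.array([]),
                  np.sort(rng.uniform(0, 1000, 10))]
        pos = np.array([[1.0, 0.5], [2.0, 0.5], [3.0, 0.5]])
        cmap = accumulate_map(SpikeRaster(trains, 1000.0), pos, max_lag_ms=5.0)
        assert cmap.n_silent == 1
        assert cmap.n_pairs == 2  # one unordered pair, both orders

    def test_all_silent_raises(self):
        trains = [np.array([]), np.array([])]
        pos = np.zeros((2, 2))
        with pytest.raises(EmptyMapError):
            accumulate_map(SpikeRaster(trains, 1000.0), pos, max_lag_ms=5.0)

    def test_independent_trains_below_noise_bound(self):
        """Null calibration: independent renewal trains give map values
        within the analytic noise bound ~4/sqrt(pairs x bins)."""
        from ca3net.sources import RenewalParams, generate_population_trains

        n = 100
        duration = 5000.0
        trains = generate_population_trains(n, RenewalParams(5.0), duration, 9)
        rng = np.random.default_rng(1)
        # compact sheet so every spatial bin accumulates many pairs and
        # the Gaussian noise bound applies
        pos = np.column_stack([rng.uniform(0, 1, n), rng.uniform(0, 0.5, n)])
        raster = SpikeRaster(trains, duration)
        cmap = accumulate_map(raster, pos, max_lag_ms=30.0)
        finite = np.isfinite(cmap.values)
        counts = np.broadcast_to(cmap.counts[:, :, None], cmap.values.shape)
        ok = finite & (counts >= 20)
        assert ok.sum() > 1000
        bound = 4.0 / np.sqrt(counts[ok] * (duration - 30.0))
        ratio = np.abs(cmap.values[ok]) / bound
        # 4 sigma bound at alpha ~ 1e-4: allow the nominal false-positive
        # rate over ~1e4 bins, but nothing far outside it
        assert (ratio > 1).mean() < 1e-3
        assert ratio.max() < 1.3


class TestLocalMap:
    def _setup(self, rng):
        n = 30
        pos = np.column_stack([rng.uniform(0, 10, n), rng.uniform(0, 3, n)])
        trains = [np.sort(rng.uniform(0, 2000, 20)) for _ in range(n)]
        return SpikeRaster(trains, 2000.0), pos, SectionGrid()

    def test_requires_one_member_in_section(self, rng):
        raster, pos, grid = self._setup(rng)
        in_sec = (grid.row_mask_array(pos[:, 0])[:, 0]
                  & (grid.column_index_array(pos[:, 1]) == 0))
        if in_sec.sum() == 0:
            pytest.skip("no neuron landed in the section for this seed")
        lm = local_map(raster, pos, grid, "septal", "CA3c", max_lag_ms=10.0)
        n_in = in_sec.sum()
        n_out = (~in_sec).sum()
        expected_unordered = n_in * (n_in - 1) // 2 + n_in * n_out
        assert lm.n_pairs == 2 * expected_unordered

    def test_pair_in_two_sections_counts_in_both(self):
        # one neuron per section, pair spans both sections
        pos = np.array([[8.0, 0.5], [8.0, 2.5]])  # septal CA3c, septal CA3a
        times = np.arange(5.5, 900, 40.0)
        raster = SpikeRaster([times, times + 1.0], 1000.0)
        grid = SectionGrid()
        for col in ("CA3c", "CA3a"):
            lm = local_map(raster, pos, grid, "septal", col, max_lag_ms=10.0)
            assert lm.n_pairs == 2

    def test_unknown_section_rejected(self, rng):
        raster, pos, grid = self._setup(rng)
        with pytest.raises(ValueError):
            local_map(raster, pos, grid, "apex", "CA3c")


class TestCrossSectionAndPeak:
    def test_threshold_keeps_only_large_bins(self):
        raster, pos = _coincident_pair_raster()
        cmap = accumulate_map(raster, pos, max_lag_ms=20.0)
        sl, _ = cross_section(cmap, "longitudinal-temporal", at=0.0,
                              threshold=0.30)
        m = np.nanmax(np.abs(sl))
        nz = sl[np.nonzero(np.nan_to_num(sl))]
        assert np.all(np.abs(nz) >= 0.30 * m)

    def test_slice_commutes_with_symmetry(self, rng):
        n = 10
        trains = [np.sort(rng.uniform(0, 1500, 12)) for _ in range(n)]
        pos = np.column_stack([rng.uniform(0, 5, n), rng.uniform(0, 2, n)])
        cmap = accumulate_map(SpikeRaster(trains, 1500.0), pos, max_lag_ms=8.0)
        sl, _ = cross_section(cmap, "longitudinal-transverse", at=0.0)
        np.testing.assert_allclose(sl, cmap.values[:, :, cmap.max_lag],
                                   equal_nan=True)

    def test_out_of_range_slice(self):
        raster, pos = _coincident_pair_raster()
        cmap = accumulate_map(raster, pos, max_lag_ms=10.0)
        with pytest.raises(IndexError):
            cross_section(cmap, "longitudinal-temporal", at=99.0)

    def test_peak_of_coincident_pair_is_one(self):
        raster, pos = _coincident_pair_raster()
        cmap = accumulate_map(raster, pos, max_lag_ms=10.0)
        assert peak_correlation(cmap) == pytest.approx(1.0, rel=1e-9)


class TestClusterRecovery:
    def test_planted_sd_recovered_within_20pct(self):
        """Planted Gaussian co-activation of sd 0.5 mm is recovered from
        the global map's spatial half-width within 20%."""
        from ca3net.fixtures import ClusterFixtureSpec, make_cluster_raster
        from ca3net.geometry import PopulationConfig, SheetExtent, build_layout

        layout = build_layout(
            PopulationConfig(sizes={"EC": 0, "DG": 800, "CA3": 0}), seed=21)
        spec = ClusterFixtureSpec(n_clusters=3, spatial_sd_mm=0.5,
                                  jitter_sd_ms=2.0, participation=0.6,
                                  background_rate_hz=0.3, events_hz=3.0,
                                  duration_ms=5000.0, seed=21)
        raster, events = make_cluster_raster(spec, layout.positions("DG"),
                                             layout.config.extents["DG"])
        assert len(events) > 0
        cmap = accumulate_map(raster, layout.positions("DG"),
                              max_lag_ms=25.0, max_pairs=40000, seed=0)
        est = estimate_cluster_sd(cmap)
        assert est == pytest.approx(0.5, rel=0.20)
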