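import numpy as np
import pytest

from ca3net.connectivity import Connectome, PathwayEdges
from ca3net.fixtures import make_toy_network
from ca3net.neuron import PRESETS
from ca3net.simulate import (ClassificationError, PathwayScale, SimConfig,
                             SingleCell, adaptation_index,
                             calibrated_kinetics, classify_firing_type,
                             firing_response, reference_cell, scale_weights,
                             simulate_network)
from ca3net.sources import SpikeRaster
from ca3net.synapses import EPSP_TARGETS, measure_epsp


class TestClassifyFiringType:
    def test_constant_isi_is_weakly_adapting(self):
        t = np.arange(0, 500, 50.0)
        assert adaptation_index(t) == 0.0
        assert classify_firing_type(t) == "weakly adapting"

    def test_geometric_isis_strongly_adapting(self):
        t = np.concatenate([[0.0], np.cumsum([20.0, 40.0, 80.0, 160.0])])
        assert adaptation_index(t) == pytest.approx(140.0 / 180.0)
        assert classify_firing_type(t) == "strongly adapting"

    def test_onset_burst_detected(self):
        t = np.array([0.0, 4.0, 9.0, 100.0, 200.0])
        assert classify_firing_type(t) == "bursting"

    def test_too_few_spikes(self):
        with pytest.raises(ClassificationError):
            classify_firing_type(np.array([10.0]))

    @pytest.mark.parametrize("preset, expected", [
        ("bursting", "bursting"),
        ("strongly_adapting", "strongly adapting"),
        ("weakly_adapting", "weakly adapting"),
    ])
    def test_shipped_presets_classify_correctly(self, preset, expected):
        times = firing_response(preset)
        assert classify_firing_type(times) == expected


class TestSingleCellEpsp:
    def test_unitary_pp_epsp_subthreshold(self):
        """A single calibrated lacunosum synapse yields the 0.30 mV target
        at the soma and no output spike."""
        kin = calibrated_kinetics("ca3")
        cal = kin.calibrations["lacunosum_distal"]
        cell = reference_cell()
        trace = cell.epsp_trace("lacunosum_distal", cal.ampa, cal.nmda)
        m = measure_epsp(trace)
        assert m.peak_mV == pytest.approx(0.30, rel=0.02)
        assert trace.v_mV.max() < -40.0  # far below spike threshold

    def test_unitary_mf_epsp_is_3_2_mV(self):
        kin = calibrated_kinetics("ca3")
        cal = kin.calibrations["lucidum"]
        m = measure_epsp(reference_cell().epsp_trace("lucidum", cal.ampa,
                                                     cal.nmda))
        assert m.peak_mV == pytest.approx(3.2, rel=0.02)
        assert m.hhw_ms == pytest.approx(135.0, rel=0.02)


def _single_edge_net(delay_ms=2.0, weight=1.0):
    edges = {"MF": PathwayEdges(
        "DG", np.array([0], dtype=np.int32), np.array([0], dtype=np.int32),
        np.array([4], dtype=np.int8), np.array([delay_ms], dtype=np.float32),
        np.array([weight], dtype=np.float32))}
    return Connectome(edges, 0, "test")


class TestSimulateNetwork:
    kin = calibrated_kinetics("ca3")

    def test_empty_connectome_silent(self):
        conn = Connectome({}, 0, "empty")
        raster = simulate_network(conn, {}, PRESETS["weakly_adapting"](),
                                  self.kin, SimConfig(duration_ms=200.0), 3)
        assert raster.spike_counts().sum() == 0

    def test_single_mf_edge_epsp_no_spike(self):
        """One unitary mossy-fiber spike depolarizes but does not fire the
        cell (unreliable detonation at low frequency)."""
        conn = _single_edge_net()
        src = SpikeRaster([np.array([50.0])], 500.0, population="DG")
        cfg = SimConfig(duration_ms=500.0, record_cell=0)
        raster = simulate_network(conn, {"DG": src},
                                  PRESETS["weakly_adapting"](), self.kin,
                                  cfg, 1)
        assert raster.spike_counts().sum() == 0

    def test_low_rate_mf_drive_rarely_spikes(self):
        conn = _single_edge_net()
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 3000, 3))  # ~1 Hz
        src = SpikeRaster([times], 3000.0, population="DG")
        raster = simulate_network(conn, {"DG": src},
                                  PRESETS["weakly_adapting"](), self.kin,
                                  SimConfig(duration_ms=3000.0), 1)
        assert raster.spike_counts().sum() <= 1

    def test_determinism_bit_exact(self):
        layout, conn = make_toy_network(5, 5, "MF", "fan", seed=4)
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(0, 800, 6)) for _ in range(5)]
        src = SpikeRaster(trains, 800.0, population="DG")
        cfg = SimConfig(duration_ms=800.0)
        args = (conn, {"DG": src}, PRESETS["weakly_adapting"](), self.kin,
                cfg, 5)
        a = simulate_network(*args, scale=PathwayScale(MF=4.0))
        b = simulate_network(*args, scale=PathwayScale(MF=4.0))
        for x, y in zip(a.trains, b.trains):
            np.testing.assert_array_equal(x, y)

    def test_scale_zero_equals_pathway_removed(self):
        layout, conn = make_toy_network(4, 4, "MF", "fan", seed=2)
        rng = np.random.default_rng(1)
        src = SpikeRaster([np.sort(rng.uniform(0, 500, 5)) for _ in range(4)],
                          500.0, population="DG")
        cfg = SimConfig(duration_ms=500.0)
        silenced = simulate_network(conn, {"DG": src},
                                    PRESETS["weakly_adapting"](), self.kin,
                                    cfg, 4, scale=PathwayScale(MF=0.0))
        removed = simulate_network(Connectome({}, 0, "x"), {},
                                   PRESETS["weakly_adapting"](), self.kin,
                                   cfg, 4)
        assert silenced.spike_counts().sum() == removed.spike_counts().sum() == 0

    def test_scale_weights_identity_and_multiplication(self):
        _, conn = make_toy_network(3, 3, "MF", "single_edge", seed=1)
        same = scale_weights(conn, "MF", 1.0)
        np.testing.assert_array_equal(same.edges["MF"].weight,
                                      conn.edges["MF"].weight)
        five = scale_weights(conn, "MF", 5.0)
        np.testing.assert_allclose(five.edges["MF"].weight, 5.0)

    def test_dt_convergence(self):
        """Halving the step changes stimulus-locked spike times by < 0.5 ms.

        Only the early, input-locked spikes are compared: in a tonic
        regime the phase of later spikes drifts cumulatively and is not
        a meaningful convergence measure.
        """
        conn = _single_edge_net(weight=4.0)
        src = SpikeRaster([np.array([20.0, 120.0])], 400.0, population="DG")
        times = {}
        for dt in (0.025, 0.0125):
            cfg = SimConfig(dt_ms=dt, duration_ms=400.0)
            raster = simulate_network(conn, {"DG": src},
                                      PRESETS["weakly_adapting"](), self.kin,
                                      cfg, 1)
            times[dt] = raster.trains[0]
        assert min(len(times[0.025]), len(times[0.0125])) >= 4
        assert np.all(np.abs(times[0.025][:4] - times[0.0125][:4]) < 0.5)

    def test_shared_input_fan_produces_zero_lag_correlation(self):
        """Two cells sharing one presynaptic source correlate at lag 0."""
        from ca3net.corrmap import normalized_xcorr
        from ca3net.sources import RenewalParams, bin_spikes, \
            generate_renewal_train

        _, conn = make_toy_network(1, 2, "MF", "fan", seed=6)
        train = generate_renewal_train(RenewalParams(8.0), 10_000.0,
                                       np.random.default_rng(2))
        src = SpikeRaster([train], 10_000.0, population="DG")
        raster = simulate_network(conn, {"DG": src},
                                  PRESETS["weakly_adapting"](), self.kin,
                                  SimConfig(duration_ms=10_000.0), 2,
                                  scale=PathwayScale(MF=12.0))
        binned = bin_spikes(raster)
        assert np.all(binned.sigma > 0)
        r = normalized_xcorr(binned.x[0].astype(float),
                             binned.x[1].astype(float), 20)
        center = r.values[np.abs(r.lags) <= 3].max()
        far = np.nanmax(np.abs(r.values[np.abs(r.lags) >= 15]))
        assert center > 0.05
        assert center > far
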