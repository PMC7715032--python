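import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.stats import chisquare, skewnorm

from ca3net.connectivity import (ConfigurationError, ConnectivityConfig,
                                 GenerationError, MF_REGION_MEANS_UM,
                                 MossyFiberPath, SkewFieldParams,
                                 assoc_field_for, assoc_field_params_at,
                                 build_connectome, compute_delay,
                                 default_assoc_param_grid,
                                 default_mf_deviation_spline, mf_assign_post,
                                 mf_place_synapses, mf_trajectory,
                                 pp_field_for, sample_inputs_postsynaptic,
                                 skew_gaussian_density, synapse_budget)
from ca3net.geometry import (PopulationConfig, SheetExtent, UnfoldedPosition,
                             build_layout)


class TestPPField:
    def test_extent_to_sd_rule(self):
        pos = UnfoldedPosition(5.0, 1.0, "EC")
        field = pp_field_for(pos, lambda y: y, extent_mm=1.25)
        assert field.sd == pytest.approx(0.3125)

    def test_topographic_monotonicity(self):
        topo = lambda y: y * 0.9 + 0.3
        centers = [pp_field_for(UnfoldedPosition(y, 1.0, "EC"), topo).center
                   for y in (1.0, 3.0, 5.0, 8.0)]
        assert np.all(np.diff(centers) > 0)

    def test_truncated_density_integrates_to_one(self):
        field = pp_field_for(UnfoldedPosition(0.5, 1.0, "EC"), lambda y: y,
                             ca3_longitudinal_extent=10.0)
        y = np.linspace(0, 10, 20001)
        mass = np.trapezoid(field.density(y), y)
        assert mass == pytest.approx(1.0, rel=1e-6)

    def test_non_ec_position_rejected(self):
        with pytest.raises(ConfigurationError):
            pp_field_for(UnfoldedPosition(5.0, 1.0, "CA3"), lambda y: y)


class TestSynapseBudget:
    @pytest.mark.parametrize("frac, layer, expected", [
        (1.0, "lacunosum_distal", 1658),
        (1.0, "lacunosum_proximal", 1105),
        (1.0, "radiatum", 11281),
        (1.0, "oriens", 17893),
        (0.0, "lacunosum_distal", 0),
        (0.0, "lacunosum_proximal", 0),
        (0.0, "radiatum", 11241),
        (0.0, "oriens", 7147),
    ])
    def test_extremes_match_layer_table(self, frac, layer, expected):
        assert getattr(synapse_budget(frac), layer) == expected

    def test_radiatum_from_density_times_length(self):
        # proximal radiatum count back-solves to a 3,114 um dendritic length
        b = synapse_budget(0.0, lengths={"lacunosum_distal": 0.0,
                                         "lacunosum_proximal": 0.0,
                                         "radiatum": 11241 / 3.61,
                                         "oriens": 7147 / 3.15})
        assert b.radiatum == 11241

    def test_out_of_range_fraction(self):
        with pytest.raises(ConfigurationError):
            synapse_budget(1.5)


class TestPostsynapticSampling:
    def test_zero_budget(self, rng):
        assert len(sample_inputs_postsynaptic(np.array([1.0, 2.0]), 0, rng)) == 0

    def test_multinomial_fractions(self):
        rng = np.random.default_rng(0)
        draws = sample_inputs_postsynaptic(np.array([0.75, 0.25]), 10_000, rng)
        frac = (draws == 0).mean()
        se = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(frac - 0.75) < 3 * se

    def test_all_zero_probabilities_rejected(self, rng):
        with pytest.raises(GenerationError):
            sample_inputs_postsynaptic(np.zeros(4), 5, rng)

    def test_zero_probability_candidates_never_drawn(self, rng):
        p = np.array([0.0, 1.0, 0.0, 2.0])
        draws = sample_inputs_postsynaptic(p, 5000, rng)
        assert set(np.unique(draws)) <= {1, 3}


class TestMossyFiberTrajectory:
    extent = SheetExtent(10.0, 3.0)

    def _origin(self, lon=5.0, blade="suprapyramidal"):
        return UnfoldedPosition(lon, 1.0, "DG", blade)

    def test_noiseless_path_deterministic(self):
        spline = default_mf_deviation_spline(3.0)
        a = mf_trajectory(self._origin(), spline, noise_sd=0.0, seed=1,
                          ca3_extent=self.extent)
        b = mf_trajectory(self._origin(), spline, noise_sd=0.0, seed=99,
                          ca3_extent=self.extent)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        x = a.vertices[:, 1]
        np.testing.assert_allclose(a.vertices[:, 0], 5.0 + spline(x))

    def test_distal_deviation_toward_temporal_pole(self):
        path = mf_trajectory(self._origin(), noise_sd=0.0, seed=0,
                             ca3_extent=self.extent)
        deviation = path.vertices[:, 0] - 5.0
        assert deviation[-1] < 0          # temporal = decreasing longitudinal
        third = path.vertices[:, 1] < 2.0
        assert np.all(np.abs(deviation[third]) < 0.15)

    def test_noisy_mean_matches_noiseless(self):
        spline = default_mf_deviation_spline(3.0)
        clean = mf_trajectory(self._origin(), spline, noise_sd=0.0, seed=0,
                              ca3_extent=self.extent)
        rng = np.random.default_rng(5)
        acc = np.zeros_like(clean.vertices[:, 0])
        n = 1000
        for _ in range(n):
            p = mf_trajectory(self._origin(), spline, noise_sd=0.05, seed=rng,
                              ca3_extent=self.extent)
            acc += p.vertices[:, 0]
        mean = acc / n
        se = 0.05 / np.sqrt(n)
        assert np.all(np.abs(mean - clean.vertices[:, 0]) < 4 * se)

    def test_arc_length_monotone(self):
        path = mf_trajectory(self._origin(), noise_sd=0.1, seed=3,
                             ca3_extent=self.extent)
        assert np.all(np.diff(path.arc) > 0)

    def test_non_dg_origin_rejected(self):
        with pytest.raises(ConfigurationError):
            mf_trajectory(UnfoldedPosition(5.0, 1.0, "CA3"))


class TestMossySynapsePlacement:
    def _straight_path(self, length_mm, trans=0.5):
        # a path confined to one region (constant transverse coordinate)
        n = 50
        lon = np.linspace(0, length_mm, n)
        vertices = np.column_stack([lon, np.full(n, trans)])
        arc = np.concatenate([[0], np.cumsum(np.hypot(np.diff(lon), 0))])
        return MossyFiberPath(0.0, "suprapyramidal", vertices, arc)

    def test_zero_length_path(self):
        path = MossyFiberPath(0.0, "suprapyramidal",
                              np.array([[0.0, 0.5]]), np.array([0.0]))
        assert len(mf_place_synapses(path, seed=0)) == 0

    def test_poisson_count_in_ca3c(self):
        """1.62 mm of CA3c fiber: synapse count is Poisson with mean 10."""
        path = self._straight_path(1.62, trans=0.5)
        counts = [len(mf_place_synapses(path, seed=i)) for i in range(1000)]
        mean = np.mean(counts)
        se = np.sqrt(10.0 / 1000)
        assert abs(mean - 10.0) < 3 * se
        # index of dispersion ~ 1 for a Poisson count
        assert 0.85 < np.var(counts) / mean < 1.15

    @pytest.mark.parametrize("trans, region", [(0.5, "CA3c"), (1.5, "CA3b"),
                                               (2.5, "CA3a")])
    def test_intersynapse_distances_recover_region_means(self, trans, region):
        path = self._straight_path(400.0, trans=trans)
        rng = np.random.default_rng(17)
        gaps = []
        for _ in range(5):
            s = mf_place_synapses(path, seed=rng)
            gaps.append(np.diff(s))
        gaps = np.concatenate(gaps) * 1000.0  # mm -> um
        assert gaps.mean() == pytest.approx(MF_REGION_MEANS_UM[region], rel=0.05)

    def test_nonpositive_mean_rejected(self):
        path = self._straight_path(1.0)
        with pytest.raises(ConfigurationError):
            mf_place_synapses(path, {"CA3c": 0.0, "CA3b": 223.0, "CA3a": 345.0})


class TestMossyAssignment:
    def test_no_cell_in_radius_dropped(self, rng):
        xy = np.array([[5.0, 1.5]])
        cells = np.array([[0.0, 0.0]])
        post, dropped = mf_assign_post(xy, cells, 0.03, rng)
        assert dropped == 1 and post[0] == -1

    def test_single_candidate_always_chosen(self, rng):
        xy = np.array([[5.0, 1.5]])
        cells = np.array([[5.01, 1.5], [9.0, 2.0]])
        post, dropped = mf_assign_post(xy, cells, 0.03, rng)
        assert dropped == 0 and post[0] == 0

    def test_uniform_among_candidates(self):
        rng = np.random.default_rng(2)
        xy = np.tile([[5.0, 1.5]], (6000, 1))
        cells = np.array([[5.005, 1.5], [4.995, 1.5], [5.0, 1.51]])
        post, _ = mf_assign_post(xy, cells, 0.03, rng)
        h = np.bincount(post, minlength=3)
        _, p = chisquare(h)
        assert p > 0.01

    def test_infrapyramidal_targets_proximal_oriens_in_ca3c(self):
        layout = build_layout(
            PopulationConfig(sizes={"EC": 0, "DG": 40, "CA3": 4000}), seed=5)
        conn = build_connectome(
            layout, ConnectivityConfig(pathways=("MF",),
                                       mf_capture_radius_mm=0.2), seed=5)
        e = conn.edges["MF"]
        blades = layout.blades("DG")
        pos = layout.positions("CA3")
        # classify by postsynaptic position with a margin wider than the
        # capture radius (the layer rule follows the synapse location)
        deep_ca3c = pos[e.post, 1] < 1.0 - 0.25
        deep_distal = pos[e.post, 1] > 1.0 + 0.25
        infra = blades[e.pre] == 1
        assert np.all(e.comp[infra & deep_ca3c] == 6)
        assert np.all(e.comp[~infra] == 4)
        assert np.all(e.comp[infra & deep_distal] == 4)


class TestSkewField:
    def test_zero_skew_reduces_to_gaussian(self):
        p = SkewFieldParams(0.0, 1.0, 0.0, 0.0, 2.0, 0.0)
        u = np.linspace(-3, 3, 50)
        got = skew_gaussian_density(u, 0.5, p)
        want = (np.exp(-u ** 2 / 2) / np.sqrt(2 * np.pi)
                * np.exp(-0.5 ** 2 / (2 * 4)) / (2 * np.sqrt(2 * np.pi)))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_positive_skew_shifts_mode_positive(self):
        p = SkewFieldParams(0.0, 1.0, 4.0, 0.0, 1.0, 0.0)
        u = np.linspace(-4, 4, 4001)
        mode = u[np.argmax(skew_gaussian_density(u, 0.0, p))]
        assert mode > 0

    def test_integrates_to_one(self):
        p = SkewFieldParams(0.5, 1.3, 2.0, -0.2, 0.8, -1.5)
        val, err = dblquad(
            lambda y, x: skew_gaussian_density(x, y, p),
            -15, 15, lambda _: -15, lambda _: 15, epsabs=1e-9)
        assert abs(val - 1.0) < 1e-6

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            SkewFieldParams(0.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class TestAssocGrid:
    grid = default_assoc_param_grid(SheetExtent(10.0, 3.0))

    def test_node_identity(self):
        node = self.grid[(0, 0)]
        got = assoc_field_for(
            UnfoldedPosition(node.loc_long, node.loc_trans, "CA3"), self.grid)
        np.testing.assert_allclose(got.as_array(), node.as_array())

    def test_bilinear_midpoint(self):
        a, b = self.grid[(0, 0)], self.grid[(1, 0)]
        mid_lon = 0.5 * (a.loc_long + b.loc_long)
        got = assoc_field_params_at(mid_lon, a.loc_trans, self.grid)[0]
        np.testing.assert_allclose(got, 0.5 * (a.as_array() + b.as_array()))

    def test_linear_extrapolation_outside_grid(self):
        a, b = self.grid[(0, 0)], self.grid[(1, 0)]
        dy = a.loc_long - b.loc_long
        beyond = a.loc_long + dy
        got = assoc_field_params_at(beyond, a.loc_trans, self.grid)[0]
        np.testing.assert_allclose(got, 2 * a.as_array() - b.as_array())

    def test_malformed_grid_rejected(self):
        bad = {k: v for k, v in self.grid.items() if k != (2, 2)}
        with pytest.raises(ConfigurationError):
            assoc_field_params_at(5.0, 1.5, bad)


class TestDelays:
    @pytest.mark.parametrize("length, pathway, expected", [
        (0.0, "MF", 0.0),
        (1.0, "LPP", 3.125),
        (1.0, "MPP", 3.125),
        (2.7, "MF", 10.0),
        (3.9, "ASSOC", 10.0),
    ])
    def test_linear_in_length(self, length, pathway, expected):
        assert compute_delay(length, pathway) == pytest.approx(expected)

    def test_unknown_pathway(self):
        with pytest.raises(ConfigurationError):
            compute_delay(1.0, "CA1")


class TestBuildConnectome:
    def _small(self, pathways, seed=3):
        layout = build_layout(
            PopulationConfig(sizes={"EC": 150, "DG": 80, "CA3": 60}), seed=seed)
        cfg = ConnectivityConfig(pathways=pathways, budget_scale=0.01,
                                 mf_capture_radius_mm=0.25)
        return layout, build_connectome(layout, cfg, seed=seed)

    def test_disabled_pathways_empty(self):
        _, conn = self._small(())
        assert conn.n_edges() == 0

    def test_budget_conservation_exact(self):
        from ca3net.connectivity import _scaled_budget

        layout, conn = self._small(("LPP", "MPP", "ASSOC"))
        pos = layout.positions("CA3")
        ext = layout.config.extents["CA3"]
        for pathway, getter in (
                ("LPP", lambda b: b.lacunosum_distal),
                ("MPP", lambda b: b.lacunosum_proximal),
                ("ASSOC", lambda b: b.radiatum + b.oriens)):
            deg = conn.in_degree(pathway, len(pos))
            want = [getter(_scaled_budget(x / ext.transverse, 0.01))
                    for x in pos[:, 1]]
            np.testing.assert_array_equal(deg, want)

    def test_bit_reproducible_per_seed(self):
        _, a = self._small(("LPP", "MF"), seed=9)
        _, b = self._small(("LPP", "MF"), seed=9)
        for name in a.edges:
            np.testing.assert_array_equal(a.edges[name].pre, b.edges[name].pre)
            np.testing.assert_array_equal(a.edges[name].post, b.edges[name].post)
            np.testing.assert_array_equal(a.edges[name].delay_ms,
                                          b.edges[name].delay_ms)

    def test_delays_nonnegative_and_velocity_consistent(self):
        layout, conn = self._small(("LPP", "MPP", "MF", "ASSOC"))
        for name, e in conn.edges.items():
            assert np.all(e.delay_ms >= 0)
        # ASSOC delay equals pairwise distance / 0.39
        e = conn.edges["ASSOC"]
        pos = layout.positions("CA3")
        dist = np.hypot(pos[e.pre, 0] - pos[e.post, 0],
                        pos[e.pre, 1] - pos[e.post, 1])
        np.testing.assert_allclose(e.delay_ms, dist / 0.39, rtol=1e-5)

    def test_pp_partners_within_field_support(self):
        """Sampled presynaptic EC cells have non-vanishing field density
        at the postsynaptic position (no probability-zero draws)."""
        layout, conn = self._small(("LPP",))
        ec = layout.positions("EC")
        ca3 = layout.positions("CA3")
        e = conn.edges["LPP"]
        sd = 1.25 / 4
        z = np.abs(ec[e.pre, 0] - ca3[e.post, 0]) / sd
        assert np.all(z < 6.0)

    def test_scale_weights_copy_semantics(self):
        _, conn = self._small(("LPP", "MPP"))
        scaled = conn.scale_weights("LPP", 5.0)
        np.testing.assert_allclose(scaled.edges["LPP"].weight, 5.0)
        np.testing.assert_allclose(scaled.edges["MPP"].weight, 1.0)
        np.testing.assert_allclose(conn.edges["LPP"].weight, 1.0)
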