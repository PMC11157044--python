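"""Rich-club metrics: degrees, core selection, TC/TS/LF/JF, aggregation."""

import numpy as np
import pytest

from mlfcn import (
    CoreAssignment,
    aggregate,
    joint_functionality,
    local_functionality,
    max_degrees,
    multilayer_degrees,
    normalized_degree,
    select_core,
    shared_core_matrix,
    temporal_centrality,
    temporal_stability,
    toy_parcellation,
    union_graph,
)

from bruteforce import (
    bf_degrees,
    bf_jf,
    bf_lf,
    bf_select_core,
    bf_shared_core,
    bf_tc,
    bf_ts_literal,
    bf_union_graph,
)
from conftest import (
    parc_lookup_tables,
    random_core_assignment,
    random_parcellation,
    random_spatial_fcn,
    random_temporal_fcn,
)


class TestDegrees:
    def test_empty_network_all_zero(self, toy_parc):
        from mlfcn import SpatialMultilayerFCN

        net = SpatialMultilayerFCN(
            np.zeros((5, 5)), np.zeros((20, 20)), np.zeros((6, 20))
        )
        assert multilayer_degrees(net, toy_parc).sum() == 0

    def test_gm_inherits_mrsn_hyperedge_count(self, toy_parc):
        rng = np.random.default_rng(0)
        net = random_spatial_fcn(rng, toy_parc)
        deg = multilayer_degrees(net, toy_parc)
        for m in toy_parc.gm_mrsns:
            expected = net.H[toy_parc.mrsn_pos[m.mrsn_id]].sum()
            for ri in m.member_roi_indices:
                assert deg[ri - 1, 0] == expected

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_counting(self, seed):
        rng = np.random.default_rng(seed)
        parc = random_parcellation(rng)
        net = random_spatial_fcn(rng, parc)
        tissue, mrsn_of, mrsn_pos, gm_order, wm_order, _ = parc_lookup_tables(parc)
        expected = bf_degrees(
            net.H.tolist(), net.A1.tolist(), net.A2.tolist(),
            tissue, mrsn_of, mrsn_pos, gm_order, wm_order,
        )
        got = multilayer_degrees(net, parc)
        assert [tuple(r) for r in got] == expected


class TestNormalizedDegree:
    def test_saturated_gm_node_reaches_one(self, default_parc):
        dm = max_degrees(default_parc)
        an_roi = default_parc.mrsn_by_name("AN").member_roi_indices[0]
        deg = np.zeros((138, 3))
        deg[an_roi - 1] = (13, 2, 48)
        nd = normalized_degree(deg, dm)
        assert nd[an_roi - 1] == pytest.approx(1.0)

    def test_wm_single_layer_ratio(self, default_parc):
        dm = max_degrees(default_parc)
        wm_roi = default_parc.wm_roi_indices[0]
        deg = np.zeros((138, 3))
        deg[wm_roi - 1, 2] = 45
        nd = normalized_degree(deg, dm)
        assert nd[wm_roi - 1] == pytest.approx(0.5)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            normalized_degree(np.ones((2, 3)), np.zeros((2, 3)))


class TestSelectCore:
    def test_exact_core_size(self, default_parc):
        nd = np.random.default_rng(1).random(138)
        core = select_core(nd, 15)
        assert core.sum() == 15

    def test_all_equal_tie_break_picks_lowest_indices(self):
        core = select_core(np.full(30, 0.5), 15)
        np.testing.assert_array_equal(np.flatnonzero(core), np.arange(15))

    def test_strictly_decreasing_degrees(self):
        nd = np.linspace(1, 0, 20)
        core = select_core(nd, 5)
        np.testing.assert_array_equal(np.flatnonzero(core), np.arange(5))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        nd = rng.integers(0, 4, size=12) / 3.0  # plenty of ties
        got = select_core(nd, 5)
        assert got.tolist() == bf_select_core(nd.tolist(), 5)


class TestTemporalMetrics:
    def test_always_core_gives_tc_one(self):
        R = np.ones((3, 4), dtype=np.uint8)
        tc = temporal_centrality(CoreAssignment(R, 3))
        np.testing.assert_array_equal(tc, 1.0)

    def test_alternating_node(self):
        R = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=np.uint8)
        ca = CoreAssignment(R, 1)
        np.testing.assert_allclose(temporal_centrality(ca), [0.5, 0.5])
        np.testing.assert_allclose(temporal_stability(ca, "literal"), [1.0, 1.0])
        np.testing.assert_allclose(temporal_stability(ca, "prose"), [0.0, 0.0])

    def test_enumerated_transitions(self):
        # identities (1,1,0,1) and complement: 1 of 3 transitions consistent
        R = np.array([[1, 1, 0, 1], [0, 0, 1, 0]], dtype=np.uint8)
        ca = CoreAssignment(R, 1)
        np.testing.assert_allclose(
            temporal_stability(ca, "literal"), [2 / 3, 2 / 3]
        )
        np.testing.assert_allclose(
            temporal_stability(ca, "prose"), [1 / 3, 1 / 3]
        )

    def test_constant_identity_is_fully_stable(self):
        R = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.uint8)
        ca = CoreAssignment(R, 1)
        np.testing.assert_allclose(temporal_stability(ca, "literal"), 0.0)
        np.testing.assert_allclose(temporal_stability(ca, "prose"), 1.0)

    def test_tc_sums_to_core_size(self):
        rng = np.random.default_rng(2)
        ca = random_core_assignment(rng, 20, 6, 7)
        assert temporal_centrality(ca).sum() == pytest.approx(7.0)

    def test_single_layer_stability_rejected(self):
        ca = CoreAssignment(np.ones((3, 1), dtype=np.uint8), 3)
        with pytest.raises(ValueError):
            temporal_stability(ca)


class TestSharedCore:
    def test_zero_when_no_shared_neighbors(self, toy_parc):
        rng = np.random.default_rng(3)
        tfcn = random_temporal_fcn(rng, toy_parc, 3)
        # every node core nowhere shares anything: make all nodes core once
        # simpler trivial case: empty networks
        for layer in tfcn.layers:
            layer.H[:] = 0
            layer.A1[:] = 0
            layer.A2[:] = 0
        ca = random_core_assignment(rng, toy_parc.n_roi, 3, 5)
        P = shared_core_matrix(tfcn, ca, toy_parc)
        assert np.all(P == 0)

    def test_normalization_ceiling(self):
        # two peripheral nodes connected to every core node in every layer
        parc = toy_parcellation(n_mrsn=2, gm_per_mrsn=2, n_wm=2)  # 6 nodes
        from mlfcn import SpatialMultilayerFCN, TemporalMultilayerFCN, WindowSpec

        # cores: the two WM nodes? WM cannot connect to WM.  Use GM cores:
        # nodes 1,2 (MRSN1) core; peripheral WM nodes 5,6 connect via A2.
        A2 = np.zeros((2, 4), dtype=np.uint8)
        A2[:, 0] = 1  # both WM connect to GM node 1
        A2[:, 1] = 1  # and GM node 2
        layers = [
            SpatialMultilayerFCN(
                np.zeros((2, 2)), np.zeros((4, 4)), A2.copy(), t
            )
            for t in range(3)
        ]
        tfcn = TemporalMultilayerFCN(layers, WindowSpec(10, 5), parc)
        R = np.zeros((6, 3), dtype=np.uint8)
        R[0] = 1
        R[1] = 1
        ca = CoreAssignment(R, 2)
        P = shared_core_matrix(tfcn, ca, parc)
        assert P[4, 5] == pytest.approx(1.0)

    def test_symmetry_and_zero_diagonal(self, toy_parc):
        rng = np.random.default_rng(4)
        tfcn = random_temporal_fcn(rng, toy_parc, 3)
        ca = random_core_assignment(rng, toy_parc.n_roi, 3, 5)
        P = shared_core_matrix(tfcn, ca, toy_parc)
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_array_equal(np.diag(P), 0.0)
        assert P.min() >= 0 and P.max() <= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        parc = random_parcellation(rng)
        T = int(rng.integers(2, 4))
        tfcn = random_temporal_fcn(rng, parc, T)
        n_core = int(rng.integers(1, parc.n_roi))
        ca = random_core_assignment(rng, parc.n_roi, T, n_core)
        tissue, mrsn_of, mrsn_pos, gm_order, wm_order, _ = parc_lookup_tables(parc)
        unions = [
            bf_union_graph(
                l.H.tolist(), l.A1.tolist(), l.A2.tolist(),
                tissue, mrsn_of, mrsn_pos, gm_order, wm_order,
            )
            for l in tfcn.layers
        ]
        expected = np.array(bf_shared_core(unions, ca.R.tolist(), n_core))
        got = shared_core_matrix(tfcn, ca, parc)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monotone_in_core_peripheral_edges(self, toy_parc):
        # adding a WM-GM edge can only increase shared-core counts
        rng = np.random.default_rng(5)
        tfcn = random_temporal_fcn(rng, toy_parc, 3)
        ca = random_core_assignment(rng, toy_parc.n_roi, 3, 5)
        P0 = shared_core_matrix(tfcn, ca, toy_parc)
        layer = tfcn.layers[1]
        empty = np.argwhere(layer.A2 == 0)
        w, g = empty[rng.integers(len(empty))]
        layer.A2[w, g] = 1
        P1 = shared_core_matrix(tfcn, ca, toy_parc)
        assert np.all(P1 >= P0 - 1e-15)


class TestFunctionalities:
    def test_zero_matrix(self, toy_parc):
        P = np.zeros((toy_parc.n_roi, toy_parc.n_roi))
        assert local_functionality(P, toy_parc).sum() == 0
        assert joint_functionality(P, toy_parc).sum() == 0

    def test_constant_p_algebra(self, toy_parc):
        p = 0.3
        n = toy_parc.n_roi
        P = np.full((n, n), p)
        np.fill_diagonal(P, 0.0)
        lf = local_functionality(P, toy_parc)
        jf = joint_functionality(P, toy_parc)
        for r in toy_parc.rois:
            n_s = toy_parc.mrsn_size(r.mrsn_id)
            assert lf[r.index - 1] == pytest.approx(p * (n_s - 1) / n_s)
            assert jf[r.index - 1] == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_index_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        parc = random_parcellation(rng)
        n = parc.n_roi
        P = rng.random((n, n))
        P = (P + P.T) / 2
        np.fill_diagonal(P, 0.0)
        _, mrsn_of, *_ = parc_lookup_tables(parc)
        np.testing.assert_allclose(
            local_functionality(P, parc), bf_lf(P.tolist(), mrsn_of)
        )
        np.testing.assert_allclose(
            joint_functionality(P, parc), bf_jf(P.tolist(), mrsn_of)
        )

    def test_single_network_jf_rejected(self):
        parc = toy_parcellation(n_mrsn=1, gm_per_mrsn=3, n_wm=0)
        P = np.zeros((3, 3))
        with pytest.raises(ValueError):
            joint_functionality(P, parc)


class TestAggregate:
    def test_constant_members(self, toy_parc):
        v = np.zeros(toy_parc.n_roi)
        m = toy_parc.gm_mrsns[0]
        for ri in m.member_roi_indices:
            v[ri - 1] = 0.7
        out = aggregate(v, toy_parc, "mrsn")
        assert out.loc[out["unit"] == m.name, "value"].item() == pytest.approx(0.7)

    def test_whole_brain_tc_is_core_share(self, toy_parc):
        rng = np.random.default_rng(6)
        ca = random_core_assignment(rng, toy_parc.n_roi, 4, 5)
        tc = temporal_centrality(ca)
        out = aggregate(tc, toy_parc, "whole_brain", metric_name="tc")
        assert out["value"].item() == pytest.approx(5 / toy_parc.n_roi)
        assert out["constant_by_construction"].item()

    def test_mixed_values_match_mean_oracle(self, toy_parc):
        v = np.random.default_rng(7).random(toy_parc.n_roi)
        out = aggregate(v, toy_parc, "mrsn")
        for m in toy_parc.mrsns:
            members = [v[i - 1] for i in m.member_roi_indices]
            expected = sum(members) / len(members)
            assert out.loc[out["unit"] == m.name, "value"].item() == pytest.approx(
                expected
            )
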