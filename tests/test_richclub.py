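import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcnet.fc_network import EmptyNetworkError, WeightedNetwork
from rcnet.richclub import (
    club_members,
    compare_curves,
    node_strength,
    null_reshuffle,
    phi_w,
    prominence_ranking,
    rho_w,
    threshold_grid,
)

from conftest import fc_from_matrix, random_small_network


def brute_force_phi(net: WeightedNetwork, threshold: float):
    """Independent enumeration oracle for the weighted rich-club ratio."""
    strengths = {nid: 0.0 for nid in net.node_ids}
    for i, j, w in net.edges:
        strengths[net.node_ids[i]] += w
        strengths[net.node_ids[j]] += w
    club = {nid for nid, s in strengths.items() if s > threshold}
    internal = [
        w for i, j, w in net.edges
        if net.node_ids[i] in club and net.node_ids[j] in club
    ]
    if not internal:
        return None
    all_sorted = sorted((w for _, _, w in net.edges), reverse=True)
    return sum(internal) / sum(all_sorted[: len(internal)])


def uniform_complete(n=8, w=1.0):
    iu, ju = np.triu_indices(n, k=1)
    return WeightedNetwork(
        node_ids=[f"n{i}" for i in range(n)],
        node_hemisphere=["ipsi"] * (n // 2) + ["contra"] * (n - n // 2),
        edge_i=iu,
        edge_j=ju,
        weights=np.full(len(iu), w),
    )


class TestNodeStrength:
    def test_hand_summed_strengths(self, toy_net):
        sv = node_strength(toy_net)
        assert dict(zip(sv.node_ids, sv.s)) == {"A": 4.0, "B": 6.0, "C": 5.0, "D": 3.0}

    def test_single_edge_and_isolated_node(self):
        net = WeightedNetwork(
            node_ids=["a", "b", "c"],
            node_hemisphere=["ipsi", "ipsi", "contra"],
            edge_i=np.array([0]),
            edge_j=np.array([1]),
            weights=np.array([0.7]),
        )
        sv = node_strength(net)
        np.testing.assert_allclose(sv.s, [0.7, 0.7, 0.0])

    def test_matches_networkx_oracle(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = random_small_network(rng)
            g = nx.Graph()
            g.add_nodes_from(net.node_ids)
            for i, j, w in net.edges:
                g.add_edge(net.node_ids[i], net.node_ids[j], weight=w)
            expected = dict(g.degree(weight="weight"))
            sv = node_strength(net)
            for nid, s in zip(sv.node_ids, sv.s):
                assert s == pytest.approx(expected[nid])


class TestClubMembers:
    def test_strict_inequality(self, toy_net):
        sv = node_strength(toy_net)
        assert club_members(sv, 4.0) == {"B", "C"}

    def test_threshold_below_all(self, toy_net):
        assert club_members(node_strength(toy_net), -1.0) == {"A", "B", "C", "D"}

    def test_threshold_at_max_gives_empty(self, toy_net):
        assert club_members(node_strength(toy_net), 6.0) == set()


class TestPhiW:
    def test_enumerated_example(self, toy_net):
        summary = phi_w(toy_net, 4.0)
        assert summary.members == {"B", "C"}
        assert summary.E_gt_s == 1
        assert summary.W_gt_s == pytest.approx(2.0)
        assert summary.phi == pytest.approx(2.0 / 3.0)

    def test_uniform_weights_give_phi_one(self):
        net = uniform_complete()
        for t in (0.0, 3.0, 5.0):
            summary = phi_w(net, t)
            if summary.phi is not None:
                assert summary.phi == pytest.approx(1.0)

    def test_whole_network_club_gives_phi_one(self, toy_net):
        summary = phi_w(toy_net, 0.0)
        assert summary.members == {"A", "B", "C", "D"}
        assert summary.E_gt_s == toy_net.E
        assert summary.phi == pytest.approx(1.0)

    def test_edgeless_club_marked_undefined(self, toy_net):
        summary = phi_w(toy_net, 5.5)  # club = {B} only
        assert summary.phi is None
        assert summary.E_gt_s == 0

    def test_phi_in_unit_interval_and_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            net = random_small_network(rng)
            s = node_strength(net).s
            for t in rng.uniform(0, s.max() + 0.5, 4):
                summary = phi_w(net, float(t))
                expected = brute_force_phi(net, float(t))
                if expected is None:
                    assert summary.phi is None
                else:
                    assert summary.phi == pytest.approx(expected, abs=1e-12)
                    assert 0 < summary.phi <= 1 + 1e-12


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    n=st.integers(3, 6),
    edge_bits=st.integers(0, 2**15 - 1),
    weight_seed=st.integers(0, 2**20),
    threshold_frac=st.floats(0.0, 1.2),
)
def test_phi_equals_brute_force_on_arbitrary_small_networks(
    n, edge_bits, weight_seed, threshold_frac
):
    """Property: phi_w agrees with explicit enumeration on any small network."""
    iu, ju = np.triu_indices(n, k=1)
    keep = np.array([(edge_bits >> k) & 1 for k in range(len(iu))], dtype=bool)
    if keep.sum() < 2:
        return
    rng = np.random.default_rng(weight_seed)
    net = WeightedNetwork(
        node_ids=[f"n{i}" for i in range(n)],
        node_hemisphere=["ipsi"] * n,
        edge_i=iu[keep],
        edge_j=ju[keep],
        weights=rng.uniform(0.01, 1.0, int(keep.sum())),
    )
    t = threshold_frac * node_strength(net).s.max()
    expected = brute_force_phi(net, t)
    got = phi_w(net, t).phi
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0 < got <= 1 + 1e-12


class TestNullReshuffle:
    def test_conserves_topology_and_weight_multiset(self, toy_net):
        rng = np.random.default_rng(2)
        null = null_reshuffle(toy_net, rng)
        np.testing.assert_array_equal(null.edge_i, toy_net.edge_i)
        np.testing.assert_array_equal(null.edge_j, toy_net.edge_j)
        assert sorted(null.weights) == pytest.approx(sorted(toy_net.weights))
        assert null.total_weight() == pytest.approx(toy_net.total_weight())

    def test_some_strength_changes_for_nonuniform_weights(self):
        rng = np.random.default_rng(3)
        net = random_small_network(rng)
        changed = False
        for _ in range(20):
            null = null_reshuffle(net, rng)
            if not np.allclose(node_strength(null).s, node_strength(net).s):
                changed = True
                break
        assert changed

    def test_seeded_reproducibility(self, toy_net):
        a = null_reshuffle(toy_net, np.random.default_rng(42))
        b = null_reshuffle(toy_net, np.random.default_rng(42))
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_requires_two_edges(self):
        net = WeightedNetwork(
            node_ids=["a", "b"],
            node_hemisphere=["ipsi", "contra"],
            edge_i=np.array([0]),
            edge_j=np.array([1]),
            weights=np.array([0.5]),
        )
        with pytest.raises(ValueError):
            null_reshuffle(net, np.random.default_rng(0))


class TestThresholdGrid:
    def test_uniform_complete_never_reaches_empty_club(self):
        net = uniform_complete(8)
        grid = threshold_grid(net, n_points=10)
        assert grid.max() < 7.0  # all strengths are 7
        for t in grid:
            assert phi_w(net, float(t)).phi is not None

    def test_enumerated_break_point(self, toy_net):
        grid = threshold_grid(toy_net, n_points=10, min_club_nodes=2, min_club_edges=1)
        # at s=5 the club is {B} alone, so the grid must stay below 5
        assert grid.max() < 5.0
        assert grid[0] == 0.0

    def test_single_point_grid(self, toy_net):
        grid = threshold_grid(toy_net, n_points=1, min_club_nodes=2, min_club_edges=1)
        np.testing.assert_array_equal(grid, [0.0])

    def test_degenerate_network_rejected(self):
        net = WeightedNetwork(
            node_ids=["a", "b", "c"],
            node_hemisphere=["ipsi", "ipsi", "contra"],
            edge_i=np.array([0, 1]),
            edge_j=np.array([1, 2]),
            weights=np.array([1.0, 1.0]),
        )
        with pytest.raises(EmptyNetworkError):
            threshold_grid(net, min_club_nodes=5, min_club_edges=2)


class TestRhoW:
    def test_uniform_weights_give_rho_exactly_one(self):
        net = uniform_complete(8)
        curve = rho_w(net, n_null=20, seed=0)
        defined = curve.defined
        assert defined.any()
        np.testing.assert_allclose(curve.rho[defined], 1.0)

    def test_seeded_curve_bit_reproducible(self, toy_net):
        kw = dict(n_null=2, seed=5, n_points=5, min_club_nodes=2, min_club_edges=1)
        a = rho_w(toy_net, **kw)
        b = rho_w(toy_net, **kw)
        np.testing.assert_array_equal(a.rho, b.rho)
        np.testing.assert_array_equal(a.phi_random_samples, b.phi_random_samples)

    def test_null_sample_shape_and_ratio_definition(self, toy_net):
        curve = rho_w(toy_net, n_null=7, seed=1, n_points=4,
                      min_club_nodes=2, min_club_edges=1)
        assert curve.phi_random_samples.shape == (7, 4)
        d = curve.defined
        np.testing.assert_allclose(
            curve.rho[d], curve.phi[d] / curve.phi_random_mean[d]
        )

    def test_rejects_invalid_null_count(self, toy_net):
        with pytest.raises(ValueError):
            rho_w(toy_net, n_null=0, seed=0)


class TestProminenceRanking:
    def test_sorted_by_descending_strength(self, toy_net):
        r = prominence_ranking(toy_net, k=2)
        assert r.node_ids[:2] == ["B", "C"]
        assert r.top_k == ["B", "C"]
        np.testing.assert_allclose(r.strengths, [6, 5, 4, 3])

    def test_ties_broken_alphabetically(self):
        net = uniform_complete(4)
        r = prominence_ranking(net, k=4)
        assert r.node_ids == sorted(net.node_ids)

    def test_k_beyond_node_count_rejected(self, toy_net):
        with pytest.raises(ValueError):
            prominence_ranking(toy_net, k=5)


class TestCompareCurves:
    def _group(self, rng, n_animals, shift=0.0, condition="pre"):
        mats = []
        base = rng.uniform(0.1, 0.7, (10, 10))
        base = (base + base.T) / 2
        for _ in range(n_animals):
            a = base + rng.normal(0, 0.05, (10, 10)) + shift
            r = np.clip((a + a.T) / 2, -0.99, 0.99)
            np.fill_diagonal(r, 1.0)
            mats.append(fc_from_matrix(r, condition))
        return mats

    def test_identical_groups_show_no_effect(self):
        rng = np.random.default_rng(4)
        pre = self._group(rng, 3)
        post = [fc_from_matrix(m.r.copy(), "post") for m in pre]
        comp = compare_curves(pre, post, n_permutations=50, seed=0,
                              n_null=20, n_points=6)
        d = np.isfinite(comp.delta_rho)
        np.testing.assert_allclose(comp.delta_rho[d], 0.0, atol=1e-12)
        assert not comp.significant.any()

    def test_three_animals_enumerates_exactly_with_floor_p(self):
        rng = np.random.default_rng(5)
        pre = self._group(rng, 3)
        post = self._group(rng, 3, shift=-0.1, condition="post")
        comp = compare_curves(pre, post, n_permutations=100, seed=0,
                              n_null=20, n_points=6)
        assert comp.exact
        finite = comp.p_values[np.isfinite(comp.p_values)]
        # 2^3 = 8 label assignments -> p can never drop below 1/8,
        # so nothing can reach the 0.01 significance level with 3 animals
        assert finite.min() >= 1 / 8 - 1e-12
        assert not comp.significant.any()

    def test_unpaired_groups_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            compare_curves(self._group(rng, 3), self._group(rng, 2, condition="post"),
                           n_permutations=10, seed=0)
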