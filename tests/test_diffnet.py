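import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fragstatis.diffnet import (CorrelationNetwork, DegenerateTableError,
                                InsufficientDataError, abundance_tests,
                                class_association_chi2, classify_quadrants,
                                correlation_network, dc_permutation_test,
                                differential_connectivity, network_density)


def _net_from_adjacency(adj, nodes=None):
    adj = np.asarray(adj, dtype=bool)
    p = adj.shape[0]
    nodes = nodes or [f"m{i}" for i in range(p)]
    r = adj.astype(float) * 0.9
    np.fill_diagonal(r, 1.0)
    q = np.where(adj, 0.01, 0.5).astype(float)
    return CorrelationNetwork(nodes, r, q / 10, q, adj)


class TestCorrelationNetwork:
    def test_perfectly_correlated_pair_gets_edge(self, rng):
        x = rng.normal(size=21)
        data = np.column_stack([x, 3.0 * x, rng.normal(size=21)])
        net = correlation_network(data, fdr=0.05)
        assert (0, 1) in {tuple(sorted(e)) for e in net.edges} or \
            (net.nodes[0], net.nodes[1]) in net.edges
        assert net.q[0, 1] < 1e-10

    def test_constant_metabolite_flagged_without_edges(self, rng):
        data = np.column_stack([np.full(21, 7.0), rng.normal(size=(21, 3))])
        net = correlation_network(data, nodes=list("abcd"))
        assert net.constant_nodes == ["a"]
        assert net.degrees()[0] == 0

    def test_too_few_samples(self, rng):
        with pytest.raises(InsufficientDataError):
            correlation_network(rng.normal(size=(3, 5)))

    def test_matches_nested_loop_oracle(self, rng):
        """Edge set identical to a per-pair pearsonr + BH oracle."""
        n, p = 21, 20
        data = rng.normal(size=(n, p))
        data[:, 1] = data[:, 0] * 0.9 + 0.3 * rng.normal(size=n)
        data[:, 5] = -data[:, 4] + 0.2 * rng.normal(size=n)
        net = correlation_network(data, fdr=0.05)
        pvals, pairs = [], []
        for i in range(p):
            for j in range(i + 1, p):
                pvals.append(stats.pearsonr(data[:, i], data[:, j]).pvalue)
                pairs.append((i, j))
        q = multipletests(pvals, method="fdr_bh")[1]
        oracle = {(net.nodes[i], net.nodes[j])
                  for (i, j), qv in zip(pairs, q) if qv < 0.05}
        assert net.edges == oracle

    def test_edges_invariant_to_metabolite_order(self, rng):
        data = pd.DataFrame(rng.normal(size=(21, 10)),
                            columns=[f"m{i}" for i in range(10)])
        data["m3"] = data["m0"] * 0.95 + 0.2 * rng.normal(size=21)
        net1 = correlation_network(data)
        perm = rng.permutation(data.columns)
        net2 = correlation_network(data[perm])
        assert net1.edges == net2.edges
        assert network_density(net1) == network_density(net2)


class TestDensity:
    def test_empty_network(self):
        assert network_density(_net_from_adjacency(np.zeros((10, 10)))) == 0

    def test_complete_network(self):
        adj = ~np.eye(10, dtype=bool)
        assert network_density(_net_from_adjacency(adj)) == 1

    def test_hand_count(self):
        adj = np.zeros((5, 5), dtype=bool)
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4)]:
            adj[a, b] = adj[b, a] = True
        assert network_density(_net_from_adjacency(adj)) == pytest.approx(0.4)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            network_density(_net_from_adjacency(np.zeros((1, 1))))


class TestDifferentialConnectivity:
    def test_identical_networks_give_zero(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        net = _net_from_adjacency(adj)
        assert np.allclose(differential_connectivity(net, net), 0.0)

    def test_hand_computed_degrees(self):
        # D edges {0-1, 0-3}: degrees (2,1,0,1), max 2
        adj_d = np.zeros((4, 4), dtype=bool)
        adj_d[0, 1] = adj_d[1, 0] = True
        adj_d[0, 3] = adj_d[3, 0] = True
        # W edges {1-2, 1-3}: degrees (0,2,1,1), max 2
        adj_w = np.zeros((4, 4), dtype=bool)
        adj_w[1, 2] = adj_w[2, 1] = True
        adj_w[1, 3] = adj_w[3, 1] = True
        dc = differential_connectivity(_net_from_adjacency(adj_d),
                                       _net_from_adjacency(adj_w))
        assert np.allclose(dc, [1.0, -0.5, -0.5, 0.0])

    def test_extreme_case_is_unity(self):
        adj_d = np.zeros((4, 4), dtype=bool)
        adj_d[0, 1:] = adj_d[1:, 0] = True
        empty = np.zeros((4, 4), dtype=bool)
        dc = differential_connectivity(_net_from_adjacency(adj_d),
                                       _net_from_adjacency(empty))
        assert dc[0] == 1.0
        assert np.abs(dc).max() <= 1.0

    def test_empty_network_contributes_zero_degrees(self):
        empty = _net_from_adjacency(np.zeros((5, 5)))
        assert np.allclose(differential_connectivity(empty, empty), 0.0)

    def test_node_mismatch_rejected(self):
        a = _net_from_adjacency(np.zeros((3, 3)), nodes=list("abc"))
        b = _net_from_adjacency(np.zeros((3, 3)), nodes=list("abd"))
        with pytest.raises(ValueError):
            differential_connectivity(a, b)


class TestPermutationTest:
    def test_identical_groups_give_p_one(self, rng):
        data = rng.normal(size=(21, 15))
        acc = np.repeat([f"a{i}" for i in range(7)], 3)
        dc, p, q = dc_permutation_test(data, data.copy(), acc,
                                       np.char.add(acc, "w"), B=50, seed=1)
        assert np.allclose(dc, 0.0)
        assert np.allclose(p, 1.0)

    def test_p_floor_is_add_one_estimator(self, rng):
        d = rng.normal(size=(12, 10))
        w = rng.normal(size=(12, 10))
        acc_d = np.repeat(list("abcd"), 3)
        acc_w = np.repeat(list("efgh"), 3)
        B = 40
        _, p, _ = dc_permutation_test(d, w, acc_d, acc_w, B=B, seed=2)
        assert (p >= 1.0 / (B + 1) - 1e-12).all()
        assert (p <= 1.0).all()

    def test_needs_two_accessions_per_group(self, rng):
        d = rng.normal(size=(6, 5))
        with pytest.raises(InsufficientDataError):
            dc_permutation_test(d, d, ["a"] * 6, ["b", "b", "b", "c", "c",
                                                  "c"], B=10, seed=0)


class TestAbundanceTests:
    def test_identical_groups(self, rng):
        data = np.abs(rng.normal(5, 1, size=(10, 6)))
        t, p, q, d = abundance_tests(data, data.copy())
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_matches_welch_formula_by_hand(self):
        x = np.array([[3.1], [4.2], [5.3]])
        y = np.array([[2.0], [2.5], [2.2]])
        t, p, q, d = abundance_tests(x, y, log_transform=False)
        m1, m2 = x.mean(), y.mean()
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        t_hand = (m1 - m2) / np.sqrt(v1 / 3 + v2 / 3)
        assert t[0] == pytest.approx(t_hand, abs=1e-12)
        assert d[0] == "up_in_D"

    def test_planted_shift_detected(self, rng):
        base = rng.normal(size=(21, 30))
        shifted = rng.normal(size=(21, 30))
        shifted[:, :5] += 2.0  # 2-SD shift on 5 metabolites
        t, p, q, d = abundance_tests(shifted, base, log_transform=False)
        assert (q[:5] < 0.05).all()
        assert (d[:5] == "up_in_D").all()


class TestQuadrants:
    @pytest.mark.parametrize("dc,direction,expected", [
        (0.5, "up_in_D", "top_right"),
        (0.5, "down_in_D", "top_left"),
        (-0.5, "down_in_D", "bottom_left"),
        (-0.5, "up_in_D", "bottom_right"),
    ])
    def test_significant_quadrant_mapping(self, dc, direction, expected):
        rec = pd.DataFrame({"dc": [dc], "q_perm": [0.01], "q_t": [0.01],
                            "abundance_direction": [direction]})
        assert classify_quadrants(rec)["quadrant"].iloc[0] == expected

    def test_nonsignificant_dc_gates_to_ns(self):
        rec = pd.DataFrame({"dc": [0.9], "q_perm": [0.2], "q_t": [0.001],
                            "abundance_direction": ["up_in_D"]})
        assert classify_quadrants(rec)["quadrant"].iloc[0] == "ns"

    def test_nonsignificant_abundance_gates_to_ns(self):
        rec = pd.DataFrame({"dc": [0.9], "q_perm": [0.001], "q_t": [0.2],
                            "abundance_direction": ["up_in_D"]})
        assert classify_quadrants(rec)["quadrant"].iloc[0] == "ns"


class TestClassAssociationChi2:
    def test_balanced_table_gives_zero(self):
        met_class = np.array(["primary"] * 10 + ["secondary"] * 10)
        dc = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1] * 2, dtype=float)
        chi2, p, table = class_association_chi2(met_class, dc,
                                                scope="all_nonzero_dc")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_yates_formula(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            met_class = np.array(["primary"] * (a + b)
                                 + ["secondary"] * (c + d))
            dc = np.concatenate([np.ones(a), -np.ones(b),
                                 np.ones(c), -np.ones(d)])
            chi2, p, _ = class_association_chi2(met_class, dc,
                                                scope="all_nonzero_dc")
            n = a + b + c + d
            hand = (n * max(0.0, abs(a * d - b * c) - n / 2) ** 2
                    / ((a + b) * (c + d) * (a + c) * (b + d)))
            assert chi2 == pytest.approx(hand, abs=1e-10)
            assert p == pytest.approx(stats.chi2.sf(hand, 1), abs=1e-12)

    def test_zero_marginal_rejected(self):
        met_class = np.array(["primary"] * 4)
        dc = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(DegenerateTableError):
            class_association_chi2(met_class, dc, scope="all_nonzero_dc")

    def test_significant_scope_needs_mask(self):
        with pytest.raises(ValueError):
            class_association_chi2(np.array(["primary"]), np.array([1.0]),
                                   scope="significant_only")
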