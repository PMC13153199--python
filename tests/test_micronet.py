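"""Co-occurrence networks, Zi–Pi roles, RMT scan and OTU Venn counts."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from foulcast import micronet as mn
from foulcast.synthdata import gen_abundance_table


class TestBuildNetwork:
    def test_perfectly_correlated_pair_single_positive_edge(self):
        x = np.linspace(0, 1, 10)
        table = pd.DataFrame({f"s{i}": [x[i], 2 * x[i] + 1, -x[i]] for i in range(10)},
                             index=["a", "b", "c"])
        g = mn.build_network(table, method="pearson", threshold=0.9)
        assert g.has_edge("a", "b") and g.edges["a", "b"]["sign"] == 1
        assert g.has_edge("a", "c") and g.edges["a", "c"]["sign"] == -1

    def test_strict_cutoff_with_noise_gives_empty_graph(self, rng):
        table = pd.DataFrame(rng.normal(size=(6, 30)))
        table.index = [f"t{i}" for i in range(6)]
        g = mn.build_network(table, threshold=0.999)
        assert g.number_of_edges() == 0

    def test_constant_taxon_excluded_with_warning(self, rng):
        table = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"])
        table.loc["c"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            g = mn.build_network(table, threshold=0.5, drop_isolated=False)
        assert "c" not in g

    def test_invalid_threshold_rejected(self, rng):
        table = pd.DataFrame(rng.normal(size=(3, 10)), index=list("abc"))
        with pytest.raises(ValueError, match="threshold"):
            mn.build_network(table, threshold=1.5)

    def test_planted_modules_recovered(self):
        table, truth = gen_abundance_table(seed=0)
        g = mn.build_network(table, threshold=truth["edge_threshold"])
        part, _ = mn.detect_modules(g)
        keep = [t for t in table.index if t in g and t not in truth["connectors"]]
        ari = adjusted_rand_score(
            [truth["membership"][t] for t in keep], [part[t] for t in keep]
        )
        assert ari > 0.9


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(4))
        part, q = mn.detect_modules(g)
        assert len(set(part.values())) == 2
        assert q > 0.3

    def test_single_clique_one_module(self):
        part, _ = mn.detect_modules(nx.complete_graph(6))
        assert len(set(part.values())) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mn.detect_modules(nx.Graph())


def brute_force_zi_pi(graph, partition):
    """Independent per-node tally of within-module degree stats and Pi."""
    out = {}
    for v in graph.nodes:
        module_members = [u for u in graph.nodes if partition[u] == partition[v]]
        kappas = []
        for u in module_members:
            kappas.append(
                sum(1 for w in graph.neighbors(u) if partition[w] == partition[u])
            )
        kappa_v = sum(1 for w in graph.neighbors(v) if partition[w] == partition[v])
        mean = sum(kappas) / len(kappas)
        sd = (sum((k - mean) ** 2 for k in kappas) / len(kappas)) ** 0.5
        zi = (kappa_v - mean) / sd if sd > 0 else 0.0
        k = graph.degree(v)
        if k == 0:
            pi = 0.0
        else:
            counts = {}
            for w in graph.neighbors(v):
                counts[partition[w]] = counts.get(partition[w], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        out[v] = (zi, pi)
    return out


class TestZiPi:
    def test_within_single_module_pi_zero(self):
        g = nx.complete_graph(5)
        part = {v: 0 for v in g}
        for r in mn.zi_pi(g, part):
            assert r.pi == 0.0

    def test_balanced_two_module_split_pi_half(self):
        g = nx.Graph([("c", "a1"), ("c", "a2"), ("c", "b1"), ("c", "b2")])
        part = {"c": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = {r.node: r for r in mn.zi_pi(g, part)}
        assert roles["c"].pi == pytest.approx(0.5)

    def test_toy_graph_hand_computed(self):
        # two triangles bridged by node 0; module 0 = {0,1,2}, module 1 = {3,4,5,6}
        g = nx.Graph(
            [(0, 1), (0, 2), (1, 2), (0, 3), (3, 4), (3, 5), (4, 5), (5, 6)]
        )
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 1}
        roles = {r.node: r for r in mn.zi_pi(g, part)}
        # node 0: within-degree 2, module degrees all 2 -> sd 0 -> zi 0;
        # total degree 3, split 2/1 -> pi = 1 - (4/9 + 1/9) = 4/9
        assert roles[0].zi == 0.0
        assert roles[0].pi == pytest.approx(4.0 / 9.0)
        # node 5: within-degree 3 vs module profile (2,2,3,1)
        kappas = np.array([2, 2, 3, 1])
        assert roles[5].zi == pytest.approx((3 - kappas.mean()) / kappas.std())
        assert roles[5].pi == 0.0

    @pytest.mark.filterwarnings("ignore:node .* has degree 0")
    def test_matches_brute_force_on_random_graphs(self, rng):
        for n, p in [(12, 0.3), (20, 0.2), (30, 0.15)]:
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            part = {v: int(rng.integers(3)) for v in g}
            expected = brute_force_zi_pi(g, part)
            for r in mn.zi_pi(g, part):
                zi, pi = expected[r.node]
                assert r.zi == pytest.approx(zi, abs=1e-12)
                assert r.pi == pytest.approx(pi, abs=1e-12)

    def test_zi_mean_zero_within_modules_and_pi_bounds(self, rng):
        g = nx.gnp_random_graph(25, 0.2, seed=5)
        part = {v: v % 3 for v in g}
        roles = mn.zi_pi(g, part)
        assert all(0.0 <= r.pi <= 1.0 for r in roles)
        for m in range(3):
            zis = [r.zi for r in roles if part[r.node] == m]
            assert np.mean(zis) == pytest.approx(0.0, abs=1e-10)

    def test_role_thresholds_boundaries_fall_to_peripheral(self):
        # star with 12 leaves in one module: hub zi > 2.5, pi = 0
        g = nx.star_graph(12)
        part = {v: 0 for v in g}
        roles = {r.node: r for r in mn.zi_pi(g, part)}
        assert roles[0].role == "module_hub"
        assert all(roles[v].role == "peripheral" for v in range(1, 13))

    def test_role_relabeling_invariance(self, rng):
        g = nx.gnp_random_graph(18, 0.25, seed=9)
        part = {v: v % 2 for v in g}
        relabeled = {v: 1 - m for v, m in part.items()}
        a = {r.node: (r.zi, r.pi, r.role) for r in mn.zi_pi(g, part)}
        b = {r.node: (r.zi, r.pi, r.role) for r in mn.zi_pi(g, relabeled)}
        assert a == b

    def test_degree_zero_node_pi_zero_with_warning(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        with pytest.warns(UserWarning, match="degree 0"):
            roles = {r.node: r for r in mn.zi_pi(g, {0: 0, 1: 0, 2: 0})}
        assert roles[2].pi == 0.0

    def test_missing_module_assignment_rejected(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValueError, match="without a module"):
            mn.zi_pi(g, {0: 0, 1: 0})


class TestRmtThresholdScan:
    def test_identity_matrix_compatible_everywhere(self):
        suggested, diag = mn.rmt_threshold_scan(np.eye(40), [0.3, 0.5, 0.7])
        assert (diag["poisson_distance"] == 0.0).all()
        assert suggested == 0.3

    def test_all_ones_block_flagged_non_poisson(self):
        R = np.ones((40, 40))
        suggested, diag = mn.rmt_threshold_scan(R, [0.2, 0.5, 0.8], tolerance=1.0)
        assert (diag["poisson_distance"] > 1.0).all()
        assert suggested is None

    def test_deterministic_for_fixed_input(self, rng):
        table = pd.DataFrame(rng.normal(size=(25, 40)),
                             index=[f"t{i}" for i in range(25)])
        out1 = mn.rmt_threshold_scan(table, [0.2, 0.4, 0.6])
        out2 = mn.rmt_threshold_scan(table, [0.2, 0.4, 0.6])
        assert out1[0] == out2[0]
        pd.testing.assert_frame_equal(out1[1], out2[1])

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mn.rmt_threshold_scan(np.eye(10), [0.5, 0.6])


class TestOtuVenn:
    def test_identical_sets_all_in_full_intersection(self):
        counts = mn.otu_venn({"A": {1, 2, 3}, "B": {1, 2, 3}, "C": {1, 2, 3}})
        assert counts["A&B&C"] == 3
        assert sum(v for k, v in counts.items() if k != "A&B&C") == 0

    def test_disjoint_sets_only_uniques(self):
        counts = mn.otu_venn({"A": {1}, "B": {2, 3}, "C": {4}})
        assert (counts["A"], counts["B"], counts["C"]) == (1, 2, 1)
        assert all(v == 0 for k, v in counts.items() if "&" in k)

    def test_enumerated_two_set_example(self):
        counts = mn.otu_venn({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert counts == {"A": 1, "B": 1, "A&B": 2}

    def test_four_sets_have_fifteen_classes_covering_universe(self, rng):
        sets = {k: set(rng.integers(0, 40, size=15).tolist()) for k in "ABCD"}
        counts = mn.otu_venn(sets)
        assert len(counts) == 15
        assert sum(counts.values()) == len(set().union(*sets.values()))
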