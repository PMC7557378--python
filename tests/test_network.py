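import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from fec.io import CountTable, FecError
from fec.network import (
    CombinedNetwork,
    EdgeRecord,
    centralities,
    combine_networks,
    genus_table,
    host_network,
    hub_candidates,
    network_summary,
    spearman_edges,
)
from fec.synth import CorrelatedModule, SyntheticConfig, abundant_core_taxa, generate
from conftest import make_taxonomy


def net_from_edges(edges) -> CombinedNetwork:
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, site_count=2, acc_rho_pos=1.0, acc_rho_neg=0.0, sites="x,y")
    return CombinedNetwork(host="H", graph=g)


class TestGenusTable:
    def test_sums_by_genus_and_drops_unassigned(self):
        ct = CountTable(
            ["a1", "a2", "u"], ["s1", "s2"], np.array([[3, 5], [2, 0], [7, 1]])
        )
        tax = make_taxonomy(
            {
                "a1": ("F", "P", "C", "O", "Fa", "Alternaria", "sp1"),
                "a2": ("F", "P", "C", "O", "Fa", "Alternaria", "sp2"),
                "u": ("F", "P", "C", "O", "Fa"),
            }
        )
        gt = genus_table(ct, tax)
        assert gt.taxon_ids == ["Alternaria"]
        assert gt.counts[0].tolist() == [5, 5]

    def test_error_when_nothing_assigned(self):
        ct = CountTable(["u"], ["s"], np.array([[1]]))
        tax = make_taxonomy({"u": ("F",)})
        with pytest.raises(FecError, match="no genus"):
            genus_table(ct, tax)


class TestSpearmanEdges:
    def _ct(self, rows):
        rows = np.asarray(rows)
        return CountTable(
            [f"g{i}" for i in range(rows.shape[0])],
            [f"p{j}" for j in range(rows.shape[1])],
            rows,
        )

    def test_perfect_monotone_pair_retained(self):
        base = np.arange(1, 11)
        other = np.array([5, 2, 8, 1, 9, 3, 7, 4, 6, 10]) * 3
        ct = self._ct(np.vstack([base * 10, base * 20, other]))
        edges = spearman_edges(ct, "siteX", alpha=0.001, min_prevalence=1, scale="raw")
        pairs = {(e.genus_a, e.genus_b): e for e in edges}
        assert ("g0", "g1") in pairs
        assert pairs[("g0", "g1")].rho == pytest.approx(1.0)

    def test_rho_matches_scipy_with_ties(self):
        a = np.array([3, 3, 5, 1, 1, 9, 7, 2, 8, 8, 4, 6])
        b = np.array([2, 5, 5, 1, 4, 8, 8, 2, 9, 7, 3, 6])
        filler = np.arange(12) % 5 + 1
        ct = self._ct(np.vstack([a, b, filler]))
        edges = spearman_edges(ct, "s", alpha=1.0, min_prevalence=1, scale="raw")
        pair = {frozenset((e.genus_a, e.genus_b)): e for e in edges}[
            frozenset(("g0", "g1"))
        ]
        ref = spearmanr(a, b)
        assert pair.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert pair.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_genus_skipped(self):
        ct = self._ct(np.vstack([np.arange(1, 9), np.full(8, 4), np.arange(8, 0, -1)]))
        edges = spearman_edges(ct, "s", alpha=1.0, min_prevalence=1, scale="raw")
        assert all("g1" not in (e.genus_a, e.genus_b) for e in edges)

    def test_low_prevalence_skipped(self):
        rare = np.zeros(10, dtype=int)
        rare[:3] = [5, 2, 9]
        ct = self._ct(np.vstack([np.arange(1, 11), rare, np.arange(10, 0, -1)]))
        edges = spearman_edges(ct, "s", alpha=1.0, min_prevalence=5, scale="raw")
        assert all("g1" not in (e.genus_a, e.genus_b) for e in edges)

    def test_too_few_plants_error(self):
        ct = self._ct(np.ones((3, 4), dtype=int))
        with pytest.raises(FecError, match="at least 5"):
            spearman_edges(ct, "s")


class TestCombineNetworks:
    def test_single_site_pair_dropped(self):
        by_site = {
            "s1": [EdgeRecord("A", "B", "s1", 0.9, 1e-5)],
            "s2": [],
        }
        net = combine_networks(by_site)
        assert net.graph.number_of_edges() == 0

    def test_positive_accumulation(self):
        by_site = {
            s: [EdgeRecord("A", "B", s, r, 1e-5)]
            for s, r in (("s1", 0.8), ("s2", 0.9), ("s3", 0.7))
        }
        net = combine_networks(by_site)
        d = net.graph["A"]["B"]
        assert d["site_count"] == 3
        assert d["acc_rho_pos"] == pytest.approx(2.4)
        assert d["acc_rho_neg"] == 0.0

    def test_mixed_sign_accumulation(self):
        by_site = {
            "s1": [EdgeRecord("A", "B", "s1", 0.8, 1e-5)],
            "s2": [EdgeRecord("A", "B", "s2", -0.75, 1e-5)],
        }
        d = combine_networks(by_site).graph["A"]["B"]
        assert d["acc_rho_pos"] == pytest.approx(0.8)
        assert d["acc_rho_neg"] == pytest.approx(-0.75)
        assert d["site_count"] == 2

    def test_site_order_invariance_and_idempotence(self):
        e = lambda s, r: [EdgeRecord("A", "B", s, r, 1e-5), EdgeRecord("B", "C", s, r, 1e-5)]
        by_site = {"s1": e("s1", 0.5), "s2": e("s2", 0.6), "s3": []}
        n1 = combine_networks(by_site)
        n2 = combine_networks(dict(reversed(list(by_site.items()))))
        assert nx.utils.graphs_equal(n1.graph, n2.graph)
        n3 = combine_networks(by_site)
        assert nx.utils.graphs_equal(n1.graph, n3.graph)


class TestCentralities:
    def test_path_graph(self):
        cent = centralities(net_from_edges([("a", "b"), ("b", "c")]))
        assert cent["degree"].tolist() == [1, 2, 1]
        assert cent["betweenness"].tolist() == [0.0, 1.0, 0.0]

    def test_star_center_max_closeness(self):
        cent = centralities(
            net_from_edges([("hub", leaf) for leaf in "abcd"])
        )
        assert cent["closeness"].idxmax() == "hub"
        assert cent["degree"]["hub"] == 4

    def test_complete_graph_symmetric(self):
        edges = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        cent = centralities(net_from_edges(edges))
        for col in cent.columns:
            assert cent[col].nunique() == 1

    def test_empty_graph_error(self):
        with pytest.raises(FecError):
            centralities(CombinedNetwork("H", nx.Graph()))


class TestHubCandidates:
    def test_star_center_penalized_by_betweenness(self):
        ranked = hub_candidates(net_from_edges([("hub", l) for l in "abcd"]))
        assert ranked.index[0] != "hub"
        # leaf ties broken by id
        assert list(ranked.index[:4]) == ["a", "b", "c", "d"]

    def test_clique_outranks_pendant(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")]
        ranked = hub_candidates(net_from_edges(edges))
        assert ranked.index.get_loc("d") == 3

    def test_planted_module_recovered(self):
        """Genera of a planted association module occupy the top hub ranks."""
        kw = dict(
            hosts=["H"], sites_per_host={"H": ["s1", "s2", "s3"]},
            plants_per_population=40, n_core_taxa=150, n_sporadic_taxa=60, seed=77,
        )
        base = SyntheticConfig(**kw)
        # abundant but not dominant taxa: the very top taxa distort every
        # other genus's relative abundance when they co-vary
        module = abundant_core_taxa(base, 10)[5:]
        cfg = SyntheticConfig(
            **kw, correlated_modules=[CorrelatedModule(module, 0.9)],
        )
        ct, meta, tax, truth = generate(cfg)
        pops = {s: ids for (h, s), ids in meta.populations().items()}
        net = host_network(ct, tax, pops, host="H")
        module_genera = {truth.genus_of[t] for t in module}
        top = set(hub_candidates(net, top_k=5).index)
        assert len(module_genera & top) >= 4


class TestNetworkSummary:
    def test_triangle(self):
        s = network_summary(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert (s["diameter"], s["mean_distance"], s["edge_density"]) == (1, 1.0, 1.0)

    def test_path_of_three(self):
        s = network_summary(net_from_edges([("a", "b"), ("b", "c")]))
        assert s["diameter"] == 2
        assert s["mean_distance"] == pytest.approx(4 / 3)
        assert s["edge_density"] == pytest.approx(2 / 3)

    def test_two_disjoint_edges(self):
        s = network_summary(net_from_edges([("a", "b"), ("c", "d")]))
        assert s["edge_density"] == pytest.approx(2 / 6)
        assert s["diameter"] == 1
        assert s["largest_component"] == 2
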