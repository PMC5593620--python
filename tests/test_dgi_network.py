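import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from pharmsignal import (
    GeneSet,
    bh_adjust,
    build_network,
    export_network,
    filter_significant,
    hypergeometric_enrichment,
    import_network_tsv,
    read_edge_tsv,
    read_gmt,
    simulate_gene_universe,
)


class TestBuildNetwork:
    def test_star_graph(self):
        net = build_network("DIGOXIN", [("DIGOXIN", g) for g in ["G1", "G2", "G3"]])
        assert net.n_nodes == 4
        assert net.n_edges == 3
        assert net.direct_genes == {"G1", "G2", "G3"}
        assert net.indirect_genes == set()

    def test_two_layer_hand_enumeration(self):
        net = build_network(
            "DIGOXIN",
            [("DIGOXIN", "G1"), ("DIGOXIN", "G2")],
            [("G1", "G3"), ("G2", "G3"), ("G1", "G2")],
        )
        assert net.n_nodes == 4
        assert net.n_edges == 5
        assert net.direct_genes == {"G1", "G2"}
        assert net.indirect_genes == {"G3"}

    def test_direct_classification_takes_precedence(self):
        net = build_network("D", [("D", "G1"), ("D", "G2")], [("G1", "G2")])
        assert net.indirect_genes == set()
        assert net.direct_genes == {"G1", "G2"}

    def test_dangling_gene_gene_edge_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_network("D", [("D", "G1")], [("G5", "G6")])
        assert "not incident to a direct gene" in caplog.text
        assert net.n_nodes == 2

    def test_duplicate_and_reversed_edges_collapse(self):
        net = build_network(
            "D", [("D", "G1"), ("G1", "D")], [("G1", "G2"), ("G2", "G1")]
        )
        assert net.n_edges == 2

    def test_empty_direct_set_rejected(self):
        with pytest.raises(ValueError, match="no direct interactions"):
            build_network("D", [("OTHER", "G1")])

    def test_node_count_identity(self):
        net = build_network(
            "D",
            [("D", f"G{i}") for i in range(5)],
            [("G0", f"H{i}") for i in range(7)] + [("G1", "H0")],
        )
        assert net.n_nodes == 1 + len(net.direct_genes) + len(net.indirect_genes)
        assert net.n_edges >= len(net.direct_genes)


def brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by enumerating every draw composition."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


class TestHypergeometricEnrichment:
    def make_universe(self, N):
        return [f"g{i}" for i in range(N)]

    def run_single(self, N, K, n, k):
        bg = self.make_universe(N)
        members = frozenset(bg[:k] + [f"x{i}" for i in range(K - k)])
        # pad set members from background genes outside the query
        members = frozenset(bg[:k] + bg[n : n + (K - k)])
        query = bg[:n]
        results = hypergeometric_enrichment(query, [GeneSet("S", "s", members)], bg)
        return results[0]

    def test_worked_fixture(self):
        r = self.run_single(N=20, K=5, n=4, k=3)
        assert r.p_value == pytest.approx(155 / 4845, abs=5e-7)
        assert r.rate == pytest.approx(3.0)
        assert r.k_overlap == 3

    def test_matches_bruteforce_enumeration_small_universes(self):
        for N in range(2, 13):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(1, min(K, n) + 1):
                        if n + (K - k) > N:
                            continue
                        r = self.run_single(N, K, n, k)
                        assert r.p_value == pytest.approx(
                            brute_force_upper_tail(N, K, n, k), rel=1e-9
                        ), (N, K, n, k)

    def test_query_equal_to_background_is_certain(self):
        bg = self.make_universe(15)
        sets = [GeneSet(f"S{i}", "s", frozenset(bg[i : i + 5])) for i in range(3)]
        for r in hypergeometric_enrichment(bg, sets, bg):
            assert r.k_overlap == r.K
            assert r.rate == pytest.approx(1.0)
            assert r.p_value == pytest.approx(1.0)

    def test_zero_overlap_reports_unit_p(self):
        bg = self.make_universe(20)
        results = hypergeometric_enrichment(
            bg[:4], [GeneSet("S", "s", frozenset(bg[10:15]))], bg
        )
        assert results[0].p_value == 1.0
        assert results[0].rate == 0.0

    def test_query_outside_background_dropped_with_warning(self, caplog):
        bg = self.make_universe(10)
        with caplog.at_level("WARNING"):
            results = hypergeometric_enrichment(
                bg[:3] + ["NOT_A_GENE"], [GeneSet("S", "s", frozenset(bg[:3]))], bg
            )
        assert "outside the background" in caplog.text
        assert results[0].n == 3

    def test_empty_query_after_intersection_rejected(self):
        bg = self.make_universe(10)
        with pytest.raises(ValueError, match="empty"):
            hypergeometric_enrichment(["ZZZ"], [GeneSet("S", "s", frozenset(bg[:3]))], bg)

    def test_results_sorted_by_p(self):
        bg = self.make_universe(50)
        sets = [
            GeneSet("HIT", "s", frozenset(bg[:10])),
            GeneSet("MISS", "s", frozenset(bg[40:45])),
        ]
        results = hypergeometric_enrichment(bg[:10], sets, bg)
        assert [r.set_id for r in results] == ["HIT", "MISS"]
        assert results[0].p_value <= results[0].p_adj <= 1.0


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_equal_spacing_fixture(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_cumulative_minimum_fixture(self):
        assert bh_adjust([0.005, 0.04, 0.04]) == pytest.approx([0.015, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_statsmodels_fdr_bh(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        ours = bh_adjust(list(p))
        _, oracle, _, _ = multipletests(p, method="fdr_bh")
        assert ours == pytest.approx(list(oracle), rel=1e-12)

    def test_monotone_on_sorted_input_and_capped(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.uniform(size=25))
        adj = bh_adjust(list(p))
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert max(adj) <= 1.0

    def test_constant_adjusted_vectors_are_fixed_points(self):
        # the step-up map is not idempotent in general (e.g. (0.02, 0.9,
        # 0.95) maps to (0.06, 0.95, 0.95) and then (0.18, 0.95, 0.95));
        # constant outputs such as the equal-spacing fixture are fixed points
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert bh_adjust(adj) == pytest.approx(adj)


class TestFilterSignificant:
    def make_result(self, set_id, p_adj):
        return type("R", (), {"set_id": set_id, "p_adj": p_adj})()

    def test_threshold_is_strict(self):
        results = [self.make_result("a", 0.049), self.make_result("b", 0.05),
                   self.make_result("c", 0.2)]
        kept = filter_significant(results)
        assert [r.set_id for r in kept] == ["a"]

    def test_degenerate_alphas(self):
        results = [self.make_result("a", 1.0), self.make_result("b", 0.5)]
        assert filter_significant(results) == []
        assert filter_significant(results, alpha=1.01) == results


class TestExportImport:
    @pytest.fixture
    def net(self):
        return build_network(
            "DIGOXIN", [("DIGOXIN", "G1"), ("DIGOXIN", "G2")], [("G1", "G3")]
        )

    def test_sif_star_lines(self, tmp_path):
        star = build_network("D", [("D", g) for g in ["G1", "G2", "G3"]])
        path = tmp_path / "net.sif"
        export_network(star, path, "sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert all("\tinteracts\t" in line for line in lines)

    def test_edge_tsv_roundtrip(self, tmp_path, net):
        path = tmp_path / "net.tsv"
        export_network(net, path, "edge-tsv")
        back = import_network_tsv(path)
        assert set(back.graph.edges) == set(net.graph.edges)
        assert dict(back.graph.nodes(data="role")) == dict(net.graph.nodes(data="role"))

    def test_graphml_preserves_counts_and_roles(self, tmp_path, net):
        import networkx as nx

        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        loaded = nx.read_graphml(path)
        assert loaded.number_of_nodes() == net.n_nodes
        assert loaded.number_of_edges() == net.n_edges
        assert loaded.nodes["G3"]["role"] == "indirect"

    def test_unknown_format_rejected(self, net, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_network(net, tmp_path / "x", "gexf")


class TestFileReaders:
    def test_edge_tsv_header_detected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("drug\tgene\nDIGOXIN\tATP1A1\nDIGOXIN\tATP1B1\n")
        assert read_edge_tsv(path) == [("DIGOXIN", "ATP1A1"), ("DIGOXIN", "ATP1B1")]

    def test_edge_tsv_headerless(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("ATP1A1\tFXYD1\nATP1A1\tATP1B1\n")
        assert read_edge_tsv(path) == [("ATP1A1", "FXYD1"), ("ATP1A1", "ATP1B1")]

    def test_gmt_parsing(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "GO:0015682\tferric iron transport\tTFRC\tCLTC\tTCIRG1\n"
            "GO:0006826\tiron ion transport\tTFRC\tPICALM\n"
        )
        sets = read_gmt(path)
        assert len(sets) == 2
        assert sets[0].set_id == "GO:0015682"
        assert sets[0].members == frozenset({"TFRC", "CLTC", "TCIRG1"})

    def test_gmt_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\ta\tG1\nS1\tb\tG2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)


class TestInjectedEnrichment:
    def test_injected_set_ranks_first_in_most_replicates(self):
        hits = 0
        for seed in range(200):
            bg, collection, query = simulate_gene_universe(
                N=200, n_sets=20, set_size=(10, 30), query_size=30,
                enriched_set_overlap=15, seed=seed,
            )
            results = hypergeometric_enrichment(query, collection, bg)
            best = min(results, key=lambda r: r.p_adj)
            if best.set_id == "SET0000":
                hits += 1
        assert hits >= 190

    def test_null_universe_rarely_produces_tiny_p(self):
        ok = 0
        for seed in range(100):
            bg, collection, query = simulate_gene_universe(
                N=200, n_sets=20, set_size=(10, 30), query_size=30,
                enriched_set_overlap=0, seed=seed,
            )
            results = hypergeometric_enrichment(query, collection, bg)
            if min(r.p_value for r in results) > 0.001:
                ok += 1
        assert ok >= 95
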