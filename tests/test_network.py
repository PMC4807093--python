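"""Residue networks, Girvan-Newman communities and betweenness hubs."""

import numpy as np
import networkx as nx
import pytest

from mdcna.dccm import CorrelationMatrix, ContactOccupancy, filter_correlations
from mdcna.network import (
    annotate_residues,
    build_network,
    centrality_threshold,
    edge_betweenness,
    girvan_newman,
    nearest_rank_threshold,
    node_betweenness,
    CentralityProfile,
)
from mdcna import synthetic as syn
from mdcna import dccm as dccm_mod

from conftest import full_selection
from oracles import brute_force_betweenness, random_connected_graph


def fc_from_corr(c_vals, occ_vals=None, labels=None):
    n = len(c_vals)
    labels = labels or tuple(f"R{i}" for i in range(n))
    c = CorrelationMatrix(np.asarray(c_vals, dtype=float), tuple(labels))
    occ = ContactOccupancy(
        np.ones((n, n)) if occ_vals is None else np.asarray(occ_vals, dtype=float),
        tuple(labels), 10.0,
    )
    return filter_correlations(c, occ)


class TestBuildNetwork:
    def test_path_graph_from_kept_pairs(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        c[1, 2] = c[2, 1] = 0.7
        g = build_network(fc_from_corr(c))
        assert g.number_of_edges() == 2
        assert sorted(g.edges) == [("R0", "R1"), ("R1", "R2")]
        assert np.isclose(g["R0"]["R1"]["path_weight"], -np.log(0.8))

    def test_half_correlation_path_weight(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 0.5
        g = build_network(fc_from_corr(c))
        assert np.isclose(g["R0"]["R1"]["path_weight"], 0.6931471805599453)

    def test_perfect_correlation_clamped_with_warning(self, caplog):
        c = np.ones((2, 2))
        with caplog.at_level("WARNING"):
            g = build_network(fc_from_corr(c))
        assert g["R0"]["R1"]["path_weight"] > 0
        assert any("clamped" in r.message for r in caplog.records)

    def test_isolated_nodes_retained_and_empty_rejected(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        g = build_network(fc_from_corr(c))
        assert set(g.nodes) == {"R0", "R1", "R2"}
        with pytest.raises(ValueError, match="no surviving"):
            build_network(fc_from_corr(np.eye(3)))


class TestBetweenness:
    def test_path_and_star(self):
        path = nx.Graph()
        path.add_edge("a", "b", path_weight=1.0)
        path.add_edge("b", "c", path_weight=1.0)
        prof = node_betweenness(path)
        assert prof.centrality == {"a": 0.0, "b": 1.0, "c": 0.0}

        star = nx.Graph()
        for leaf in "abc":
            star.add_edge("s", leaf, path_weight=1.0)
        assert node_betweenness(star).centrality["s"] == 3.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_connected_graph(rng)
            node_oracle, edge_oracle = brute_force_betweenness(g)
            prof = node_betweenness(g)
            eb = edge_betweenness(g)
            for v in g:
                assert abs(prof.centrality[v] - node_oracle[v]) < 1e-9
            for e in edge_oracle:
                assert abs(eb[e] - edge_oracle[e]) < 1e-9


class TestGirvanNewman:
    def test_two_triangles_with_bridge(self):
        g = nx.Graph()
        tri1 = [("a", "b"), ("b", "c"), ("a", "c")]
        tri2 = [("x", "y"), ("y", "z"), ("x", "z")]
        for u, v in tri1 + tri2 + [("c", "x")]:
            g.add_edge(u, v, corr=0.8, path_weight=-np.log(0.8))
        part = girvan_newman(g)
        groups = {tuple(sorted(part.community_nodes(i))) for i in range(part.n_communities)}
        assert groups == {("a", "b", "c"), ("x", "y", "z")}
        # the removed bridge is the only cut edge
        assert np.isclose(part.total_coupling, 0.8)

    def test_single_triangle_stays_whole(self):
        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, corr=0.9, path_weight=-np.log(0.9))
        part = girvan_newman(g)
        assert part.n_communities == 1 and part.sizes == (3,)

    def test_invariant_to_node_input_order(self):
        rng = np.random.default_rng(1)
        g = random_connected_graph(rng, max_nodes=10, max_edges=14)
        part1 = girvan_newman(g)
        shuffled = nx.Graph()
        nodes = list(g.nodes)
        rng.shuffle(nodes)
        shuffled.add_nodes_from(nodes)
        edges = list(g.edges(data=True))
        rng.shuffle(edges)
        shuffled.add_edges_from(edges)
        part2 = girvan_newman(shuffled)
        assert part1.membership == part2.membership

    def test_recovers_planted_blocks(self, two_block_run):
        design, ensemble, truth = two_block_run
        sel = full_selection(ensemble)
        aligned = dccm_mod.align_to_first_frame(ensemble, sel)
        c = dccm_mod.compute_dccm(aligned, sel)
        occ = dccm_mod.contact_occupancy(aligned, sel, 10.0)
        part = girvan_newman(build_network(dccm_mod.filter_correlations(c, occ)))
        recovered = [part.membership[l] for l in sel.labels]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth["partition"], recovered) >= 0.9

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            girvan_newman(nx.Graph())


class TestCentralityThreshold:
    def test_nearest_rank_on_200_values(self):
        values = {f"n{i:03d}": float(i) for i in range(1, 201)}
        prof = centrality_threshold(CentralityProfile(values), percentile=98.5)
        assert prof.threshold == 197.0
        assert prof.high_set == ("n198", "n199", "n200")
        frac_below = np.mean([v <= prof.threshold for v in values.values()])
        assert frac_below >= 0.985

    def test_all_equal_values_empty_high_set(self):
        prof = centrality_threshold(
            CentralityProfile({f"n{i}": 2.5 for i in range(50)}), 98.5
        )
        assert prof.high_set == ()

    def test_reference_threshold_on_shrunk_profile(self):
        ref_values = {f"n{i:03d}": float(i) for i in range(1, 201)}
        ref = centrality_threshold(CentralityProfile(ref_values), 98.5)
        shrunk = CentralityProfile({k: v * 0.5 for k, v in ref_values.items()})
        applied = centrality_threshold(shrunk, 98.5, reference=ref)
        assert len(applied.high_set) < len(ref.high_set)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_rank_threshold([], 98.5)
        with pytest.raises(ValueError, match="percentile"):
            nearest_rank_threshold([1.0], 150.0)


class TestAnnotateResidues:
    def _setup(self):
        g = nx.Graph()
        # four communities of two nodes each
        pairs = [("ALA1", "ALA2"), ("ALA10", "ALA11"),
                 ("ALA20", "ALA21"), ("ALA30", "ALA31")]
        for u, v in pairs:
            g.add_edge(u, v, corr=0.9, path_weight=-np.log(0.9))
        part = girvan_newman(g)
        prof = CentralityProfile(
            {n: 0.0 for n in g}, 98.5, 0.5,
            high_set=("ALA1", "ALA10", "ALA20", "ALA30"),
        )
        return part, prof

    def test_spine_like_set_spans_four_communities(self):
        part, prof = self._setup()
        report = annotate_residues(
            part, prof, {"R-spine": ["ALA1", "ALA10", "ALA20", "ALA30"]}
        )
        row = report.iloc[0]
        assert row["n_communities"] == 4
        assert row["n_high"] == 4  # all four hubs are in the named set

    def test_unmapped_residues_reported_not_fatal(self):
        part, prof = self._setup()
        report = annotate_residues(part, prof, {"sites": ["ALA1", "ALA999"]})
        assert report.iloc[0]["unmapped"] == "ALA999"
        assert report.iloc[0]["n_mapped"] == 1

    def test_bare_residue_numbers_resolve(self):
        part, prof = self._setup()
        report = annotate_residues(part, prof, {"sites": [1, 10]})
        assert report.iloc[0]["n_mapped"] == 2
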