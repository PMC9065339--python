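"""Residue interaction network construction and topology descriptors.

Closed-form values are frozen from hand enumeration of shortest paths;
random graphs are cross-checked against both the brute-force oracles in
tests/oracles.py and networkx.
"""

from __future__ import annotations

import numpy as np
import pytest

import networkx as nx

from drugsite import (
    ContactRule,
    FixtureSpec,
    avg_nearest_neighbor_degree,
    betweenness,
    build_rin,
    closeness,
    clustering_coefficient,
    compute_all_topology,
    degree,
    eccentricity,
    eigenvector_centrality,
    make_complex,
    read_structure,
)

from . import oracles
from .conftest import graph_from_adjacency, random_graph


def path_graph(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return graph_from_adjacency(adj)


def star_graph(n_leaves):
    adj = np.zeros((n_leaves + 1, n_leaves + 1), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return graph_from_adjacency(adj)


def complete_graph(n):
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    return graph_from_adjacency(adj)


class TestClosedForms:
    def test_path3_betweenness(self):
        g = path_graph(3)
        assert betweenness(g).tolist() == [0.0, 1.0, 0.0]

    def test_star_center_betweenness(self):
        g = star_graph(3)
        cb = betweenness(g)
        assert cb[0] == pytest.approx(3.0)  # 3 leaf pairs route via center
        assert np.all(cb[1:] == 0)

    def test_complete_graph_betweenness_zero(self):
        assert np.all(betweenness(complete_graph(4)) == 0)

    def test_path3_closeness(self):
        cl = closeness(path_graph(3))
        assert cl[1] == pytest.approx(1.0)       # 2/(1+1)
        assert cl[0] == pytest.approx(2.0 / 3.0)  # 2/(1+2)

    def test_isolated_node_closeness_zero(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        g = graph_from_adjacency(adj)
        assert closeness(g)[2] == 0.0

    def test_triangle_eigenvector(self):
        ec = eigenvector_centrality(complete_graph(3))
        assert ec == pytest.approx(np.full(3, 1 / np.sqrt(3)), abs=1e-9)

    def test_star_eigenvector_ratio(self):
        # K1,3: center x_c solves x_c = 3 x_l / λ with λ = √3 → ratio √3
        ec = eigenvector_centrality(star_graph(3))
        assert ec[0] / ec[1] == pytest.approx(np.sqrt(3), abs=1e-8)

    def test_two_disjoint_edges_tie_break(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        ec = eigenvector_centrality(graph_from_adjacency(adj))
        expect = oracles.bf_eigenvector(adj.astype(float))
        # first component in node order receives the mass
        assert ec == pytest.approx(expect, abs=1e-8)
        assert ec[0] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
        assert np.all(ec[2:] == 0)

    def test_path5_eccentricity(self):
        ecc = eccentricity(path_graph(5))
        assert ecc.tolist() == [4, 3, 2, 3, 4]

    def test_complete_graph_eccentricity_one(self):
        assert np.all(eccentricity(complete_graph(5)) == 1)

    def test_star_degree(self):
        d = degree(star_graph(4))
        assert d[0] == 4 and np.all(d[1:] == 1)

    def test_triangle_clustering_one(self):
        assert np.all(clustering_coefficient(complete_graph(3)) == 1.0)

    def test_star_center_clustering_zero(self):
        assert clustering_coefficient(star_graph(3))[0] == 0.0

    def test_star_avg_neighbor_degree(self):
        an = avg_nearest_neighbor_degree(star_graph(3))
        assert an[0] == pytest.approx(1.0)   # neighbours are 3 leaves
        assert an[1] == pytest.approx(3.0)   # single neighbour is the center


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = random_graph(n, float(rng.uniform(0.05, 0.4)), rng)
        adj = g.adjacency.astype(float)
        assert betweenness(g) == pytest.approx(oracles.bf_betweenness(adj), abs=1e-8)
        assert closeness(g) == pytest.approx(oracles.bf_closeness(adj), abs=1e-8)
        assert eccentricity(g) == pytest.approx(oracles.bf_eccentricity(adj), abs=1e-8)
        assert degree(g) == pytest.approx(oracles.bf_degree(adj), abs=1e-8)
        assert clustering_coefficient(g) == pytest.approx(
            oracles.bf_clustering(adj), abs=1e-8)
        assert avg_nearest_neighbor_degree(g) == pytest.approx(
            oracles.bf_avg_neighbor_degree(adj), abs=1e-8)
        if g.n_edges:
            assert eigenvector_centrality(g) == pytest.approx(
                oracles.bf_eigenvector(adj), abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_match_networkx(self, seed):
        """Cross-check against an independently maintained graph library."""
        rng = np.random.default_rng(100 + seed)
        g = random_graph(25, 0.15, rng)
        nxg = nx.from_numpy_array(g.adjacency.astype(int))
        cb_nx = nx.betweenness_centrality(nxg, normalized=False)
        assert betweenness(g) == pytest.approx(
            [cb_nx[i] for i in range(g.n_nodes)], abs=1e-8)
        cl_nx = nx.closeness_centrality(nxg, wf_improved=False)
        assert closeness(g) == pytest.approx(
            [cl_nx[i] for i in range(g.n_nodes)], abs=1e-8)
        cc_nx = nx.clustering(nxg)
        assert clustering_coefficient(g) == pytest.approx(
            [cc_nx[i] for i in range(g.n_nodes)], abs=1e-8)


class TestGraphProperties:
    def test_degree_sum_twice_edges(self, rng):
        for _ in range(10):
            g = random_graph(int(rng.integers(4, 30)), 0.2, rng)
            assert degree(g).sum() == 2 * g.n_edges

    def test_relabelling_invariance(self, rng):
        g = random_graph(20, 0.2, rng)
        perm = rng.permutation(20)
        adj_p = g.adjacency[np.ix_(perm, perm)]
        gp = graph_from_adjacency(adj_p)
        for fn in (betweenness, closeness, eccentricity):
            assert fn(gp) == pytest.approx(fn(g)[perm], abs=1e-10)

    def test_vertex_transitive_constant(self):
        # cycle C6 and complete K5: every metric constant across nodes
        n = 6
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = True
        for g in (graph_from_adjacency(adj), complete_graph(5)):
            for fn in (betweenness, closeness, eccentricity, degree,
                       clustering_coefficient, avg_nearest_neighbor_degree,
                       eigenvector_centrality):
                vals = fn(g)
                assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)


class TestBuildRin:
    def _line_structure(self, tmp_path, xs, cutoff):
        lines = []
        for i, x in enumerate(xs):
            lines.append(
                f"ATOM  {i + 1:>5d}  CA  GLY A{i + 1:>4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}")
        p = tmp_path / "line.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        s = read_structure(p)
        return build_rin(s, ContactRule("c_alpha", cutoff, 1))

    def test_three_on_a_line_path(self, tmp_path):
        g = self._line_structure(tmp_path, [0.0, 6.0, 12.0], cutoff=7.0)
        assert g.n_edges == 2
        assert not g.adjacency[0, 2]

    def test_three_on_a_line_triangle(self, tmp_path):
        g = self._line_structure(tmp_path, [0.0, 6.0, 12.0], cutoff=13.0)
        assert g.n_edges == 3

    def test_min_seq_separation_filter(self, tmp_path):
        g = self._line_structure(tmp_path, [0.0, 6.0, 12.0], cutoff=7.0)
        g2 = self._line_structure(tmp_path, [0.0, 6.0, 12.0], cutoff=7.0)
        # min_sep 2 removes sequence-adjacent contacts
        s = read_structure(tmp_path / "line.pdb")
        g3 = build_rin(s, ContactRule("c_alpha", 7.0, 2))
        assert g.n_edges == g2.n_edges == 2 and g3.n_edges == 0

    def test_edges_match_bruteforce_on_fixture(self, tmp_path, rng):
        spec = FixtureSpec(n_residues=30, geometry="random_coil", seed=5)
        path, _ = make_complex(spec, tmp_path / "coil.pdb")
        s = read_structure(path)
        g = build_rin(s, ContactRule("c_alpha", 7.0, 1))
        coords = np.array([s.residues[k][0].coord for k in s.residue_keys])
        for i in range(30):
            for j in range(i + 1, 30):
                expect = np.linalg.norm(coords[i] - coords[j]) <= 7.0
                assert g.adjacency[i, j] == expect

    def test_any_atom_mode(self, tmp_path):
        spec = FixtureSpec(n_residues=15, with_sidechains=True, seed=2)
        path, _ = make_complex(spec, tmp_path / "sc.pdb")
        s = read_structure(path)
        g = build_rin(s, ContactRule("any_atom", 5.0, 1))
        # brute force over all atom pairs
        keys = s.residue_keys
        for i in range(15):
            for j in range(i + 1, 15):
                dmin = min(
                    np.linalg.norm(a.coord - b.coord)
                    for a in s.residues[keys[i]] for b in s.residues[keys[j]])
                assert g.adjacency[i, j] == (dmin <= 5.0)

    def test_single_residue_rejected(self, tmp_path):
        spec = FixtureSpec(n_residues=1, seed=0)
        path, _ = make_complex(spec, tmp_path / "one.pdb")
        with pytest.raises(ValueError, match="at least 2"):
            build_rin(read_structure(path))


class TestComputeAllTopology:
    def test_path3_full_table(self, tmp_path):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        t = compute_all_topology(graph_from_adjacency(adj))
        assert list(t.columns[-7:]) == ["B", "Cl", "EC", "E", "D", "CC", "AN"]
        mid = t.iloc[1]
        assert mid["B"] == pytest.approx(1.0)
        assert mid["Cl"] == pytest.approx(1.0)
        assert mid["E"] == 1.0 and mid["D"] == 2.0 and mid["CC"] == 0.0
        assert mid["AN"] == pytest.approx(1.0)
        assert mid["EC"] == pytest.approx(np.sqrt(2) / 2, abs=1e-8)

    def test_edgeless_graph_all_zero_but_eccentricity(self):
        t = compute_all_topology(graph_from_adjacency(np.zeros((4, 4), bool)))
        assert (t[["B", "Cl", "EC", "E", "D", "CC", "AN"]].to_numpy() == 0).all()

    def test_column_count(self, rng):
        g = random_graph(10, 0.3, rng)
        t = compute_all_topology(g)
        assert t.shape == (10, 5 + 7)
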