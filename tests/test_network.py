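"""Dynamic network construction, GC weights, paths, communities, betweenness."""

import itertools

import networkx as nx
import numpy as np
import pytest

from allonet import network, synthetic
from allonet.model import FrameEnsemble, Topology, select
from allonet.network import (DynamicNetwork, NodeMap, assign_nodes,
                             build_edges, community_betweenness,
                             detect_communities, gc_from_mi,
                             generalized_correlation, jaccard,
                             mutual_information_knn, optimal_path,
                             sensitivity_scan, suboptimal_paths)


def _bare_nodes(n):
    """NodeMap over n abstract single-atom nodes (for graph-level tests)."""
    return NodeMap([str(i) for i in range(n)],
                   [np.array([i]) for i in range(n)], np.arange(n))


def _net_from_edges(n, edges, gc):
    return DynamicNetwork(_bare_nodes(n), list(edges), np.asarray(gc, dtype=float),
                          cutoff_nm=0.45, persistence=0.75)


class TestAssignNodes:
    def test_chain_one_node_per_residue(self, planted_small):
        top, _, _ = planted_small
        nodes = assign_nodes(top, select(top, "all"))
        assert nodes.n_nodes == top.n_residues

    def test_atp_and_ion_nodes(self):
        names, resids, resnames = [], [], []
        for r in range(1, 31):
            names.append("CA")
            resids.append(r)
            resnames.append("ALA")
        atp_atoms = ["N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9",
                     "C1'", "O4'", "PA", "O1A", "PB", "O1B", "PG", "O1G"]
        for a in atp_atoms:
            names.append(a)
            resids.append(31)
            resnames.append("ATP")
        names.append("MG")
        resids.append(32)
        resnames.append("MG")
        top = Topology.from_atom_records(names, resids, resnames)
        nodes = assign_nodes(
            top, select(top, "resname ALA"),
            ligands={"ATP": select(top, "resname ATP"),
                     "MG": select(top, "resname MG")})
        assert nodes.n_nodes == 30 + 2 + 1
        # partition: every heavy atom of the analyzed selections in exactly one node
        all_assigned = np.concatenate(nodes.atom_sets)
        assert len(all_assigned) == len(set(all_assigned.tolist()))
        heavy = set(np.flatnonzero(top.is_heavy).tolist())
        assert set(all_assigned.tolist()) == heavy
        ring_node = nodes.labels.index("ATP:ring")
        assert len(nodes.atom_sets[ring_node]) == 10
        assert top.atom_names[nodes.anchors[ring_node]] == "N1"
        gamma_node = nodes.labels.index("ATP:gamma")
        assert top.atom_names[nodes.anchors[gamma_node]] == "PG"

    def test_missing_calpha_raises(self):
        top = Topology.from_atom_records(["CB"], [1], ["ALA"])
        with pytest.raises(ValueError, match="no CA"):
            assign_nodes(top, select(top, "all"))


class TestEdges:
    def _scripted_pair(self, frac_in, n_frames=50):
        """Two beads within 0.38 nm in a fraction of frames, 1.0 nm otherwise."""
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        coords = np.zeros((n_frames, 2, 3))
        n_in = int(round(frac_in * n_frames))
        coords[:n_in, 1, 0] = 0.38
        coords[n_in:, 1, 0] = 1.0
        return top, FrameEnsemble(top, coords)

    def test_always_in_contact(self):
        top, ens = self._scripted_pair(1.0)
        nodes = assign_nodes(top, select(top, "all"))
        assert build_edges(ens, nodes, 0.45, 0.75) == [(0, 1)]

    def test_persistence_bracketing(self):
        top, ens = self._scripted_pair(0.70)
        nodes = assign_nodes(top, select(top, "all"))
        assert build_edges(ens, nodes, 0.45, 0.75) == []
        assert build_edges(ens, nodes, 0.45, 0.65) == [(0, 1)]

    def test_matches_brute_force_recount(self, planted_small):
        top, ens, _ = planted_small
        short = ens.subset_frames(slice(0, 50))
        nodes = assign_nodes(top, select(top, "all"))
        edges = set(build_edges(short, nodes, 0.45, 0.75))
        brute = set()
        for i in range(nodes.n_nodes):
            for j in range(i + 1, nodes.n_nodes):
                d = np.linalg.norm(short.coords[:, i] - short.coords[:, j], axis=1)
                if (d <= 0.45).mean() >= 0.75:
                    brute.add((i, j))
        assert edges == brute


class TestGeneralizedCorrelation:
    def _pair_ensemble(self, rho, n, seed=0):
        rng = np.random.default_rng(seed)
        z1 = rng.standard_normal((n, 3))
        z2 = rng.standard_normal((n, 3))
        coords = np.stack([z1, rho * z1 + np.sqrt(1 - rho ** 2) * z2], axis=1) * 0.02
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        return FrameEnsemble(top, coords), assign_nodes(top, select(top, "all"))

    def test_gaussian_closed_form(self):
        # GC = |rho| exactly for jointly Gaussian 3-D displacements
        ens, nodes = self._pair_ensemble(0.6, 3000, seed=1)
        gc = generalized_correlation(ens, nodes, [(0, 1)])[0]
        assert abs(gc - 0.6) < 0.05

    def test_independent_near_zero(self):
        ens, nodes = self._pair_ensemble(0.0, 3000, seed=2)
        assert generalized_correlation(ens, nodes, [(0, 1)])[0] <= 0.1

    def test_duplicated_series_clipped_and_flagged(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((800, 3)) * 0.02
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        ens = FrameEnsemble(top, np.stack([z, z], axis=1))
        nodes = assign_nodes(top, select(top, "all"))
        with pytest.warns(UserWarning, match="clipped"):
            gc = generalized_correlation(ens, nodes, [(0, 1)])[0]
        assert gc < 1.0

    def test_zero_variance_node_raises(self):
        top = Topology.from_atom_records(["CA", "CA"], [1, 2], ["ALA", "ALA"])
        coords = np.zeros((600, 2, 3))
        coords[:, 1] = np.random.default_rng(0).normal(size=(600, 3))
        ens = FrameEnsemble(top, coords)
        nodes = assign_nodes(top, select(top, "all"))
        with pytest.raises(ValueError, match="zero fluctuation"):
            generalized_correlation(ens, nodes, [(0, 1)])


class TestPaths:
    def test_single_edge_path(self):
        net = _net_from_edges(2, [(0, 1)], [0.8])
        assert optimal_path(net, 0, 1) == [0, 1]

    def test_disconnected_returns_none(self):
        net = _net_from_edges(4, [(0, 1), (2, 3)], [0.8, 0.8])
        assert optimal_path(net, 0, 3) is None

    def test_source_equals_sink_rejected(self):
        net = _net_from_edges(2, [(0, 1)], [0.5])
        with pytest.raises(ValueError):
            optimal_path(net, 1, 1)

    def test_floyd_warshall_matches_dijkstra_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = 12
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            edges = sorted(tuple(sorted(e)) for e in g.edges)
            gc = rng.uniform(0.05, 0.95, len(edges))
            net = _net_from_edges(n, edges, gc)
            dm, _ = net.all_pairs()
            gx = net.graph()
            lengths = dict(nx.all_pairs_dijkstra_path_length(gx, weight="dist"))
            for i in range(n):
                for j in range(n):
                    expected = lengths.get(i, {}).get(j, np.inf)
                    assert dm[i, j] == pytest.approx(expected, abs=1e-9)

    def test_suboptimal_exhaustion_flagged(self):
        # diamond graph: exactly 3 simple paths 0->3
        net = _net_from_edges(4, [(0, 1), (0, 2), (1, 3), (2, 3), (1, 2)],
                              [0.9, 0.5, 0.9, 0.5, 0.7])
        ps = suboptimal_paths(net, 0, 3, count=20)
        assert ps.exhausted
        assert len(ps.paths) == 4  # 0-1-3, 0-2-3, 0-1-2-3, 0-2-1-3
        assert all(b >= a - 1e-12 for a, b in zip(ps.costs, ps.costs[1:]))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = 8
            g = nx.gnp_random_graph(n, 0.45, seed=trial + 1)
            if not nx.has_path(g, 0, n - 1):
                continue
            edges = sorted(tuple(sorted(e)) for e in g.edges)
            gc = rng.uniform(0.1, 0.9, len(edges))
            net = _net_from_edges(n, edges, gc)
            d = dict(zip(edges, net.distances))
            # brute-force all simple paths sorted by cost
            gx = net.graph()
            all_paths = []
            for p in nx.all_simple_paths(gx, 0, n - 1):
                cost = sum(d[tuple(sorted((a, b)))] for a, b in zip(p[:-1], p[1:]))
                all_paths.append((cost, p))
            all_paths.sort(key=lambda t: t[0])
            k = min(5, len(all_paths))
            ps = suboptimal_paths(net, 0, n - 1, count=k - 1)
            assert np.allclose(ps.costs, [c for c, _ in all_paths[:k]], atol=1e-9)

    def test_node_occurrence_fractions(self):
        net = _net_from_edges(4, [(0, 1), (0, 2), (1, 3), (2, 3)],
                              [0.9, 0.5, 0.9, 0.5])
        ps = suboptimal_paths(net, 0, 3, count=1)
        occ = ps.node_occurrence()
        assert occ[0] == occ[3] == 1.0
        assert occ[1] == occ[2] == 0.5


class TestCommunities:
    def _two_cliques(self):
        edges, gc = [], []
        for block in (range(10), range(10, 20)):
            for a, b in itertools.combinations(block, 2):
                edges.append((a, b))
                gc.append(0.8)
        edges.append((4, 14))
        gc.append(0.05)
        return _net_from_edges(20, edges, gc)

    def test_two_cliques_recovered(self):
        part = detect_communities(self._two_cliques(), seed=0)
        assert len(part.communities) == 2
        groups = sorted(tuple(v) for v in part.communities.values())
        assert groups == [tuple(range(10)), tuple(range(10, 20))]

    def test_satellite_below_one_percent_discarded(self):
        # 200 nodes: two dense 100-ish cliques... a lone satellite node attached
        # weakly is below the 1% floor and must be discarded
        edges, gc = [], []
        for block in (range(99), range(99, 199)):
            block = list(block)
            for a, b in zip(block[:-1], block[1:]):
                edges.append((a, b))
                gc.append(0.8)
            for a, b in zip(block[:-2], block[2:]):
                edges.append((a, b))
                gc.append(0.7)
        net = _net_from_edges(200, edges, gc)  # node 199 is isolated
        part = detect_communities(net, seed=0)
        assert 199 in part.discarded
        assert 199 not in part.assignment

    def test_deterministic_under_seed(self):
        net = self._two_cliques()
        a = detect_communities(net, seed=3)
        b = detect_communities(net, seed=3)
        assert a.assignment == b.assignment

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(_net_from_edges(0, [], []), seed=0)


class TestBetweenness:
    def _path_graph(self, n):
        edges = [(i, i + 1) for i in range(n - 1)]
        return _net_from_edges(n, edges, [0.5] * (n - 1))

    def test_three_node_path_center(self):
        net = self._path_graph(3)
        part = detect_communities(net, seed=0, min_fraction=0.0)
        part = community_betweenness(net, part)
        assert part.node_betweenness[1] == pytest.approx(1.0)

    def test_five_node_path_center_four_sixths(self):
        net = self._path_graph(5)
        part = detect_communities(net, seed=0, min_fraction=0.0)
        part = community_betweenness(net, part)
        assert part.node_betweenness[2] == pytest.approx(4 / 6)

    def test_complete_graph_zero(self):
        edges = list(itertools.combinations(range(6), 2))
        net = _net_from_edges(6, edges, [0.5] * len(edges))
        part = detect_communities(net, seed=0, min_fraction=0.0)
        part = community_betweenness(net, part)
        assert max(part.node_betweenness.values()) == pytest.approx(0.0)

    def test_matches_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(11)
        g = nx.gnp_random_graph(9, 0.4, seed=5)
        edges = sorted(tuple(sorted(e)) for e in g.edges)
        gc = rng.uniform(0.2, 0.9, len(edges))
        net = _net_from_edges(9, edges, gc)
        part = detect_communities(net, seed=0, min_fraction=0.0)
        part = community_betweenness(net, part)
        oracle = nx.betweenness_centrality(net.graph(), weight="dist",
                                           normalized=True)
        for node, val in part.node_betweenness.items():
            assert val == pytest.approx(oracle[node], abs=1e-12)


class TestInvariants:
    def test_distance_decreasing_in_gc(self):
        net = _net_from_edges(3, [(0, 1), (1, 2)], [0.3, 0.9])
        d = net.distances
        assert d[0] > d[1]

    def test_relabeling_preserves_path_cost(self):
        edges = [(0, 1), (1, 2), (0, 2), (2, 3)]
        gc = [0.8, 0.7, 0.3, 0.9]
        net = _net_from_edges(4, edges, gc)
        perm = [3, 2, 1, 0]
        edges_p = sorted((tuple(sorted((perm[a], perm[b]))), w)
                         for (a, b), w in zip(edges, gc))
        net_p = _net_from_edges(4, [e for e, _ in edges_p], [w for _, w in edges_p])
        d1, _ = net.all_pairs()
        d2, _ = net_p.all_pairs()
        assert d1[0, 3] == pytest.approx(d2[3, 0], abs=1e-12)


class TestSensitivity:
    def test_jaccard_identities(self):
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == pytest.approx(0.5)
        assert jaccard({"A"}, {"B"}) == 0.0
        assert jaccard(set(), set()) == 1.0

    def test_reference_only_grid_all_ones(self, planted_small):
        top, ens, truth = planted_small
        nodes = assign_nodes(top, select(top, "all"))
        df = sensitivity_scan(ens, nodes, 4, 24, cutoffs_nm=[0.45],
                              persistences=[0.75], n_suboptimal=5)
        assert len(df) == 1
        row = df.iloc[0]
        assert row.jaccard_edges == 1.0
        assert row.jaccard_path_residues == 1.0
        assert row.jaccard_path_connections == 1.0

    def test_reference_must_be_on_grid(self, planted_small):
        top, ens, _ = planted_small
        nodes = assign_nodes(top, select(top, "all"))
        with pytest.raises(ValueError, match="reference"):
            sensitivity_scan(ens, nodes, 4, 24, cutoffs_nm=[0.42],
                             persistences=[0.75])
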