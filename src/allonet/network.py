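"""Dynamic correlation networks and allosteric pathway analysis.

A dynamic network has one node per protein residue (anchored at its Cα),
optional ligand pseudo-nodes (an ATP-like ligand splits into a purine-ring
node anchored at N1 and a phosphate/ribose node anchored at the terminal
phosphorus; a metal ion is its own node).  Two nodes are joined by an edge
when any of their heavy atoms stay within a distance cutoff (default
0.45 nm) for at least a persistence fraction of the frames (default 75%).
Edge weights are the generalized correlation coefficient

    GC_ij = sqrt(1 − exp(−2 I_ij / 3)),

with I_ij the mutual information between the two nodes' 3-D anchor
displacement series, estimated with the Kraskov k-nearest-neighbour
estimator (default k = 7, Chebyshev metric).  GC captures nonlinear as well
as linear coupling and equals |ρ| exactly for jointly Gaussian
displacements.  The edge length d_ij = −log GC_ij turns strongly coupled
contacts into short links, so the minimum-total-distance source→sink path
(Floyd–Warshall) is the optimal allosteric pathway; the next-cheapest
simple paths are the suboptimal set.  Louvain modularity communities (on GC
weights), betweenness centrality (on d_ij lengths) and a cutoff sensitivity
scan with Jaccard similarities complete the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from scipy.special import digamma
from sklearn.neighbors import KDTree

from .model import AtomSelection, FrameEnsemble, Topology

__all__ = [
    "NodeMap",
    "DynamicNetwork",
    "PathSet",
    "CommunityPartition",
    "assign_nodes",
    "build_edges",
    "generalized_correlation",
    "mutual_information_knn",
    "build_network",
    "optimal_path",
    "suboptimal_paths",
    "detect_communities",
    "community_betweenness",
    "sensitivity_scan",
    "jaccard",
]

_GC_CLIP = 1.0 - 1e-12

ATP_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9")


@dataclass
class NodeMap:
    """Ordered network nodes with their atom sets and fluctuation anchors."""

    labels: list[str]
    atom_sets: list[np.ndarray]        # heavy atoms owned by each node
    anchors: np.ndarray                # one anchor atom index per node
    topology: Topology = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.intp)
        seen: set[int] = set()
        for s in self.atom_sets:
            overlap = seen & set(int(a) for a in s)
            if overlap:
                raise ValueError(f"atoms {sorted(overlap)} assigned to multiple nodes")
            seen |= set(int(a) for a in s)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def assign_nodes(topology: Topology, protein: AtomSelection,
                 ligands: Optional[dict[str, AtomSelection]] = None) -> NodeMap:
    """One node per protein residue (Cα anchor) plus ligand pseudo-nodes.

    Ligand selections covering an ATP-like residue produce two nodes: the
    purine-ring heavy atoms anchored at N1, and phosphate + ribose heavy
    atoms anchored at the terminal (γ) phosphorus.  Single-atom ligand
    selections (metal ions) become one node.
    """
    labels: list[str] = []
    atom_sets: list[np.ndarray] = []
    anchors: list[int] = []
    heavy = topology.is_heavy
    prot_res = sorted(set(topology.resindices[protein.indices].tolist()))
    prot_atoms = set(protein.indices.tolist())
    for r in prot_res:
        atoms = topology.atoms_of_residue(r)
        atoms = np.array([a for a in atoms if heavy[a] and a in prot_atoms], dtype=np.intp)
        ca = [a for a in topology.atoms_of_residue(r) if topology.atom_names[a] == "CA"]
        if not ca:
            raise ValueError(f"residue {topology.residue_label(r)} has no CA anchor")
        labels.append(topology.residue_label(r))
        atom_sets.append(atoms)
        anchors.append(ca[0])
    for name, sel in (ligands or {}).items():
        idx = np.array([a for a in sel.indices if heavy[a]], dtype=np.intp)
        if len(idx) == 0:
            raise ValueError(f"ligand selection {name!r} has no heavy atoms")
        names = {topology.atom_names[a]: a for a in idx}
        if len(idx) == 1:
            labels.append(name)
            atom_sets.append(idx)
            anchors.append(int(idx[0]))
        elif "N1" in names and "PG" in names:
            ring = np.array([names[a] for a in ATP_RING_ATOMS if a in names], dtype=np.intp)
            rest = np.array([a for a in idx if a not in set(ring.tolist())], dtype=np.intp)
            labels.append(f"{name}:ring")
            atom_sets.append(ring)
            anchors.append(names["N1"])
            labels.append(f"{name}:gamma")
            atom_sets.append(rest)
            anchors.append(names["PG"])
        else:
            raise ValueError(
                f"ligand {name!r} is neither a single atom nor an ATP-like residue "
                "(needs N1 and PG atoms for the two-node split)"
            )
    return NodeMap(labels, atom_sets, np.array(anchors), topology)


@dataclass
class DynamicNetwork:
    """Undirected persistent-contact graph with GC weights and d = −log GC lengths."""

    nodes: NodeMap
    edges: list[tuple[int, int]]
    gc: np.ndarray                 # per-edge generalized correlation in [0, 1)
    cutoff_nm: float
    persistence: float
    _dist_matrix: Optional[np.ndarray] = field(default=None, repr=False)
    _predecessors: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gc = np.clip(np.asarray(self.gc, dtype=float), 0.0, _GC_CLIP)

    @property
    def distances(self) -> np.ndarray:
        return -np.log(np.maximum(self.gc, 1e-300))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.nodes.n_nodes))
        d = self.distances
        for (i, j), w, dist in zip(self.edges, self.gc, d):
            g.add_edge(i, j, gc=float(w), dist=float(dist))
        return g

    def all_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Floyd–Warshall distance and predecessor matrices (cached)."""
        if self._dist_matrix is None:
            n = self.nodes.n_nodes
            mat = np.full((n, n), np.inf)
            d = self.distances
            for (i, j), dist in zip(self.edges, d):
                mat[i, j] = mat[j, i] = dist
            np.fill_diagonal(mat, 0.0)
            dm, pred = floyd_warshall(mat, directed=False, return_predecessors=True)
            self._dist_matrix = dm
            self._predecessors = pred
        return self._dist_matrix, self._predecessors

    def to_tsv(self, path: str) -> None:
        d = self.distances
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\tlabel_i\tlabel_j\tgc\tdist\n")
            for (i, j), w, dist in zip(self.edges, self.gc, d):
                fh.write(f"{i}\t{j}\t{self.nodes.labels[i]}\t{self.nodes.labels[j]}"
                         f"\t{w:.6f}\t{dist:.6f}\n")

    def to_graphml(self, path: str) -> None:
        g = self.graph()
        for i, label in enumerate(self.nodes.labels):
            g.nodes[i]["label"] = label
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Edge construction
# ---------------------------------------------------------------------------

def contact_persistence(ensemble: FrameEnsemble, nodes: NodeMap,
                        cutoff_nm: float, candidate_reach_nm: float = 1.0
                        ) -> dict[tuple[int, int], float]:
    """Fraction of frames each node pair has any heavy-atom pair within cutoff.

    Pairs whose mean anchor separation exceeds ``candidate_reach_nm`` plus
    each node's atom-spread are skipped (they can never reach the cutoff).
    """
    coords = ensemble.coords
    n = nodes.n_nodes
    centers = coords[:, nodes.anchors, :].mean(axis=0)
    spread = np.zeros(n)
    mean_coords = coords.mean(axis=0)
    for k in range(n):
        if len(nodes.atom_sets[k]):
            spread[k] = np.max(np.linalg.norm(
                mean_coords[nodes.atom_sets[k]] - centers[k], axis=1))
    out: dict[tuple[int, int], float] = {}
    for i in range(n):
        ai = nodes.atom_sets[i]
        if len(ai) == 0:
            continue
        for j in range(i + 1, n):
            aj = nodes.atom_sets[j]
            if len(aj) == 0:
                continue
            gap = np.linalg.norm(centers[i] - centers[j]) - spread[i] - spread[j]
            if gap > candidate_reach_nm:
                continue
            diff = coords[:, ai, None, :] - coords[:, None, aj, :]
            dmin = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
            out[(i, j)] = float((dmin <= cutoff_nm).mean())
    return out


def build_edges(ensemble: FrameEnsemble, nodes: NodeMap, cutoff_nm: float = 0.45,
                persistence: float = 0.75) -> list[tuple[int, int]]:
    """Node pairs in heavy-atom contact for at least ``persistence`` of frames."""
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    if not 0 < persistence <= 1:
        raise ValueError("persistence must lie in (0, 1]")
    pers = contact_persistence(ensemble, nodes, cutoff_nm)
    return sorted(pair for pair, p in pers.items() if p >= persistence)


# ---------------------------------------------------------------------------
# Generalized correlation via k-NN mutual information
# ---------------------------------------------------------------------------

def mutual_information_knn(x: np.ndarray, y: np.ndarray, k: int = 7,
                           tree_x: Optional[KDTree] = None,
                           tree_y: Optional[KDTree] = None) -> float:
    """Kraskov estimator (algorithm 1) of I(X; Y), Chebyshev metric, in nats.

    Marginal KD-trees may be passed in to amortize their construction when a
    node participates in many pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n <= k:
        raise ValueError("series must share length > k")
    joint = np.hstack([x, y])
    tree_joint = KDTree(joint, metric="chebyshev")
    # distance to the k-th neighbour (excluding self) in the joint space
    eps = tree_joint.query(joint, k=k + 1)[0][:, -1]
    tree_x = tree_x if tree_x is not None else KDTree(x, metric="chebyshev")
    tree_y = tree_y if tree_y is not None else KDTree(y, metric="chebyshev")
    # strictly-within counts in each marginal
    r = np.nextafter(eps, 0.0)
    nx_ = tree_x.query_radius(x, r, count_only=True) - 1
    ny_ = tree_y.query_radius(y, r, count_only=True) - 1
    return float(digamma(k) + digamma(n)
                 - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1)))


def gc_from_mi(mi: float) -> float:
    """GC = sqrt(1 − exp(−2I/3)) for 3-D node fluctuation series."""
    return float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * max(mi, 0.0) / 3.0),
                                 0.0, _GC_CLIP)))


def generalized_correlation(ensemble: FrameEnsemble, nodes: NodeMap,
                            pairs: Sequence[tuple[int, int]],
                            k_neighbours: int = 7) -> np.ndarray:
    """GC for the requested node pairs from anchor displacement series.

    Displacements are positions minus their time mean; a zero-variance node
    is an error (its GC is undefined), and a pair of identical series is
    clipped just below 1 and flagged with a warning.
    """
    if ensemble.n_frames < 500:
        warnings.warn("fewer than 500 frames: GC estimates will be noisy",
                      stacklevel=2)
    anchor_coords = ensemble.coords[:, nodes.anchors, :]
    disp = anchor_coords - anchor_coords.mean(axis=0)
    needed = sorted({i for p in pairs for i in p})
    for i in needed:
        if np.allclose(disp[:, i, :].std(axis=0), 0.0):
            raise ValueError(f"node {nodes.labels[i]!r} has zero fluctuation variance; "
                             "GC undefined")
    trees = {i: KDTree(disp[:, i, :], metric="chebyshev") for i in needed}
    out = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        if np.array_equal(disp[:, i, :], disp[:, j, :]):
            warnings.warn(f"GC of pair ({nodes.labels[i]}, {nodes.labels[j]}) clipped "
                          "at 1; the series are identical", stacklevel=2)
            out[idx] = _GC_CLIP
            continue
        mi = mutual_information_knn(disp[:, i, :], disp[:, j, :], k=k_neighbours,
                                    tree_x=trees[i], tree_y=trees[j])
        out[idx] = gc_from_mi(mi)
    return out


def build_network(ensemble: FrameEnsemble, nodes: NodeMap, cutoff_nm: float = 0.45,
                  persistence: float = 0.75, k_neighbours: int = 7,
                  weight_ensemble: Optional[FrameEnsemble] = None) -> DynamicNetwork:
    """Edges from persistent contacts, weights from GC of anchor fluctuations.

    ``weight_ensemble`` supports the two-pass convention in which the edge
    topology comes from merged data while GC weights are recomputed per
    analysis window.
    """
    edges = build_edges(ensemble, nodes, cutoff_nm, persistence)
    source = weight_ensemble if weight_ensemble is not None else ensemble
    gc = generalized_correlation(source, nodes, edges, k_neighbours)
    return DynamicNetwork(nodes, edges, gc, cutoff_nm, persistence)


# ---------------------------------------------------------------------------
# Paths
# ---------------------------------------------------------------------------

@dataclass
class PathSet:
    """Optimal plus ranked suboptimal simple paths with node occurrence counts."""

    source: int
    sink: int
    paths: list[list[int]]             # paths[0] is optimal; simple node lists
    costs: list[float]                 # non-decreasing
    exhausted: bool = False            # fewer simple paths exist than requested

    @property
    def optimal(self) -> list[int]:
        return self.paths[0]

    def node_occurrence(self) -> dict[int, float]:
        """Fraction of the path set each node appears in."""
        counts: dict[int, int] = {}
        for p in self.paths:
            for node in p:
                counts[node] = counts.get(node, 0) + 1
        return {n: c / len(self.paths) for n, c in counts.items()}

    def edge_set(self) -> set[tuple[int, int]]:
        out = set()
        for p in self.paths:
            for a, b in zip(p[:-1], p[1:]):
                out.add((min(a, b), max(a, b)))
        return out

    def to_json(self, path: str, labels: Optional[list[str]] = None) -> None:
        import json
        occ = self.node_occurrence()
        payload = {
            "source": self.source, "sink": self.sink,
            "paths": self.paths, "costs": self.costs,
            "exhausted": self.exhausted,
            "node_occurrence": {str(n): f for n, f in sorted(occ.items())},
        }
        if labels:
            payload["labels"] = {str(i): labels[i]
                                 for p in self.paths for i in p}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def optimal_path(network: DynamicNetwork, source: int, sink: int
                 ) -> Optional[list[int]]:
    """Minimum total d_ij path from Floyd–Warshall; None when disconnected."""
    if source == sink:
        raise ValueError("source and sink must differ")
    dm, pred = network.all_pairs()
    if not np.isfinite(dm[source, sink]):
        return None
    path = [sink]
    node = sink
    while node != source:
        node = int(pred[source, node])
        if node < 0:
            return None
        path.append(node)
    return path[::-1]


def suboptimal_paths(network: DynamicNetwork, source: int, sink: int,
                     count: int = 20) -> PathSet:
    """Optimal path plus the ``count`` next-cheapest simple paths (Yen ranking).

    Node occurrence frequency is (paths containing the node) / (paths
    returned).  When fewer simple paths exist, all are returned and the set
    is flagged as exhausted.
    """
    best = optimal_path(network, source, sink)
    if best is None:
        raise ValueError("source and sink are disconnected; no optimal path")
    g = network.graph()
    paths: list[list[int]] = []
    costs: list[float] = []
    exhausted = False
    gen = nx.shortest_simple_paths(g, source, sink, weight="dist")
    try:
        for _ in range(count + 1):
            p = next(gen)
            paths.append([int(x) for x in p])
            costs.append(float(nx.path_weight(g, p, weight="dist")))
    except StopIteration:
        exhausted = True
    # Floyd–Warshall reconstruction and Yen's first path agree on cost; prefer
    # the FW route when costs tie so the matrix and the path set are consistent.
    if abs(costs[0] - float(nx.path_weight(g, best, weight="dist"))) < 1e-9:
        paths[0] = best
    return PathSet(source, sink, paths, costs, exhausted)


# ---------------------------------------------------------------------------
# Communities and betweenness
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Louvain communities over GC weights; sub-1% communities are discarded."""

    assignment: dict[int, int]         # retained node -> community id
    discarded: list[int]               # nodes in communities below the size floor
    seed: int
    node_betweenness: Optional[dict[int, float]] = None
    community_matrix: Optional[np.ndarray] = None   # normalized, symmetric

    @property
    def communities(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for node, com in self.assignment.items():
            out.setdefault(com, []).append(node)
        return {c: sorted(v) for c, v in sorted(out.items())}

    def sizes(self) -> dict[int, int]:
        return {c: len(v) for c, v in self.communities.items()}


def detect_communities(network: DynamicNetwork, seed: int = 0,
                       min_fraction: float = 0.01,
                       resolution: float = 1.0) -> CommunityPartition:
    """Louvain modularity communities on GC edge weights, deterministic per seed.

    Communities smaller than ``min_fraction`` of all nodes are moved to the
    discarded list (they are too small to interpret as subdomains).
    """
    g = network.graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    comms = nx.community.louvain_communities(g, weight="gc", seed=seed,
                                             resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    n = g.number_of_nodes()
    assignment: dict[int, int] = {}
    discarded: list[int] = []
    next_id = 0
    for members in comms:
        if len(members) / n < min_fraction:
            discarded.extend(members)
            continue
        for node in members:
            assignment[node] = next_id
        next_id += 1
    return CommunityPartition(assignment, sorted(discarded), seed)


def community_betweenness(network: DynamicNetwork, partition: CommunityPartition
                          ) -> CommunityPartition:
    """Betweenness centrality over d_ij shortest paths, aggregated by community.

    Node betweenness is the normalized fraction of all-pairs shortest paths
    through each node; community-pair strength sums the edge betweenness of
    edges crossing the pair and is normalized to a maximum of 1.
    """
    g = network.graph()
    node_bt = nx.betweenness_centrality(g, weight="dist", normalized=True)
    edge_bt = nx.edge_betweenness_centrality(g, weight="dist", normalized=True)
    n_comm = len(partition.communities)
    mat = np.zeros((n_comm, n_comm))
    for (a, b), val in edge_bt.items():
        ca = partition.assignment.get(a)
        cb = partition.assignment.get(b)
        if ca is None or cb is None or ca == cb:
            continue
        mat[ca, cb] += val
        mat[cb, ca] += val
    if mat.max() > 0:
        mat = mat / mat.max()
    partition.node_betweenness = {k: float(v) for k, v in node_bt.items()}
    partition.community_matrix = mat
    return partition


# ---------------------------------------------------------------------------
# Sensitivity scan
# ---------------------------------------------------------------------------

def jaccard(a: set, b: set) -> float:
    """Intersection over union; 1 for two empty sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def sensitivity_scan(ensemble: FrameEnsemble, nodes: NodeMap, source: int, sink: int,
                     cutoffs_nm: Sequence[float] = (0.42, 0.45, 0.48),
                     persistences: Sequence[float] = (0.65, 0.75, 0.85),
                     reference: tuple[float, float] = (0.45, 0.75),
                     n_suboptimal: int = 20, k_neighbours: int = 7) -> "pd.DataFrame":
    """Jaccard similarity of edges, path residues and path connections vs reference.

    Rebuilds the network and path set at every (cutoff, persistence) grid
    point and compares against the reference parameters, which must be part
    of the grid.  GC values are cached per pair across grid points (the
    estimator does not depend on the cutoffs).  Grid points where source and
    sink disconnect are recorded with missing similarities rather than
    failing.  Also returns per-node occurrence across grid points.
    """
    import pandas as pd

    if reference[0] not in set(cutoffs_nm) or reference[1] not in set(persistences):
        raise ValueError("reference parameters must be part of the scan grid")
    # persistences at the loosest cutoff bound every other grid point
    pers_all = contact_persistence(ensemble, nodes, max(cutoffs_nm))
    gc_cache: dict[tuple[int, int], float] = {}

    def network_at(cut: float, pers: float) -> DynamicNetwork:
        per_map = contact_persistence(ensemble, nodes, cut)
        edges = sorted(p for p, v in per_map.items() if v >= pers)
        missing = [e for e in edges if e not in gc_cache]
        if missing:
            vals = generalized_correlation(ensemble, nodes, missing, k_neighbours)
            gc_cache.update(dict(zip(missing, vals)))
        gc = np.array([gc_cache[e] for e in edges])
        return DynamicNetwork(nodes, edges, gc, cut, pers)

    ref_net = network_at(*reference)
    ref_paths = suboptimal_paths(ref_net, source, sink, n_suboptimal)
    ref_edges = set(ref_net.edges)
    ref_residues = {n for p in ref_paths.paths for n in p}
    ref_connections = ref_paths.edge_set()

    rows = []
    occurrence: dict[int, list[float]] = {}
    for cut in cutoffs_nm:
        for pers in persistences:
            net = network_at(cut, pers)
            edges = set(net.edges)
            try:
                ps = suboptimal_paths(net, source, sink, n_suboptimal)
                residues = {n for p in ps.paths for n in p}
                connections = ps.edge_set()
                j_res = jaccard(ref_residues, residues)
                j_conn = jaccard(ref_connections, connections)
                for node, f in ps.node_occurrence().items():
                    occurrence.setdefault(node, []).append(f)
                connected = True
            except ValueError:
                j_res = j_conn = np.nan
                connected = False
            rows.append({
                "cutoff_nm": cut, "persistence": pers,
                "is_reference": (cut, pers) == tuple(reference),
                "n_edges": len(edges),
                "jaccard_edges": jaccard(ref_edges, edges),
                "jaccard_path_residues": j_res,
                "jaccard_path_connections": j_conn,
                "connected": connected,
            })
    df = pd.DataFrame(rows)
    df.attrs["node_occurrence"] = {
        n: float(np.mean(v)) for n, v in sorted(occurrence.items())}
    df.attrs["reference"] = tuple(reference)
    return df
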