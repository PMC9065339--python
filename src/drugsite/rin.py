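"""Residue interaction network (RIN) construction and topological descriptors.

The RIN has one node per polymer residue and an undirected, unweighted edge
between residues whose representative atoms (Cα by default, any atom
optionally) lie within a distance cutoff.  Seven per-residue descriptors are
computed on this graph:

========================  ======  =======================================
descriptor                column  definition
========================  ======  =======================================
betweenness               B       Σ over node pairs {s,t} of the fraction
                                  of shortest s–t paths through the node
closeness                 Cl      (n_c − 1) / Σ geodesic distances within
                                  the node's connected component
eigenvector centrality    EC      component of the adjacency matrix's
                                  principal eigenvector (L2-normalised)
eccentricity              E       max geodesic distance to any reachable
                                  node (0 for an isolated node)
degree                    D       number of incident edges
clustering coefficient    CC      realised fraction of edges among
                                  neighbours (0 when degree < 2)
avg neighbour degree      AN      mean degree over neighbours
========================  ======  =======================================

All descriptors are raw (no normalisation beyond the definitions above);
min–max scaling for class comparisons lives in :mod:`drugsite.properties`.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

TOPOLOGY_COLUMNS = ["B", "Cl", "EC", "E", "D", "CC", "AN"]


@dataclass(frozen=True)
class ContactRule:
    """How residue–residue contacts are decided.

    mode 'c_alpha' uses Cα–Cα distance (default cutoff 7.0 Å); 'any_atom'
    uses the minimum over all atom pairs (conventional cutoff 5.0 Å).
    ``min_seq_separation`` is the minimum |i − j| of within-chain positions
    for an edge (1 allows sequence-adjacent residues).
    """

    mode: str = "c_alpha"
    cutoff: float = 7.0
    min_seq_separation: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("c_alpha", "any_atom"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ResidueGraph:
    """Undirected unweighted residue interaction network."""

    nodes: list[ResidueKey]
    adjacency: np.ndarray  # (n, n) bool, symmetric, zero diagonal
    contact_rule: ContactRule | None = None
    structure_id: str = ""
    _adjlist: list[np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.nodes):
            raise ValueError("adjacency size does not match node count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-edges are not allowed")
        self.adjacency = a
        self._adjlist = [np.flatnonzero(row) for row in a]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def neighbors(self, i: int) -> np.ndarray:
        return self._adjlist[i]

    def edge_list(self) -> list[tuple[ResidueKey, ResidueKey]]:
        iu, ju = np.nonzero(np.triu(self.adjacency))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(iu, ju)]


def build_rin(
    s: StructureModel,
    contact_rule: ContactRule | None = None,
    missing_calpha: str = "warn",
) -> ResidueGraph:
    """Build the RIN of a structure under a contact rule.

    Under 'c_alpha' mode a residue without a Cα atom is kept as an
    edge-less node with a warning (``missing_calpha='error'`` raises).
    """
    rule = contact_rule or ContactRule()
    keys = s.residue_keys
    n = len(keys)
    if n < 2:
        raise ValueError("need at least 2 polymer residues to build a network")

    # within-chain ordinal positions for the sequence-separation filter
    pos_in_chain: dict[ResidueKey, int] = {}
    for chain in {k.chain_id for k in keys}:
        for i, k in enumerate([k for k in keys if k.chain_id == chain]):
            pos_in_chain[k] = i

    adj = np.zeros((n, n), dtype=bool)
    if rule.mode == "c_alpha":
        coords = np.full((n, 3), np.nan)
        for i, k in enumerate(keys):
            ca = [a for a in s.residues[k] if a.name == "CA"]
            if ca:
                coords[i] = ca[0].coord
            elif missing_calpha == "error":
                raise ValueError(f"residue {k} has no CA atom")
            else:
                logger.warning("residue %s has no CA atom; kept edge-less", k)
        valid = np.flatnonzero(np.isfinite(coords[:, 0]))
        if valid.size >= 2:
            d = np.linalg.norm(coords[valid, None, :] - coords[None, valid, :], axis=-1)
            close = d <= rule.cutoff
            adj[np.ix_(valid, valid)] = close
    else:  # any_atom
        atom_coords, owners = s.protein_atom_arrays()
        owner_idx = np.array([keys.index(k) for k in owners])
        tree = cKDTree(atom_coords)
        for ai, aj in tree.query_pairs(rule.cutoff):
            adj[owner_idx[ai], owner_idx[aj]] = True
            adj[owner_idx[aj], owner_idx[ai]] = True

    np.fill_diagonal(adj, False)
    # sequence-separation filter (different chains: always allowed)
    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = keys[i], keys[j]
            if ki.chain_id == kj.chain_id:
                if abs(pos_in_chain[ki] - pos_in_chain[kj]) < rule.min_seq_separation:
                    adj[i, j] = adj[j, i] = False
    return ResidueGraph(keys, adj, rule, s.structure_id)


def _bfs(g: ResidueGraph, src: int) -> np.ndarray:
    """Geodesic hop distances from ``src`` (-1 for unreachable nodes)."""
    dist = np.full(g.n_nodes, -1, dtype=int)
    dist[src] = 0
    q = deque([src])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def betweenness(g: ResidueGraph) -> np.ndarray:
    """Shortest-path betweenness: Σ over unordered pairs {s,t} (s,t ≠ u) of
    σ_st(u)/σ_st, computed with Brandes' accumulation.  Raw counts, not
    normalised."""
    n = g.n_nodes
    cb = np.zeros(n)
    for s in range(n):
        # single-source shortest-path counting
        dist = np.full(n, -1, dtype=int)
        sigma = np.zeros(n)
        dist[s], sigma[s] = 0, 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for v in g.neighbors(u):
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    return cb / 2.0  # each unordered pair was counted from both endpoints


def closeness(g: ResidueGraph) -> np.ndarray:
    """Component-local closeness (n_c − 1)/Σ dist; isolated nodes get 0."""
    out = np.zeros(g.n_nodes)
    for u in range(g.n_nodes):
        dist = _bfs(g, u)
        reach = dist > 0
        total = int(dist[reach].sum())
        if total > 0:
            out[u] = reach.sum() / total
    return out


def eccentricity(g: ResidueGraph) -> np.ndarray:
    """Max geodesic distance to any reachable node; isolated node → 0."""
    out = np.zeros(g.n_nodes, dtype=float)
    for u in range(g.n_nodes):
        dist = _bfs(g, u)
        out[u] = float(dist.max()) if (dist > 0).any() else 0.0
    return out


def degree(g: ResidueGraph) -> np.ndarray:
    return g.adjacency.sum(axis=1).astype(float)


def clustering_coefficient(g: ResidueGraph) -> np.ndarray:
    """Fraction of realised edges among each node's neighbours; degree < 2 → 0."""
    a = g.adjacency
    out = np.zeros(g.n_nodes)
    for u in range(g.n_nodes):
        nb = g.neighbors(u)
        k = nb.size
        if k < 2:
            continue
        links = a[np.ix_(nb, nb)].sum() / 2
        out[u] = links / (k * (k - 1) / 2)
    return out


def avg_nearest_neighbor_degree(g: ResidueGraph) -> np.ndarray:
    """Mean degree over a node's neighbours; degree-0 node → 0."""
    deg = degree(g)
    out = np.zeros(g.n_nodes)
    for u in range(g.n_nodes):
        nb = g.neighbors(u)
        if nb.size:
            out[u] = deg[nb].mean()
    return out


def _components(g: ResidueGraph) -> list[np.ndarray]:
    seen = np.zeros(g.n_nodes, dtype=bool)
    comps = []
    for u in range(g.n_nodes):
        if not seen[u]:
            dist = _bfs(g, u)
            members = np.flatnonzero(dist >= 0)
            seen[members] = True
            comps.append(members)
    return comps


def eigenvector_centrality(
    g: ResidueGraph, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Principal eigenvector of the adjacency matrix, nonnegative, L2 = 1.

    Power iteration on A + I (same eigenvectors; the shift guarantees
    convergence on bipartite components).  On a disconnected graph the
    component with the largest spectral radius receives all the mass; exact
    ties are broken in favour of the earliest component in node order.  An
    edgeless graph yields the zero vector with a warning.
    """
    n = g.n_nodes
    if g.n_edges == 0:
        warnings.warn("eigenvector centrality of an edgeless graph is all-zero")
        return np.zeros(n)

    a = g.adjacency.astype(float)
    best: tuple[float, int, np.ndarray] | None = None
    for ci, members in enumerate(_components(g)):
        if members.size == 1:
            lam = 0.0
            vec = np.ones(1)
        else:
            sub = a[np.ix_(members, members)] + np.eye(members.size)
            x = np.full(members.size, 1.0 / np.sqrt(members.size))
            for it in range(max_iter):
                y = sub @ x
                y /= np.linalg.norm(y)
                if np.linalg.norm(y - x) < tol:
                    x = y
                    break
                x = y
            else:
                raise RuntimeError(
                    f"power iteration did not converge in {max_iter} iterations"
                )
            lam = float(x @ (sub @ x)) - 1.0  # undo the +I shift
            vec = np.abs(x)
        # strictly-larger radius wins; ties keep the earlier component
        if best is None or lam > best[0] + 1e-12:
            best = (lam, ci, members.copy())
            best_vec = vec
    out = np.zeros(n)
    out[best[2]] = best_vec
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def compute_all_topology(g: ResidueGraph) -> pd.DataFrame:
    """One row per residue with the 7 descriptors in fixed column order
    (B, Cl, EC, E, D, CC, AN), keyed by structure/chain/resnum/icode."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # edgeless-graph EC convention
        ec = eigenvector_centrality(g)
    data = {
        "structure_id": g.structure_id,
        "chain": [k.chain_id for k in g.nodes],
        "resnum": [k.residue_number for k in g.nodes],
        "icode": [k.insertion_code for k in g.nodes],
        "resname": [k.residue_name for k in g.nodes],
        "B": betweenness(g),
        "Cl": closeness(g),
        "EC": ec,
        "E": eccentricity(g),
        "D": degree(g),
        "CC": clustering_coefficient(g),
        "AN": avg_nearest_neighbor_degree(g),
    }
    return pd.DataFrame(data)
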