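"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: betweenness is computed
from the pairwise path-count identity sigma_st(u) = sigma_su * sigma_ut
(when u lies on a shortest s-t path) rather than Brandes accumulation,
eigenvector centrality comes from a dense eigendecomposition, AUC from the
Mann-Whitney pair count, and binding sites from a plain double loop over
every atom pair.
"""

from __future__ import annotations

import numpy as np


def bf_distances_and_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs geodesic distances and shortest-path counts by BFS levels.

    dist[i, j] = -1 for unreachable pairs; sigma[i, j] = 0 there.
    """
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=int)
    sigma = np.zeros((n, n))
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if dist[s, v] < 0:
                        dist[s, v] = d + 1
                        nxt.append(v)
            # accumulate counts level by level (a node may enter nxt twice)
            for v in set(nxt):
                sigma[s, v] = sum(sigma[s, u] for u in nbrs[v]
                                  if dist[s, u] == d)
            frontier = sorted(set(nxt))
            d += 1
    return dist, sigma


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist, sigma = bf_distances_and_counts(adj)
    cb = np.zeros(n)
    for u in range(n):
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == u or t == u or dist[s, t] < 0:
                    continue
                if dist[s, u] >= 0 and dist[u, t] >= 0 and \
                        dist[s, u] + dist[u, t] == dist[s, t]:
                    total += sigma[s, u] * sigma[u, t] / sigma[s, t]
        cb[u] = total
    return cb


def bf_closeness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist, _ = bf_distances_and_counts(adj)
    out = np.zeros(n)
    for u in range(n):
        reach = [dist[u, v] for v in range(n) if v != u and dist[u, v] > 0]
        if reach:
            out[u] = len(reach) / sum(reach)
    return out


def bf_eccentricity(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist, _ = bf_distances_and_counts(adj)
    return np.array([max((dist[u, v] for v in range(n) if dist[u, v] > 0),
                         default=0) for u in range(n)], dtype=float)


def bf_degree(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(float)


def bf_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for u in range(n):
        nb = np.flatnonzero(adj[u])
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for i in range(k) for j in range(i + 1, k)
                    if adj[nb[i], nb[j]])
        out[u] = links / (k * (k - 1) / 2)
    return out


def bf_avg_neighbor_degree(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    deg = bf_degree(adj)
    out = np.zeros(n)
    for u in range(n):
        nb = np.flatnonzero(adj[u])
        if len(nb):
            out[u] = deg[nb].mean()
    return out


def _components(adj: np.ndarray) -> list[np.ndarray]:
    dist, _ = bf_distances_and_counts(adj)
    seen = np.zeros(adj.shape[0], dtype=bool)
    comps = []
    for u in range(adj.shape[0]):
        if not seen[u]:
            members = np.flatnonzero(dist[u] >= 0)
            seen[members] = True
            comps.append(members)
    return comps


def bf_eigenvector(adj: np.ndarray) -> np.ndarray:
    """Dense-eigendecomposition oracle with the same disconnected-graph
    convention as the implementation: the component with the largest
    spectral radius carries the mass, ties broken by earliest component."""
    n = adj.shape[0]
    if adj.sum() == 0:
        return np.zeros(n)
    best = None
    for ci, members in enumerate(_components(adj)):
        if len(members) == 1:
            lam, vec = 0.0, np.ones(1)
        else:
            sub = adj[np.ix_(members, members)].astype(float)
            w, v = np.linalg.eigh(sub)
            lam = float(w[-1])
            vec = np.abs(v[:, -1])
        if best is None or lam > best[0] + 1e-12:
            best = (lam, members, vec)
    out = np.zeros(n)
    out[best[1]] = best[2]
    return out / np.linalg.norm(out)


def bf_binding_sites(
    protein_coords: np.ndarray,
    owner_index: np.ndarray,
    ligand_coords: np.ndarray,
    n_residues: int,
    cutoff: float,
) -> np.ndarray:
    """O(N_atoms x M_atoms) double-loop site labelling (inclusive cutoff)."""
    labels = np.zeros(n_residues, dtype=int)
    for coord, res in zip(protein_coords, owner_index):
        for lig in ligand_coords:
            if np.sqrt(np.sum((coord - lig) ** 2)) <= cutoff:
                labels[res] = 1
                break
    return labels


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U: P(score_pos > score_neg) + ties/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
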