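"""Topological outcome measures on weighted functional networks.

All four measures are computed on the (fully weighted, unthresholded)
PLI matrix of a cycle:

* weighted clustering coefficient (geometric-mean triangle form, on
  weights rescaled by the maximum), normalized against edge-weight
  shuffled surrogates -> ``gamma``;
* Newman modularity ``Q`` of the best partition found by seeded Louvain
  restarts;
* algebraic connectivity, the second-smallest eigenvalue of the
  weighted Laplacian ``L = D - W`` (0 iff disconnected);
* leaf number of the maximum-weight spanning tree (degree-1 tree
  nodes), raw and as a fraction of ``n - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

__all__ = [
    "GraphMetrics",
    "weighted_clustering",
    "normalized_gamma",
    "modularity",
    "algebraic_connectivity",
    "mst_leaf_number",
    "graph_metrics",
]


@dataclass
class GraphMetrics:
    gamma: float
    modularity_q: float
    algebraic_connectivity: float
    mst_leaf_number: int
    mst_leaf_fraction: float


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def weighted_clustering(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node and mean weighted clustering coefficient.

    Geometric-mean formulation: with ``w_hat = W / max(W)``,
    ``c_i = sum_{j,k} (w_hat_ij w_hat_ik w_hat_jk)^(1/3) / (k_i (k_i - 1))``
    where ``k_i`` counts node i's neighbours.  Nodes with fewer than two
    neighbours get 0; NaN is returned for n < 3.
    """
    W = _check_weights(W)
    n = W.shape[0]
    if n < 3 or W.max() == 0:
        return np.full(n, np.nan), float("nan")
    w_hat = W / W.max()
    cr = np.cbrt(w_hat)
    tri = np.diagonal(cr @ cr @ cr)  # 2x the triangle weight sum per node
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def normalized_gamma(W: np.ndarray, n_surrogates: int = 50,
                     seed: int = 0) -> float:
    """Mean clustering divided by that of edge-weight permuted surrogates.

    Surrogates permute the upper-triangle weights (preserving the weight
    distribution, density and symmetry); ``gamma`` is ~1 for weight
    structure compatible with random placement, > 1 for genuinely
    clustered networks, and invariant to weight rescaling.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    W = _check_weights(W)
    n = W.shape[0]
    _, c_obs = weighted_clustering(W)
    iu = np.triu_indices(n, 1)
    weights = W[iu]
    rng = np.random.default_rng(seed)
    c_surr = np.empty(n_surrogates)
    S = np.zeros_like(W)
    for s in range(n_surrogates):
        perm = rng.permutation(weights)
        S[:] = 0.0
        S[iu] = perm
        S += S.T
        _, c_surr[s] = weighted_clustering(S)
    mean_surr = float(np.mean(c_surr))
    if not mean_surr > 0:
        return float("nan")
    return c_obs / mean_surr


def modularity(W: np.ndarray, seed: int = 0, n_restarts: int = 10
               ) -> tuple[list[set[int]], float]:
    """Best-of-``n_restarts`` seeded Louvain partition and its Newman Q."""
    W = _check_weights(W)
    if W.shape[0] == 0:
        raise ValueError("empty graph")
    G = nx.from_numpy_array(W)
    best_q, best_part = -np.inf, None
    for i in range(n_restarts):
        part = nx.community.louvain_communities(G, weight="weight",
                                                seed=seed + i)
        q = nx.community.modularity(G, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return [set(c) for c in best_part], float(best_q)


def algebraic_connectivity(W: np.ndarray) -> float:
    """Second-smallest eigenvalue of the weighted Laplacian D - W."""
    W = _check_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    L = np.diag(W.sum(axis=1)) - W
    vals = scipy.linalg.eigh(L, eigvals_only=True, subset_by_index=[0, 1])
    return float(max(vals[1], 0.0))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def mst_leaf_number(W: np.ndarray) -> tuple[int, float]:
    """Leaf count (and fraction of n-1) of the maximum-weight spanning tree.

    Kruskal on edges sorted by (-weight, i, j): equal-weight ties go to
    the smaller node indices, making the tree deterministic.  Raises on
    disconnected input, naming the stranded component.
    """
    W = _check_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, 1)
    mask = W[iu, ju] > 0
    edges = sorted(zip(-W[iu, ju][mask], iu[mask], ju[mask]))
    uf = _UnionFind(n)
    deg = np.zeros(n, dtype=int)
    n_edges = 0
    for negw, i, j in edges:
        if uf.union(int(i), int(j)):
            deg[i] += 1
            deg[j] += 1
            n_edges += 1
            if n_edges == n - 1:
                break
    if n_edges < n - 1:
        roots = {uf.find(i) for i in range(n)}
        comp = [sorted(i for i in range(n) if uf.find(i) == r) for r in roots]
        raise ValueError(f"graph is disconnected; components: {comp}")
    leaves = int((deg == 1).sum())
    return leaves, leaves / (n - 1)


def graph_metrics(W: np.ndarray, n_surrogates: int = 50, seed: int = 0
                  ) -> GraphMetrics:
    """All four topology measures of one weighted (PLI) network."""
    _, q = modularity(W, seed=seed)
    leaves, frac = mst_leaf_number(W)
    return GraphMetrics(
        gamma=normalized_gamma(W, n_surrogates=n_surrogates, seed=seed),
        modularity_q=q,
        algebraic_connectivity=algebraic_connectivity(W),
        mst_leaf_number=leaves,
        mst_leaf_fraction=frac,
    )
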