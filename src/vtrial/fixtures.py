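"""Synthetic inputs with known ground truth.

Everything the analysis modules compute can be checked here without any
network simulation: phase-lagged oscillators with analytically known
PLI, and a library of small graphs whose clustering, Laplacian spectrum,
maximum-weight spanning tree and best bipartition modularity are
computed by independent exhaustive algorithms (triangle enumeration,
dense eigendecomposition, spanning-tree enumeration, partition
enumeration) — deliberately separate code paths from the fast
implementations in :mod:`vtrial.graphs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["make_lagged_oscillators", "ToyGraph", "make_toy_graphs"]


def make_lagged_oscillators(n: int, freq: float, lags: np.ndarray,
                            noise_sd: float, duration: float, fs: float,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Common sinusoid with per-channel phase offsets plus white noise.

    ``lags`` gives one phase offset (radians) per channel.  Returns
    ``(signals time x n, true PLI matrix)``: at zero noise, a channel
    pair's PLI is 1 if its offset difference is nonzero mod pi, else 0.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.shape != (n,):
        raise ValueError("lags must give one phase offset per channel")
    if fs < 4 * freq:
        raise ValueError(f"fs = {fs} Hz would alias a {freq} Hz oscillation; "
                         "need fs >= 4*freq")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs
    signals = np.sin(2 * np.pi * freq * t[:, None] + lags[None, :])
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, signals.shape)
    dlag = np.mod(lags[:, None] - lags[None, :], np.pi)
    true_pli = (np.abs(dlag) > 1e-12) & (np.abs(dlag - np.pi) > 1e-12)
    true_pli = true_pli.astype(float)
    np.fill_diagonal(true_pli, 0.0)
    return signals, true_pli


@dataclass
class ToyGraph:
    """A small graph with exhaustively computed reference metrics."""

    name: str
    W: np.ndarray
    clustering_mean: float      # triangle-enumeration oracle
    lambda2: float              # dense eigendecomposition oracle
    mst_leaves: int             # spanning-tree enumeration oracle
    best2_modularity: float     # best 2-partition, enumeration oracle
    best2_partition: frozenset = field(default=frozenset())


# ---------------------------------------------------------------- oracles

def _brute_clustering(W: np.ndarray) -> float:
    """Mean geometric-mean weighted clustering via explicit triple loops."""
    n = W.shape[0]
    w = W / W.max()
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h:
                    total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        cs.append(total / (k * (k - 1)))
    return float(np.mean(cs))


def _brute_lambda2(W: np.ndarray) -> float:
    L = np.diag(W.sum(axis=1)) - W
    return float(np.sort(np.linalg.eigvalsh(L))[1])


def _brute_mst_leaves(W: np.ndarray) -> int:
    """Enumerate all spanning trees; leaves of the max-weight one.

    Ties resolved toward lexicographically smallest edge set, matching
    the Kruskal tie-break (smaller node indices first).
    """
    n = W.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if W[i, j] > 0]
    best = None
    for subset in combinations(edges, n - 1):
        # connectivity check by union of edges
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for (i, j) in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        weight = sum(W[i, j] for i, j in subset)
        key = (weight, [e for e in subset])
        if best is None or weight > best[0] + 1e-12 or (
                abs(weight - best[0]) <= 1e-12 and list(subset) < best[1]):
            best = (weight, list(subset))
    deg = np.zeros(n, dtype=int)
    for i, j in best[1]:
        deg[i] += 1
        deg[j] += 1
    return int((deg == 1).sum())


def _brute_best_bipartition(W: np.ndarray) -> tuple[float, frozenset]:
    """Enumerate all 2-partitions; maximize weighted Newman modularity."""
    n = W.shape[0]
    two_m = W.sum()
    strength = W.sum(axis=1)
    best_q, best_set = -np.inf, frozenset()
    for bits in range(1, 2 ** (n - 1)):  # node 0 always in community A
        A = frozenset(i for i in range(n) if (i == 0) or (bits >> (i - 1)) & 1)
        q = 0.0
        for comm in (A, frozenset(range(n)) - A):
            nodes = list(comm)
            if not nodes:
                continue
            w_in = W[np.ix_(nodes, nodes)].sum()
            s = strength[nodes].sum()
            q += w_in / two_m - (s / two_m) ** 2
        if q > best_q:
            best_q, best_set = q, A
    return float(best_q), best_set


# ------------------------------------------------------------- the library

def _graph(name: str, W: np.ndarray) -> ToyGraph:
    W = np.asarray(W, dtype=float)
    q, part = _brute_best_bipartition(W)
    return ToyGraph(
        name=name,
        W=W,
        clustering_mean=_brute_clustering(W),
        lambda2=_brute_lambda2(W),
        mst_leaves=_brute_mst_leaves(W),
        best2_modularity=q,
        best2_partition=part,
    )


def make_toy_graphs() -> dict[str, ToyGraph]:
    """Named library of small graphs with precomputed reference values.

    Includes a triangle, a 6-node star, a 3-node path, K5, two 5-cliques
    joined by one edge, and a seeded random weighted 8-node graph.
    """
    graphs: dict[str, ToyGraph] = {}

    tri = np.ones((3, 3)) - np.eye(3)
    graphs["triangle"] = _graph("triangle", tri)

    star = np.zeros((6, 6))
    star[0, 1:] = star[1:, 0] = 1.0
    graphs["star6"] = _graph("star6", star)

    path = np.zeros((3, 3))
    path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
    graphs["path3"] = _graph("path3", path)

    k5 = np.ones((5, 5)) - np.eye(5)
    graphs["K5"] = _graph("K5", k5)

    two = np.zeros((10, 10))
    for offset in (0, 5):
        two[offset:offset + 5, offset:offset + 5] = 1.0
    np.fill_diagonal(two, 0.0)
    two[4, 5] = two[5, 4] = 1.0
    graphs["two_cliques"] = _graph("two_cliques", two)

    rng = np.random.default_rng(42)
    n = 8
    W = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < 0.5
    weights = np.round(rng.random(len(iu[0])), 3) * present
    W[iu] = weights
    W += W.T
    # ensure connectivity with a weak ring
    for i in range(n):
        j = (i + 1) % n
        if W[i, j] == 0:
            W[i, j] = W[j, i] = 0.05
    graphs["random8"] = _graph("random8", W)

    return graphs
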