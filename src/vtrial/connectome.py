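"""Structural network the masses live on.

A :class:`Connectome` carries the original weight matrix ``W0`` (set at
load/generation time and never modified) and the current matrix ``W``
that degeneration erodes, plus the two network-level coupling constants:
a single conduction delay ``T_delay`` (ms, identical for every edge) and
a global gain ``g``.  Matrices are symmetric, non-negative, zero on the
diagonal; coupling between two masses, where present, is reciprocal and
excitatory.

Because the 78-region DTI connectome used as the reference topology is
not redistributable, :func:`generate_synthetic_connectome` builds a
sparse, modular, hub-bearing binary graph with the same gross character
(78 cortical regions, identical initial coupling strengths on all edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "load_connectome",
    "generate_synthetic_connectome",
    "normalized_node_strength",
    "NODE_DRIVE",
]

# default summed coupling drive per mass, g * <degree>; the dynamical
# operating point of the masses is set by this product, so synthetic
# connectomes of any size are generated with gain NODE_DRIVE / <k>
NODE_DRIVE = 43.2


@dataclass
class Connectome:
    labels: list[str]
    W0: np.ndarray
    W: np.ndarray
    T_delay: float = 40.0  # ms
    g: float = 4.2
    modules: np.ndarray | None = None  # planted module id per node, if generated
    hubs: np.ndarray | None = None     # designated hub indices, if generated
    # surviving fraction of each node's intra-mass excitatory synapses;
    # degeneration erodes it together with the long-range weights
    intra_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        _validate_matrix(self.W0)
        _validate_matrix(self.W)
        if self.W.shape != self.W0.shape:
            raise ValueError("W and W0 must have the same shape")
        if len(self.labels) != self.W0.shape[0]:
            raise ValueError("label count does not match matrix size")
        if self.g < 0 or self.T_delay < 0:
            raise ValueError("g and T_delay must be >= 0")
        if self.intra_scale is None:
            self.intra_scale = np.ones(self.W0.shape[0])
        else:
            self.intra_scale = np.asarray(self.intra_scale, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.W0.shape[0]

    def degrees(self, original: bool = True) -> np.ndarray:
        """Binary degree per node (count of incident edges)."""
        M = self.W0 if original else self.W
        return (M > 0).sum(axis=1)

    def copy(self) -> "Connectome":
        return Connectome(list(self.labels), self.W0.copy(), self.W.copy(),
                          self.T_delay, self.g,
                          None if self.modules is None else self.modules.copy(),
                          None if self.hubs is None else self.hubs.copy(),
                          self.intra_scale.copy())

    def node_strength_table(self, cycle: int | None = None) -> pd.DataFrame:
        """Tidy per-node structural damage table."""
        df = pd.DataFrame({
            "node": np.arange(self.n_nodes),
            "label": self.labels,
            "degree0": self.degrees(original=True),
            "strength_ratio": normalized_node_strength(self.W, self.W0),
        })
        if cycle is not None:
            df["cycle"] = cycle
        return df


def _validate_matrix(W: np.ndarray) -> None:
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"connectome matrix must be square, got shape {W.shape}")
    bad = np.argwhere(~np.isfinite(W))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-finite connectome entry at row {i}, column {j}")
    bad = np.argwhere(W < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"negative connectome entry at row {i}, column {j}")


def _symmetrize(W: np.ndarray) -> np.ndarray:
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return W


def load_connectome(path, g: float = 4.2, T_delay: float = 40.0) -> Connectome:
    """Read a square weight matrix from CSV/TSV.

    An optional single header row supplies region labels.  The matrix is
    symmetrized by taking the elementwise maximum of the two triangles
    and the diagonal is zeroed; ``W`` starts as a copy of ``W0``.
    """
    first = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
    has_header = first.iloc[0].map(
        lambda v: isinstance(v, str) and not _is_number(v)).any()
    df = pd.read_csv(path, sep=None, engine="python",
                     header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header \
        else [f"region_{i}" for i in range(df.shape[1])]
    try:
        W0 = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric connectome entries in {path}: {err}") from None
    _validate_matrix(W0)
    W0 = _symmetrize(W0)
    return Connectome(labels, W0, W0.copy(), T_delay=T_delay, g=g)


def save_connectome(conn: Connectome, path, current: bool = False) -> None:
    """Write the original (or current) matrix as labelled CSV."""
    M = conn.W if current else conn.W0
    pd.DataFrame(M, columns=conn.labels).to_csv(path, index=False)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def generate_synthetic_connectome(
    n_nodes: int = 78,
    n_modules: int = 6,
    intra_p: float = 0.45,
    inter_p: float = 0.03,
    hub_count: int = 8,
    hub_extra_p: float = 0.25,
    seed: int = 0,
    g: float | None = None,
    T_delay: float = 40.0,
) -> Connectome:
    """Generate a sparse, modular, hub-bearing binary connectome.

    Nodes are split into ``n_modules`` near-equal planted modules wired
    with probability ``intra_p`` inside and ``inter_p`` between modules;
    ``hub_count`` designated hubs (spread across modules) gain extra
    links to every other node with probability ``hub_extra_p``.  All
    edges have identical unit strength.  Regenerates the graph (up to
    100 attempts, deterministically from ``seed``) until connected.

    When ``g`` is None the global gain is set to ``NODE_DRIVE / <k>``
    (``<k>`` the realized mean degree), holding the typical summed
    coupling input per mass constant across connectome sizes, so that
    down-scaled networks sit at the same dynamical operating point as
    the default 78-node graph.
    """
    if not (0 <= intra_p <= 1 and 0 <= inter_p <= 1 and 0 <= hub_extra_p <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_modules < 1 or n_modules > n_nodes:
        raise ValueError("n_modules must be between 1 and n_nodes")
    if hub_count >= n_nodes:
        raise ValueError("hub_count must be smaller than n_nodes")

    module = np.arange(n_nodes) % n_modules        # round-robin assignment
    hubs = np.linspace(0, n_nodes - 1, hub_count).astype(int) if hub_count else \
        np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        same = module[:, None] == module[None, :]
        p = np.where(same, intra_p, inter_p).astype(float)
        if hub_count:
            hub_mask = np.zeros(n_nodes, dtype=bool)
            hub_mask[hubs] = True
            extra = hub_mask[:, None] | hub_mask[None, :]
            p = 1.0 - (1.0 - p) * np.where(extra, 1.0 - hub_extra_p, 1.0)
        U = rng.random((n_nodes, n_nodes))
        U = np.triu(U, 1)
        W = np.zeros((n_nodes, n_nodes))
        W[np.triu_indices(n_nodes, 1)] = (
            U[np.triu_indices(n_nodes, 1)]
            < p[np.triu_indices(n_nodes, 1)]).astype(float)
        W = W + W.T
        if _is_connected(W):
            if g is None:
                g = NODE_DRIVE / max(W.sum(axis=1).mean(), 1.0)
            return Connectome([f"region_{i}" for i in range(n_nodes)],
                              W, W.copy(), T_delay=T_delay, g=g,
                              modules=module.copy(), hubs=hubs.copy())
    raise RuntimeError(
        "could not generate a connected graph in 100 attempts; "
        "increase intra_p/inter_p or hub parameters")


def _is_connected(W: np.ndarray) -> bool:
    n = W.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(W[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


def normalized_node_strength(W: np.ndarray, W0: np.ndarray) -> np.ndarray:
    """Per-node current summed weight divided by original summed weight.

    Tracks structural damage: 1 means intact, values below 1 loss.  A
    node isolated already in ``W0`` gets NaN (undefined, not an error).
    """
    W = np.asarray(W, dtype=float)
    W0 = np.asarray(W0, dtype=float)
    if W.shape != W0.shape:
        raise ValueError("W and W0 must have the same shape")
    s0 = W0.sum(axis=1)
    s = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(s0 > 0, s / np.where(s0 > 0, s0, 1.0), np.nan)
    return ratio
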