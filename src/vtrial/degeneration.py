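"""Activity-dependent degeneration (ADD).

After every cycle the coupling weights are eroded as an increasing
function of the excitatory spike density of the edge's endpoint masses:

    W[i, j] <- max(w_floor, W[i, j] * (1 - lam * L(s_ij)))
    L(s) = exp(k * (s - s_ref))

with ``s_ij`` the mean (or, optionally, per-endpoint) spike density.
Every region is damaged regardless of its absolute activity level, but
regions at or below the reference density ``s_ref`` lose weight
exponentially less.  Loss is multiplicative, so weights decay
monotonically and never go negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import Connectome
from .simulate import CycleOutput

__all__ = ["ADDParams", "apply_add", "total_activity"]


@dataclass(frozen=True)
class ADDParams:
    """Loss-function constants.

    ``lam`` is the fractional weight loss per cycle at the reference
    spike density; ``k`` (seconds) scales how steeply loss grows with
    activity above ``s_ref`` (spikes/s); ``w_floor`` bounds weights from
    below.
    """

    lam: float = 0.03
    s_ref: float = 1.45
    k: float = 0.5
    w_floor: float = 0.0
    mode: str = "mean"  # edge drive: "mean" of endpoints or per-"source"
    # relative rate at which each node's intra-mass excitatory synapses
    # (the excitatory -> inhibitory drive) erode, as a multiple of the
    # long-range loss rate; nonzero values add disinhibition-driven
    # hyperactivity and a deeper final collapse, at the cost of a much
    # weaker response to excitability interventions (the local
    # oscillator itself is destroyed); default 0 = long-range loss only
    intra_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0 or self.k < 0 or self.w_floor < 0:
            raise ValueError("lam, k and w_floor must be >= 0")
        if self.intra_fraction < 0:
            raise ValueError("intra_fraction must be >= 0")
        if self.mode not in ("mean", "source"):
            raise ValueError("mode must be 'mean' or 'source'")


def apply_add(conn: Connectome, mean_spike_density: np.ndarray,
              params: ADDParams) -> Connectome:
    """Erode ``conn.W`` in place according to the per-node activity.

    Returns the same Connectome for chaining.  In ``mean`` mode the edge
    (i, j) is damaged once by ``L((s_i + s_j) / 2)``; in ``source`` mode
    it is damaged by both endpoints in turn, preserving symmetry.
    """
    s = np.asarray(mean_spike_density, dtype=float)
    if s.shape != (conn.n_nodes,):
        raise ValueError("mean_spike_density must have one entry per node")
    if not np.isfinite(s).all() or (s < 0).any():
        raise ValueError("spike densities must be finite and non-negative")
    L_node = np.exp(params.k * (s - params.s_ref))
    if params.mode == "mean":
        loss = params.lam * np.exp(
            params.k * ((s[:, None] + s[None, :]) / 2.0 - params.s_ref))
    else:  # source: each endpoint damages the edge independently
        f = 1.0 - np.minimum(params.lam * L_node, 1.0)
        keep = f[:, None] * f[None, :]
        loss = 1.0 - keep
    if (params.lam * L_node > 1.0).any():
        warnings.warn("ADD loss saturated (lam * L(s) > 1) for at least one "
                      "node; weights clamped at w_floor", RuntimeWarning,
                      stacklevel=2)
    factor = 1.0 - np.clip(loss, 0.0, 1.0)
    W_new = np.maximum(conn.W * factor, np.where(conn.W > 0, params.w_floor, 0.0))
    W_new = np.minimum(W_new, conn.W)  # weights never increase
    np.fill_diagonal(W_new, 0.0)
    conn.W = W_new
    # all excitatory synapses degenerate: the node's intra-mass
    # excitatory drive onto its inhibitory population erodes at the same
    # activity-dependent rate (scaled by intra_fraction)
    node_loss = np.clip(params.intra_fraction * params.lam * L_node, 0.0, 1.0)
    conn.intra_scale = conn.intra_scale * (1.0 - node_loss)
    return conn


def total_activity(output: CycleOutput) -> tuple[np.ndarray, np.ndarray]:
    """Per-node activity summaries of one cycle.

    Returns ``(mean spike density, mean squared membrane potential)``;
    the first drives :func:`apply_add`, both are logged as "total
    power"-style activity measures.
    """
    if output.signals.size == 0 or output.spike_density.size == 0:
        raise ValueError("empty cycle output")
    mean_s = output.spike_density.mean(axis=0)
    mean_v2 = np.mean(np.square(output.signals), axis=0)
    return mean_s, mean_v2
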