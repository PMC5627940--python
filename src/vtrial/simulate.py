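"""Coupled-network simulation: advance all masses through one cycle.

The per-node external input at time ``t`` is ``g * sum_j W[i, j] *
E_j(t - T)``: excitatory pulse densities from connected masses, scaled
by the global gain and delayed by the single conduction delay ``T``.
Past pulse densities live in a ring buffer pre-filled with the initial
state's ``E``.  The EEG-like multichannel output per cycle is the
excitatory membrane potential and pulse density of every node, sampled
at ``fs`` after discarding an initial transient.

The inner loop (one Heun step of two second-order synaptic filters per
node plus the delayed coupling term) is compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectome import Connectome
from .mass import MassParams, MassState, sigmoid_transfer

__all__ = ["NetworkState", "CycleOutput", "initial_network_state", "run_cycle"]


@dataclass
class NetworkState:
    """Per-node filter states plus the spike-density delay buffer."""

    Ve: np.ndarray
    z_e: np.ndarray
    Vi: np.ndarray
    z_i: np.ndarray
    Ebuf: np.ndarray  # (delay_steps, n) ring buffer of past E
    ptr: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(self.Ve.copy(), self.z_e.copy(), self.Vi.copy(),
                            self.z_i.copy(), self.Ebuf.copy(), self.ptr)

    def mass_state(self, i: int, params: MassParams) -> MassState:
        """View node ``i`` as a single-mass state (for inspection/tests)."""
        return MassState(
            Ve=float(self.Ve[i]), Vi=float(self.Vi[i]),
            E=sigmoid_transfer(self.Ve[i], params.Vd1, params.q, params.r),
            I=sigmoid_transfer(self.Vi[i], params.Vd2, params.q, params.r),
            z_e=float(self.z_e[i]), z_i=float(self.z_i[i]),
        )


@dataclass
class CycleOutput:
    """Multichannel output of one cycle (transient already discarded)."""

    signals: np.ndarray        # (n_samples, n) excitatory membrane potential, mV
    spike_density: np.ndarray  # (n_samples, n) excitatory pulse density, 1/s
    mean_spike_density: np.ndarray  # (n,) time-mean pulse density, 1/s
    fs: float
    cycle_index: int = 0


def initial_network_state(conn: Connectome, params: MassParams,
                          dt: float, Ve0: float | None = None) -> NetworkState:
    """Fresh state with every node at ``Ve0`` (default: the excitatory
    threshold, so the network starts on its active branch) and the delay
    buffer filled with the matching pulse density."""
    n = conn.n_nodes
    delay_steps = _delay_steps(conn.T_delay, dt)
    Ve0 = params.Vd1 if Ve0 is None else Ve0
    E0 = sigmoid_transfer(Ve0, params.Vd1, params.q, params.r)
    return NetworkState(
        Ve=np.full(n, float(Ve0)),
        z_e=np.zeros(n),
        Vi=np.zeros(n),
        z_i=np.zeros(n),
        Ebuf=np.full((delay_steps, n), E0),
    )


def _delay_steps(T_delay_ms: float, dt: float) -> int:
    steps = T_delay_ms * 1e-3 / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"T_delay = {T_delay_ms} ms is not an integer number of dt = {dt} s steps")
    return max(int(round(steps)), 1)


@njit(cache=True)
def _integrate(W, g, P, Vd1, Vd2, C1, A, B, a, b, C2, q, r,
               Ve, z_e, Vi, z_i, Ebuf, ptr, dt, keep_every, out_V, out_E):
    n_steps = P.shape[0]
    n = W.shape[0]
    L = Ebuf.shape[0]
    kept = 0
    for t in range(n_steps):
        E_del = Ebuf[ptr]
        ext = g * np.dot(W, E_del)
        for i in range(n):
            E_i = q / (1.0 + np.exp(r * (Vd1[i] - Ve[i])))
            I_i = q / (1.0 + np.exp(r * (Vd2[i] - Vi[i])))
            Ebuf[ptr, i] = E_i
            u_e = P[t, i] + ext[i] - C2 * I_i
            u_i = C1[i] * E_i
            # Heun step of both critically damped second-order filters
            k1v = z_e[i]
            k1z = A * a * u_e - 2.0 * a * z_e[i] - a * a * Ve[i]
            v1 = Ve[i] + dt * k1v
            zz1 = z_e[i] + dt * k1z
            k2z = A * a * u_e - 2.0 * a * zz1 - a * a * v1
            Ve[i] = Ve[i] + 0.5 * dt * (k1v + zz1)
            z_e[i] = z_e[i] + 0.5 * dt * (k1z + k2z)

            k1v = z_i[i]
            k1z = B * b * u_i - 2.0 * b * z_i[i] - b * b * Vi[i]
            v1 = Vi[i] + dt * k1v
            zz1 = z_i[i] + dt * k1z
            k2z = B * b * u_i - 2.0 * b * zz1 - b * b * v1
            Vi[i] = Vi[i] + 0.5 * dt * (k1v + zz1)
            z_i[i] = z_i[i] + 0.5 * dt * (k1z + k2z)
        ptr = (ptr + 1) % L
        if (t + 1) % keep_every == 0:
            for i in range(n):
                out_V[kept, i] = Ve[i]
                out_E[kept, i] = q / (1.0 + np.exp(r * (Vd1[i] - Ve[i])))
            kept += 1
    return ptr


def run_cycle(
    conn: Connectome,
    state: NetworkState,
    params: MassParams,
    Vd1: np.ndarray | None = None,
    Vd2: np.ndarray | None = None,
    duration: float = 4.0,
    dt: float = 1e-3,
    fs: float = 500.0,
    rng: np.random.Generator | int | None = None,
    transient: float = 0.5,
    cycle_index: int = 0,
) -> tuple[CycleOutput, NetworkState]:
    """Advance the whole network for ``duration`` seconds.

    ``Vd1``/``Vd2`` override the per-node thresholds (interventions);
    the intra-mass excitatory->inhibitory coupling is ``params.C1``
    scaled per node by ``conn.intra_scale`` (eroded by degeneration);
    all other mass parameters are shared by every node.  ``rng`` may be
    a Generator (carried across cycles for noise continuity) or a seed.
    The state is advanced in place-free fashion: the returned state is a
    new object, the input is left untouched.
    """
    if duration < 2.0 * transient + 1.0 / fs:
        raise ValueError("duration too short for the requested transient")
    n = conn.n_nodes
    keep_every = int(round(1.0 / (fs * dt)))
    if abs(keep_every * fs * dt - 1.0) > 1e-9 or keep_every < 1:
        raise ValueError(f"fs = {fs} Hz is not an integer subsampling of dt = {dt} s")
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # thalamic input, truncated Gaussian pulse density, one column per node
    P = rng.normal(params.P_mean, params.P_sd, (n_steps, n))
    np.clip(P, 0.0, None, out=P)

    vd1 = np.full(n, params.Vd1) if Vd1 is None else np.asarray(Vd1, dtype=float)
    vd2 = np.full(n, params.Vd2) if Vd2 is None else np.asarray(Vd2, dtype=float)

    st = state.copy()
    if st.Ebuf.shape[0] != _delay_steps(conn.T_delay, dt):
        raise ValueError("state delay buffer does not match connectome T_delay")
    n_kept = n_steps // keep_every
    out_V = np.empty((n_kept, n))
    out_E = np.empty((n_kept, n))
    c1 = params.C1 * conn.intra_scale
    st.ptr = _integrate(
        np.ascontiguousarray(conn.W), conn.g, P, vd1, vd2, c1,
        params.A, params.B, params.a, params.b, params.C2,
        params.q, params.r,
        st.Ve, st.z_e, st.Vi, st.z_i, st.Ebuf, st.ptr,
        dt, keep_every, out_V, out_E,
    )
    if not np.isfinite(st.Ve).all():
        bad = int(np.flatnonzero(~np.isfinite(st.Ve))[0])
        raise FloatingPointError(
            f"network integration diverged at node {bad} during cycle {cycle_index}")
    skip = int(round(transient * fs))
    out = CycleOutput(
        signals=out_V[skip:],
        spike_density=out_E[skip:],
        mean_spike_density=out_E[skip:].mean(axis=0),
        fs=fs,
        cycle_index=cycle_index,
    )
    return out, st
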