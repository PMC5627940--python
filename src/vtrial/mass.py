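"""Single alpha-rhythm neural mass.

One mass lumps a large population of excitatory and one of inhibitory
neurons.  Each population carries an average membrane potential (``Ve``,
``Vi``, mV) and a pulse density (``E``, ``I``, spikes/s).  Membrane
potential is converted to pulse density by a logistic sigmoid whose
midpoint is the threshold potential ``Vd``; pulse density is converted
back to membrane potential by a critically damped second-order synaptic
filter with kernel ``G * g_rate * t * exp(-g_rate * t)`` (the classic
alpha function).  The excitatory population is driven by thalamic noise
``P(t)``, by pulse densities arriving from other masses, and (negatively)
by the local inhibitory population; the inhibitory population is driven
by the local excitatory one.  With the default parameters the closed
loop resonates in the alpha band (8-13 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "MassParams",
    "MassState",
    "sigmoid_transfer",
    "impulse_response_step",
    "step_mass",
]


@dataclass(frozen=True)
class MassParams:
    """Parameters of one neural mass.

    Attributes
    ----------
    A, B : float
        Excitatory / inhibitory synaptic gain (mV).
    a, b : float
        Excitatory / inhibitory rate constant (1/s); the synaptic filter
        peaks at ``t = 1/a`` and has DC gain ``A/a``.
    C1 : float
        Coupling constant excitatory -> inhibitory population.
    C2 : float
        Coupling constant inhibitory -> excitatory population.
    q : float
        Maximum pulse density of the sigmoid (spikes/s).
    r : float
        Sigmoid steepness (1/mV).
    Vd1, Vd2 : float
        Threshold (midpoint) potential of the excitatory / inhibitory
        sigmoid (mV).  Interventions act exclusively on these two values.
    P_mean, P_sd : float
        Mean and standard deviation of the thalamic input pulse density
        (spikes/s); samples are truncated at zero.
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 120.0
    b: float = 34.0
    C1: float = 4.3
    C2: float = 81.0
    q: float = 5.0
    r: float = 0.7
    Vd1: float = 7.0
    Vd2: float = 7.0
    P_mean: float = 238.0
    P_sd: float = 35.0

    def __post_init__(self) -> None:
        for name in ("A", "B", "a", "b", "q", "r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MassParams.{name} must be > 0")
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("C1 and C2 must be >= 0")
        if self.P_sd < 0:
            raise ValueError("P_sd must be >= 0")
        for name in ("Vd1", "Vd2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"MassParams.{name} must be finite")

    def with_thresholds(self, Vd1: float, Vd2: float) -> "MassParams":
        """Return a copy with new excitability thresholds."""
        return replace(self, Vd1=Vd1, Vd2=Vd2)


@dataclass
class MassState:
    """Dynamic state of one mass: potentials, pulse densities, and the
    first-derivative auxiliaries of the two second-order filters."""

    Ve: float = 0.0
    Vi: float = 0.0
    E: float = 0.0
    I: float = 0.0
    z_e: float = 0.0
    z_i: float = 0.0

    @classmethod
    def resting(cls, params: MassParams) -> "MassState":
        """State with zero potentials and the matching pulse densities."""
        return cls(
            Ve=0.0,
            Vi=0.0,
            E=sigmoid_transfer(0.0, params.Vd1, params.q, params.r),
            I=sigmoid_transfer(0.0, params.Vd2, params.q, params.r),
        )


def sigmoid_transfer(Vm: float, Vd: float, q: float, r: float) -> float:
    """Convert membrane potential to pulse density.

    ``S(Vm) = q / (1 + exp(r * (Vd - Vm)))``: strictly increasing in
    ``Vm``, strictly decreasing in the threshold ``Vd`` (lower threshold
    -> higher excitability), bounded in ``(0, q)`` with midpoint ``q/2``
    at ``Vm == Vd``.
    """
    Vm = float(Vm)
    Vd = float(Vd)
    if not (math.isfinite(Vm) and math.isfinite(Vd)):
        raise ValueError(f"sigmoid_transfer: non-finite input Vm={Vm}, Vd={Vd}")
    if q <= 0 or r <= 0:
        raise ValueError("sigmoid_transfer: q and r must be > 0")
    return q * float(expit(r * (Vm - Vd)))


def _filter_step(V: float, z: float, gain: float, rate: float,
                 drive: float, dt: float) -> tuple[float, float]:
    # Heun (explicit 2nd order) step of V'' = gain*rate*u - 2*rate*V' - rate^2*V
    k1v = z
    k1z = gain * rate * drive - 2.0 * rate * z - rate * rate * V
    v1 = V + dt * k1v
    z1 = z + dt * k1z
    k2v = z1
    k2z = gain * rate * drive - 2.0 * rate * z1 - rate * rate * v1
    return V + 0.5 * dt * (k1v + k2v), z + 0.5 * dt * (k1z + k2z)


def impulse_response_step(state: MassState, drive_e: float, drive_i: float,
                          params: MassParams, dt: float) -> MassState:
    """Advance the two synaptic filters by one step of size ``dt``.

    The excitatory filter (kernel ``A*a*t*exp(-a*t)``) integrates
    ``drive_e`` into ``Ve``; the inhibitory filter (``B*b*t*exp(-b*t)``)
    integrates ``drive_i`` into ``Vi``.  Pulse densities are left
    untouched; :func:`step_mass` closes the loop.
    """
    if dt <= 0:
        raise ValueError("impulse_response_step: dt must be > 0")
    Ve, z_e = _filter_step(state.Ve, state.z_e, params.A, params.a, drive_e, dt)
    Vi, z_i = _filter_step(state.Vi, state.z_i, params.B, params.b, drive_i, dt)
    if not (math.isfinite(Ve) and math.isfinite(Vi)):
        raise FloatingPointError(
            f"impulse_response_step diverged: dt={dt} too large for rate "
            f"constants a={params.a}, b={params.b} (need dt << 1/max(a, b))"
        )
    return MassState(Ve=Ve, Vi=Vi, E=state.E, I=state.I, z_e=z_e, z_i=z_i)


def step_mass(state: MassState, external_pulse_density: float,
              params: MassParams, dt: float, rng_draw: float) -> MassState:
    """One integration step of the closed mass loop.

    ``rng_draw`` is the thalamic input sample P(t) (spikes/s, truncated
    at zero here); ``external_pulse_density`` is the summed, gain- and
    delay-weighted excitatory pulse density from other masses.
    """
    E = sigmoid_transfer(state.Ve, params.Vd1, params.q, params.r)
    I = sigmoid_transfer(state.Vi, params.Vd2, params.q, params.r)
    drive_e = max(float(rng_draw), 0.0) + external_pulse_density - params.C2 * I
    drive_i = params.C1 * E
    new = impulse_response_step(
        MassState(state.Ve, state.Vi, E, I, state.z_e, state.z_i),
        drive_e, drive_i, params, dt,
    )
    new.E = sigmoid_transfer(new.Ve, params.Vd1, params.q, params.r)
    new.I = sigmoid_transfer(new.Vi, params.Vd2, params.q, params.r)
    return new


def simulate_single_mass(params: MassParams, duration: float, dt: float,
                         seed: int, state: MassState | None = None
                         ) -> np.ndarray:
    """Simulate one uncoupled mass; returns the Ve trace (1 sample per step).

    Convenience wrapper used for calibration and single-mass tests.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    noise = rng.normal(params.P_mean, params.P_sd, n_steps)
    st = MassState.resting(params) if state is None else state
    out = np.empty(n_steps)
    for t in range(n_steps):
        st = step_mass(st, 0.0, params, dt, noise[t])
        out[t] = st.Ve
    return out
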