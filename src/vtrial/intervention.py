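"""Excitability interventions: threshold-potential (Vd) strategies.

A strategy sets the excitatory and/or inhibitory threshold potentials of
every mass, uniformly and permanently, from a given cycle onward.
Lowering a threshold stimulates (more spikes at the same potential),
raising it inhibits.  The six built-in strategies, the no-intervention
arm and the healthy control bracket the baseline Vd1 = Vd2 = 7 mV.
Thresholds below 4 or above 10 mV push the system into non-functional
states (silence or runaway activity) and are refused unless explicitly
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mass import MassParams

__all__ = [
    "Strategy",
    "BUILTIN_STRATEGIES",
    "builtin_strategy",
    "apply_strategy",
    "check_vd_range",
    "VD_MIN",
    "VD_MAX",
]

BASELINE_VD = 7.0
VD_MIN = 4.0
VD_MAX = 10.0
DEFAULT_START_CYCLE = 11


@dataclass(frozen=True)
class Strategy:
    name: str
    Vd1: float
    Vd2: float
    start_cycle: int = DEFAULT_START_CYCLE
    degeneration_on: bool = True

    def active(self, cycle: int) -> bool:
        return cycle >= self.start_cycle


# name -> (Vd1, Vd2, degeneration_on)
BUILTIN_STRATEGIES: dict[str, tuple[float, float, bool]] = {
    "control": (BASELINE_VD, BASELINE_VD, False),
    "no_intervention": (BASELINE_VD, BASELINE_VD, True),
    "global_stim": (6.0, 6.0, True),
    "global_inhib": (8.0, 8.0, True),
    "stim_excitatory": (5.0, 7.0, True),
    "stim_inhibitory": (7.0, 5.0, True),
    "inhib_excitatory": (8.0, 7.0, True),
    "inhib_inhibitory": (7.0, 6.5, True),
}


def builtin_strategy(name: str, start_cycle: int = DEFAULT_START_CYCLE) -> Strategy:
    """Look up one of the built-in strategies by name."""
    try:
        vd1, vd2, deg = BUILTIN_STRATEGIES[name]
    except KeyError:
        valid = ", ".join(sorted(BUILTIN_STRATEGIES))
        raise ValueError(f"unknown strategy {name!r}; valid names: {valid}") from None
    return Strategy(name=name, Vd1=vd1, Vd2=vd2, start_cycle=start_cycle,
                    degeneration_on=deg)


def custom_strategy(Vd1: float, Vd2: float,
                    start_cycle: int = DEFAULT_START_CYCLE,
                    degeneration_on: bool = True,
                    allow_extreme: bool = False) -> Strategy:
    """Build a user-defined threshold setting.

    Values outside the plausible 4-10 mV band are refused unless
    ``allow_extreme``.
    """
    if not allow_extreme:
        for vd in (Vd1, Vd2):
            if not check_vd_range(vd):
                raise ValueError(
                    f"Vd = {vd} mV is outside the plausible range "
                    f"[{VD_MIN}, {VD_MAX}]; pass allow_extreme=True to override")
    return Strategy("custom", Vd1, Vd2, start_cycle, degeneration_on)


def apply_strategy(params, strategy: Strategy, cycle: int):
    """Return per-node parameters with the strategy's thresholds applied.

    ``params`` may be a single :class:`MassParams` (homogeneous network)
    or a sequence of them; before ``strategy.start_cycle`` it is
    returned unchanged.  Application is uniform across nodes and
    idempotent.
    """
    if not strategy.active(cycle):
        return params
    if isinstance(params, MassParams):
        return params.with_thresholds(strategy.Vd1, strategy.Vd2)
    return [p.with_thresholds(strategy.Vd1, strategy.Vd2) for p in params]


def check_vd_range(Vd: float) -> bool:
    """True if the threshold lies in the biologically plausible band."""
    return VD_MIN <= Vd <= VD_MAX
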