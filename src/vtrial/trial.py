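"""Virtual trials: conditions x runs x cycles, statistics and scores.

The model object is :class:`VirtualTrial` — built from a structural
:class:`~vtrial.connectome.Connectome` and a :class:`TrialConfig` — and
``fit()`` simulates the requested intervention arms alongside the
``control`` (no degeneration) and ``no_intervention`` (degeneration
only) reference conditions, returning a :class:`VirtualTrialResults`
with tidy per-cycle metrics, per-cycle two-tailed t-tests against
control, and per-category performance ratios.

A measure is "normal" at a cycle when it is not significantly lower
than the control condition there; a condition's performance score for a
metric category counts its normal cycles (summed over the category's
measures, from the intervention start onward) divided by the
``no_intervention`` count.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Connectome
from .connectivity import pli_matrix
from .degeneration import ADDParams, apply_add
from .graphs import graph_metrics
from .intervention import Strategy, builtin_strategy, check_vd_range
from .mass import MassParams
from .simulate import initial_network_state, run_cycle
from .spectral import spectral_metrics

__all__ = [
    "TrialConfig", "VirtualTrial", "VirtualTrialResults", "CATEGORIES",
    "run_condition", "compare_to_control", "performance_score",
    "timing_experiment", "vd_sweep",
]

ALL_METRICS = ("rel_alpha", "peak_freq", "pli", "gamma", "modularity",
               "algebraic_connectivity", "leaf_number")

CATEGORIES = {
    "oscillatory": ("rel_alpha", "peak_freq"),
    "connectivity": ("pli",),
    "topology": ("gamma", "modularity", "algebraic_connectivity",
                 "leaf_number"),
}

GRAPH_METRICS = CATEGORIES["topology"]


@dataclass
class TrialConfig:
    """Scale, seeding and analysis settings of one virtual trial."""

    n_runs: int = 10
    n_cycles: int = 50
    duration: float = 4.0      # s simulated per cycle
    dt: float = 1e-3           # s integration step
    fs: float = 500.0          # Hz analysis sample rate
    transient: float = 0.5     # s discarded per cycle
    base_seed: int = 0
    alpha: float = 0.05        # per-cycle t-test level
    params: MassParams = field(default_factory=MassParams)
    add: ADDParams = field(default_factory=ADDParams)
    metrics: tuple[str, ...] = ALL_METRICS
    node_strength: bool = True
    n_surrogates: int = 20     # for gamma normalization
    common_random_numbers: bool = True  # couple conditions run-by-run

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 (t-tests need variance)")
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    def run_seed(self, run: int, condition: str) -> list[int]:
        """Seed material for one run; identical across conditions when
        common random numbers are on."""
        if self.common_random_numbers:
            return [self.base_seed + run, 1715]
        tag = zlib.crc32(condition.encode()) % (2 ** 31)
        return [self.base_seed + run, 1715, tag]


def run_condition(conn: Connectome, strategy: Strategy, config: TrialConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one condition: ``n_runs`` independent runs of
    ``n_cycles`` cycles each, on fresh copies of the connectome.

    Returns ``(metrics, node_strength)`` tidy frames with columns
    (condition, run, cycle, metric, value) and (condition, run, cycle,
    node, label, degree0, strength_ratio).
    """
    rows: list[tuple] = []
    strength_frames: list[pd.DataFrame] = []
    want_pli = any(m in config.metrics for m in ("pli",) + GRAPH_METRICS)
    want_graph = any(m in config.metrics for m in GRAPH_METRICS)
    n_failed = 0
    for run in range(config.n_runs):
        rng = np.random.default_rng(config.run_seed(run, strategy.name))
        c = conn.copy()
        state = initial_network_state(c, config.params, config.dt)
        vd_base = (config.params.Vd1, config.params.Vd2)
        try:
            for cycle in range(1, config.n_cycles + 1):
                vd = (strategy.Vd1, strategy.Vd2) if strategy.active(cycle) \
                    else vd_base
                vd1 = np.full(c.n_nodes, vd[0])
                vd2 = np.full(c.n_nodes, vd[1])
                out, state = run_cycle(
                    c, state, config.params, Vd1=vd1, Vd2=vd2,
                    duration=config.duration, dt=config.dt, fs=config.fs,
                    rng=rng, transient=config.transient, cycle_index=cycle)
                rows.extend(_cycle_metric_rows(
                    strategy.name, run, cycle, out, c, config,
                    want_pli, want_graph))
                if config.node_strength:
                    t = c.node_strength_table(cycle)
                    t.insert(0, "run", run)
                    t.insert(0, "condition", strategy.name)
                    strength_frames.append(t)
                if strategy.degeneration_on:
                    apply_add(c, out.mean_spike_density, config.add)
        except FloatingPointError as err:
            n_failed += 1
            rows.append((strategy.name, run, -1, "failed", 1.0))
            import warnings
            warnings.warn(f"run {run} of condition {strategy.name} failed: "
                          f"{err}", RuntimeWarning, stacklevel=2)
    if n_failed > 0.2 * config.n_runs:
        raise RuntimeError(
            f"condition {strategy.name}: {n_failed}/{config.n_runs} runs "
            "diverged; check parameters")
    metrics = pd.DataFrame(
        rows, columns=["condition", "run", "cycle", "metric", "value"])
    strength = (pd.concat(strength_frames, ignore_index=True)
                if strength_frames else pd.DataFrame())
    return metrics, strength


def _cycle_metric_rows(name, run, cycle, out, conn, config,
                       want_pli, want_graph):
    rows = []
    want = config.metrics
    if "rel_alpha" in want or "peak_freq" in want:
        sp = spectral_metrics(out.signals, out.fs)
        if "rel_alpha" in want:
            rows.append((name, run, cycle, "rel_alpha",
                         sp.mean_rel_lower_alpha))
        if "peak_freq" in want:
            rows.append((name, run, cycle, "peak_freq", sp.mean_peak_freq))
    if want_pli:
        pm = pli_matrix(out.signals, out.fs)
        if "pli" in want:
            rows.append((name, run, cycle, "pli", pm.global_mean))
        if want_graph:
            seed = (config.base_seed * 1000003 + run * 1009 + cycle) % 2 ** 31
            gm = graph_metrics(pm.values, n_surrogates=config.n_surrogates,
                               seed=seed)
            pairs = {"gamma": gm.gamma, "modularity": gm.modularity_q,
                     "algebraic_connectivity": gm.algebraic_connectivity,
                     "leaf_number": float(gm.mst_leaf_number)}
            for m in GRAPH_METRICS:
                if m in want:
                    rows.append((name, run, cycle, m, pairs[m]))
    return rows


def compare_to_control(metrics: pd.DataFrame, control_metrics: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-cycle, per-metric two-tailed t-tests of a condition vs control.

    Returns columns (condition, metric, cycle, mean, mean_control, p,
    normal); ``normal`` is True unless the condition is significantly
    *lower* than control.  With zero variance in both groups the t-test
    is undefined (p = NaN) and the flag falls back to comparing means
    (equal or higher -> normal).
    """
    out = []
    for (metric, cycle), grp in metrics[metrics.cycle > 0].groupby(
            ["metric", "cycle"]):
        ctrl = control_metrics[(control_metrics.metric == metric)
                               & (control_metrics.cycle == cycle)]
        if ctrl.empty:
            continue
        x = grp.value.to_numpy(dtype=float)
        y = ctrl.value.to_numpy(dtype=float)
        mx, my = float(np.nanmean(x)), float(np.nanmean(y))
        tol = 1e-12 * (abs(mx) + abs(my) + 1.0)
        if np.nanstd(x) <= tol and np.nanstd(y) <= tol:
            p = float("nan")
            normal = mx >= my
        else:
            import warnings
            with warnings.catch_warnings():
                # nearly identical groups (common random numbers before
                # trajectories diverge) trip a harmless precision warning
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(x, y, equal_var=True,
                                          nan_policy="omit").pvalue)
            normal = not (p < alpha and mx < my)
        out.append((grp.condition.iloc[0], metric, int(cycle), mx, my, p,
                    bool(normal)))
    return pd.DataFrame(out, columns=["condition", "metric", "cycle", "mean",
                                      "mean_control", "p", "normal"])


def performance_score(condition_cmp: pd.DataFrame,
                      no_intervention_cmp: pd.DataFrame,
                      category: str,
                      from_cycle: int = 1) -> float:
    """Per-category ratio of normal-cycle counts vs no-intervention.

    Sums, over the category's measures and over cycles >= ``from_cycle``,
    the cycles flagged normal; the condition's count is divided by the
    no-intervention count.  Returns ``inf`` if the latter is 0.
    """
    try:
        measures = CATEGORIES[category]
    except KeyError:
        raise ValueError(f"unknown category {category!r}; choose from "
                         f"{sorted(CATEGORIES)}") from None

    def count(cmp: pd.DataFrame) -> int:
        sel = cmp[cmp.metric.isin(measures) & (cmp.cycle >= from_cycle)]
        return int(sel.normal.sum())

    num = count(condition_cmp)
    den = count(no_intervention_cmp)
    return float("inf") if den == 0 else num / den


class VirtualTrial:
    """In-silico intervention trial on a degenerating mass network.

    Parameters
    ----------
    connectome : Connectome
        The structural network; each run starts from a fresh copy.
    config : TrialConfig, optional
        Trial scale and analysis settings; keyword overrides accepted.

    Examples
    --------
    >>> conn = generate_synthetic_connectome(seed=1)      # doctest: +SKIP
    >>> trial = VirtualTrial(conn, n_runs=3, n_cycles=20) # doctest: +SKIP
    >>> res = trial.fit(strategies=["stim_excitatory"])   # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(self, connectome: Connectome,
                 config: TrialConfig | None = None, **overrides):
        self.connectome = connectome
        config = config or TrialConfig()
        if overrides:
            config = replace(config, **overrides)
        self.config = config
        if config.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def run_condition(self, strategy: Strategy | str
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
        if isinstance(strategy, str):
            strategy = builtin_strategy(strategy)
        return run_condition(self.connectome, strategy, self.config)

    def fit(self, strategies=("global_stim", "global_inhib",
                              "stim_excitatory", "stim_inhibitory",
                              "inhib_excitatory", "inhib_inhibitory"),
            progress: bool = False) -> "VirtualTrialResults":
        """Simulate control, no-intervention and the requested strategy
        arms; compute comparisons and performance scores."""
        strategies = [builtin_strategy(s) if isinstance(s, str) else s
                      for s in strategies]
        arms = [builtin_strategy("control"),
                builtin_strategy("no_intervention")] + list(strategies)
        metrics, strengths = [], []
        for strat in arms:
            if progress:
                print(f"[vtrial] simulating {strat.name} "
                      f"({self.config.n_runs} runs x "
                      f"{self.config.n_cycles} cycles)")
            m, s = run_condition(self.connectome, strat, self.config)
            metrics.append(m)
            strengths.append(s)
        metrics = pd.concat(metrics, ignore_index=True)
        strength = (pd.concat([s for s in strengths if not s.empty],
                              ignore_index=True)
                    if any(not s.empty for s in strengths) else pd.DataFrame())

        ctrl = metrics[metrics.condition == "control"]
        comparisons = []
        for strat in arms[1:]:
            cmp = compare_to_control(
                metrics[metrics.condition == strat.name], ctrl,
                alpha=self.config.alpha)
            comparisons.append(cmp)
        comparisons = pd.concat(comparisons, ignore_index=True)

        no_int_cmp = comparisons[comparisons.condition == "no_intervention"]
        score_rows = []
        for strat in arms[2:]:
            cmp = comparisons[comparisons.condition == strat.name]
            for cat in CATEGORIES:
                score_rows.append(
                    (strat.name, cat,
                     performance_score(cmp, no_int_cmp, cat,
                                       from_cycle=strat.start_cycle)))
        scores = pd.DataFrame(score_rows,
                              columns=["condition", "category", "ratio"])
        return VirtualTrialResults(config=self.config, metrics=metrics,
                                   node_strength=strength,
                                   comparisons=comparisons, scores=scores)

    def timing_experiment(self, strategy: Strategy | str = "stim_excitatory",
                          start_delays=(0, 10, 20)) -> dict[int, pd.DataFrame]:
        return timing_experiment(self.connectome, strategy, self.config,
                                 start_delays)

    def vd_sweep(self, family: str, vd_values, allow_extreme: bool = False
                 ) -> pd.DataFrame:
        return vd_sweep(self.connectome, family, vd_values, self.config,
                        allow_extreme=allow_extreme)


@dataclass
class VirtualTrialResults:
    """Fitted trial: tidy metrics plus statistics and scores.

    Attributes
    ----------
    metrics : DataFrame
        (condition, run, cycle, metric, value), every cycle of every run.
    node_strength : DataFrame
        Per-node structural damage ratios per cycle and run.
    comparisons : DataFrame
        Per-cycle t-tests vs control with the "normal" flag.
    scores : DataFrame
        Performance ratios per (condition, category).
    """

    config: TrialConfig
    metrics: pd.DataFrame
    node_strength: pd.DataFrame
    comparisons: pd.DataFrame
    scores: pd.DataFrame

    def mean_trajectory(self, metric: str) -> pd.DataFrame:
        """Cycle-resolved mean +- sd over runs, per condition."""
        sel = self.metrics[(self.metrics.metric == metric)
                           & (self.metrics.cycle > 0)]
        return (sel.groupby(["condition", "cycle"]).value
                .agg(["mean", "std"]).reset_index())

    def summary(self) -> str:
        """Readable report: scores and end-state metric levels."""
        lines = ["Virtual trial summary",
                 "=" * 60,
                 f"runs: {self.config.n_runs}, cycles: {self.config.n_cycles},"
                 f" base seed: {self.config.base_seed}",
                 "",
                 "Performance ratios vs no intervention "
                 "(> 1 means longer normal function):"]
        if not self.scores.empty:
            piv = self.scores.pivot(index="condition", columns="category",
                                    values="ratio")
            lines.append(piv.round(3).to_string())
        last = self.metrics.cycle.max()
        lines += ["", f"network means over the final cycle ({last}):"]
        end = (self.metrics[self.metrics.cycle == last]
               .groupby(["condition", "metric"]).value.mean().unstack())
        lines.append(end.round(3).to_string())
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write metrics/comparisons as CSV and scores as JSON."""
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        if not self.node_strength.empty:
            self.node_strength.to_csv(out / "node_strength.csv", index=False)
        scores = {f"{r.condition}/{r.category}":
                  (None if np.isinf(r.ratio) else r.ratio)
                  for r in self.scores.itertuples()}
        (out / "scores.json").write_text(json.dumps(scores, indent=2))

    def plot_trajectories(self, metric: str = "pli", ax=None):
        """Mean +- sd trajectories per condition (one matplotlib axes)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for cond, grp in self.mean_trajectory(metric).groupby("condition"):
            ax.errorbar(grp.cycle, grp["mean"], yerr=grp["std"], label=cond,
                        capsize=2)
        ax.set_xlabel("virtual time (cycle)")
        ax.set_ylabel(metric)
        ax.legend(fontsize=8)
        return ax


def timing_experiment(conn: Connectome, strategy: Strategy | str,
                      config: TrialConfig, start_delays=(0, 10, 20)
                      ) -> dict[int, pd.DataFrame]:
    """Run the same strategy with different start delays.

    A delay of d means the intervention becomes active at cycle d+1;
    returns one metrics frame per delay (keyed by delay).
    """
    if isinstance(strategy, str):
        strategy = builtin_strategy(strategy)
    results = {}
    for d in start_delays:
        strat = replace(strategy, start_cycle=int(d) + 1)
        m, _ = run_condition(conn, strat, config)
        results[int(d)] = m
    return results


SWEEP_SLOT = {
    "global_stim": "both", "global_inhib": "both",
    "stim_excitatory": "Vd1", "inhib_excitatory": "Vd1",
    "stim_inhibitory": "Vd2", "inhib_inhibitory": "Vd2",
}


def vd_sweep(conn: Connectome, family: str, vd_values, config: TrialConfig,
             allow_extreme: bool = False) -> pd.DataFrame:
    """One trial arm per threshold value within a strategy family.

    The family determines which threshold(s) the values bind to:
    global families set both Vd1 and Vd2, excitatory families Vd1 only,
    inhibitory families Vd2 only.  Values outside [4, 10] mV are
    refused unless ``allow_extreme``.
    """
    try:
        slot = SWEEP_SLOT[family]
    except KeyError:
        raise ValueError(f"unknown strategy family {family!r}; valid: "
                         f"{sorted(SWEEP_SLOT)}") from None
    base = builtin_strategy(family)
    frames = []
    for v in vd_values:
        if not allow_extreme and not check_vd_range(v):
            raise ValueError(f"Vd = {v} outside the plausible range [4, 10]; "
                             "pass allow_extreme=True to override")
        vd1 = v if slot in ("Vd1", "both") else base.Vd1
        vd2 = v if slot in ("Vd2", "both") else base.Vd2
        strat = Strategy(f"{family}[{v}]", vd1, vd2, base.start_cycle, True)
        m, _ = run_condition(conn, strat, config)
        m["vd_value"] = v
        frames.append(m)
    return pd.concat(frames, ignore_index=True)
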