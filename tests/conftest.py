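"""Shared fixtures: toy graphs, small connectomes, and the session-scoped
reduced-scale trials that the slower acceptance properties reuse."""

import numpy as np
import pytest

import vtrial as vt


@pytest.fixture(scope="session")
def toy_graphs():
    return vt.make_toy_graphs()


@pytest.fixture(scope="session")
def conn20():
    """20-node synthetic connectome used for reduced-scale trials."""
    return vt.generate_synthetic_connectome(
        n_nodes=20, n_modules=4, hub_count=3, seed=3)


@pytest.fixture(scope="session")
def control78():
    """Healthy control condition at full 78-node scale, 3 runs x 5 cycles."""
    conn = vt.generate_synthetic_connectome(seed=1)
    cfg = vt.TrialConfig(n_runs=3, n_cycles=5, base_seed=11,
                         metrics=("rel_alpha", "peak_freq"),
                         node_strength=False)
    metrics, _ = vt.run_condition(conn, vt.builtin_strategy("control"), cfg)
    return metrics


@pytest.fixture(scope="session")
def endgame78():
    """No-intervention degeneration at 78-node scale, 3 runs x 40 cycles."""
    conn = vt.generate_synthetic_connectome(seed=1)
    cfg = vt.TrialConfig(n_runs=3, n_cycles=40, base_seed=11,
                         metrics=("rel_alpha", "peak_freq"),
                         node_strength=True)
    return vt.run_condition(conn, vt.builtin_strategy("no_intervention"), cfg)


@pytest.fixture(scope="session")
def ten_seed_arms(conn20):
    """10 seed replicates of {control, no_intervention, stim_excitatory}
    at reduced scale (20 nodes, 3 runs, 20 cycles), PLI metric only."""
    out = {}
    for seed in range(10):
        cfg = vt.TrialConfig(n_runs=3, n_cycles=20, base_seed=100 + seed,
                             metrics=("pli",), node_strength=True)
        arms = {}
        for name in ("control", "no_intervention", "stim_excitatory"):
            arms[name] = vt.run_condition(conn20, vt.builtin_strategy(name),
                                          cfg)
        out[seed] = {"config": cfg, "arms": arms}
    return out


@pytest.fixture(scope="session")
def topology_trial():
    """Control and no-intervention arms with the full topology metric set
    at 78-node scale, for the end-of-degeneration comparisons."""
    conn = vt.generate_synthetic_connectome(seed=1)
    cfg = vt.TrialConfig(n_runs=2, n_cycles=16, base_seed=7,
                         n_surrogates=10, node_strength=False)
    arms = {}
    for name in ("control", "no_intervention"):
        arms[name] = vt.run_condition(conn, vt.builtin_strategy(name),
                                      cfg)[0]
    return cfg, arms
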