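"""Trial orchestration: conditions, statistics, scores, timing, sweeps."""

import numpy as np
import pandas as pd
import pytest

import vtrial as vt
from vtrial.trial import (CATEGORIES, compare_to_control, performance_score,
                          timing_experiment, vd_sweep)


def _metrics_frame(condition, values_by_cycle, metric="pli"):
    rows = []
    for cycle, values in values_by_cycle.items():
        for run, v in enumerate(values):
            rows.append((condition, run, cycle, metric, v))
    return pd.DataFrame(rows, columns=["condition", "run", "cycle",
                                       "metric", "value"])


class TestCompareToControl:
    def test_identical_values_are_normal(self):
        a = _metrics_frame("x", {1: [0.5, 0.5, 0.5], 2: [0.4, 0.4, 0.4]})
        c = _metrics_frame("control", {1: [0.5, 0.5, 0.5],
                                       2: [0.4, 0.4, 0.4]})
        cmp = compare_to_control(a, c)
        assert cmp.normal.all()
        assert cmp.p.isna().all()  # zero variance in both groups

    def test_far_below_control_flags_abnormal(self):
        a = _metrics_frame("x", {1: [0.01, 0.012, 0.011]})
        c = _metrics_frame("control", {1: [0.80, 0.81, 0.79]})
        cmp = compare_to_control(a, c)
        assert not cmp.normal.iloc[0]
        assert cmp.p.iloc[0] < 1e-4

    def test_significantly_higher_is_still_normal(self):
        # "normal" means not significantly LOWER than control
        a = _metrics_frame("x", {1: [0.9, 0.91, 0.92]})
        c = _metrics_frame("control", {1: [0.5, 0.51, 0.52]})
        assert compare_to_control(a, c).normal.iloc[0]

    def test_matches_hand_computed_t(self):
        # groups {1,2,3} vs {4,5,6}: pooled t = -3/sqrt(2/3) = -3.6742,
        # df = 4, two-sided p = 0.02131
        a = _metrics_frame("x", {1: [1.0, 2.0, 3.0]})
        c = _metrics_frame("control", {1: [4.0, 5.0, 6.0]})
        cmp = compare_to_control(a, c, alpha=0.05)
        assert cmp.p.iloc[0] == pytest.approx(0.021311641, abs=1e-6)
        assert not cmp.normal.iloc[0]


class TestPerformanceScore:
    def _cmp_frame(self, condition, normals, metric="pli"):
        return pd.DataFrame({
            "condition": condition,
            "metric": metric,
            "cycle": np.arange(1, len(normals) + 1),
            "mean": 0.5, "mean_control": 0.5, "p": 0.5,
            "normal": normals,
        })

    def test_hand_built_counts_give_ratio_two(self):
        cond = self._cmp_frame("x", [True] * 20 + [False] * 10)
        ni = self._cmp_frame("no_intervention", [True] * 10 + [False] * 20)
        assert performance_score(cond, ni, "connectivity") == 2.0

    def test_self_comparison_is_one(self):
        ni = self._cmp_frame("no_intervention", [True] * 7 + [False] * 3)
        assert performance_score(ni, ni, "connectivity") == 1.0

    def test_zero_denominator_is_infinite(self):
        cond = self._cmp_frame("x", [True] * 5)
        ni = self._cmp_frame("no_intervention", [False] * 5)
        assert performance_score(cond, ni, "connectivity") == np.inf

    def test_window_starts_at_intervention(self):
        cond = self._cmp_frame("x", [True] * 30)
        ni = self._cmp_frame("no_intervention", [True] * 10 + [False] * 20)
        # from cycle 11 on: condition 20 normal cycles, no-int 0
        assert performance_score(cond, ni, "connectivity",
                                 from_cycle=11) == np.inf
        assert performance_score(cond, ni, "connectivity",
                                 from_cycle=1) == 3.0

    def test_unknown_category_rejected(self):
        cond = self._cmp_frame("x", [True])
        with pytest.raises(ValueError, match="category"):
            performance_score(cond, cond, "vibes")

    def test_category_definitions(self):
        assert set(CATEGORIES) == {"oscillatory", "connectivity", "topology"}
        assert CATEGORIES["connectivity"] == ("pli",)
        assert len(CATEGORIES["topology"]) == 4


@pytest.fixture(scope="module")
def tiny_conn():
    return vt.generate_synthetic_connectome(n_nodes=12, n_modules=3,
                                            hub_count=2, seed=8)


@pytest.fixture(scope="module")
def tiny_cfg():
    return vt.TrialConfig(n_runs=2, n_cycles=6, base_seed=1,
                          metrics=("rel_alpha", "pli"), node_strength=True)


class TestRunCondition:
    def test_control_preserves_structure(self, tiny_conn, tiny_cfg):
        _, strength = vt.run_condition(tiny_conn,
                                       vt.builtin_strategy("control"),
                                       tiny_cfg)
        np.testing.assert_allclose(strength.strength_ratio, 1.0)

    def test_degeneration_monotone(self, tiny_conn, tiny_cfg):
        _, strength = vt.run_condition(
            tiny_conn, vt.builtin_strategy("no_intervention"), tiny_cfg)
        for (_, _), grp in strength.groupby(["run", "node"]):
            ratios = grp.sort_values("cycle").strength_ratio.to_numpy()
            assert np.all(np.diff(ratios) <= 1e-12)

    def test_bit_identical_given_seed(self, tiny_conn, tiny_cfg):
        a, _ = vt.run_condition(tiny_conn,
                                vt.builtin_strategy("no_intervention"),
                                tiny_cfg)
        b, _ = vt.run_condition(tiny_conn,
                                vt.builtin_strategy("no_intervention"),
                                tiny_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_complete_grid(self, tiny_conn, tiny_cfg):
        m, _ = vt.run_condition(tiny_conn, vt.builtin_strategy("control"),
                                tiny_cfg)
        counts = m.groupby(["metric"]).size()
        assert (counts == tiny_cfg.n_runs * tiny_cfg.n_cycles).all()


class TestVirtualTrialModel:
    def test_fit_produces_scores_and_summary(self, tiny_conn):
        trial = vt.VirtualTrial(tiny_conn, n_runs=2, n_cycles=6,
                                base_seed=2, metrics=("rel_alpha", "pli"),
                                node_strength=False)
        res = trial.fit(strategies=["global_inhib"])
        assert set(res.metrics.condition) == {"control", "no_intervention",
                                              "global_inhib"}
        assert set(res.scores.condition) == {"global_inhib"}
        assert set(res.scores.category) == set(CATEGORIES)
        text = res.summary()
        assert "global_inhib" in text and "Performance ratios" in text

    def test_save_writes_outputs(self, tiny_conn, tmp_path):
        trial = vt.VirtualTrial(tiny_conn, n_runs=2, n_cycles=4,
                                base_seed=2, metrics=("pli",),
                                node_strength=False)
        res = trial.fit(strategies=[])
        res.save(tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "comparisons.csv").exists()
        assert (tmp_path / "scores.json").exists()

    def test_too_few_runs_rejected(self, tiny_conn):
        with pytest.raises(ValueError, match="n_runs"):
            vt.VirtualTrial(tiny_conn, n_runs=1)


class TestTimingExperiment:
    def test_pre_start_trajectories_match_no_intervention(self, tiny_conn):
        cfg = vt.TrialConfig(n_runs=2, n_cycles=8, base_seed=3,
                             metrics=("pli",), node_strength=False)
        res = timing_experiment(tiny_conn, "stim_excitatory", cfg,
                                start_delays=(0, 5))
        assert set(res) == {0, 5}
        ni, _ = vt.run_condition(tiny_conn,
                                 vt.builtin_strategy("no_intervention"), cfg)
        late = res[5]
        # cycles before the late start are identical to no intervention
        for cyc in range(1, 6):
            a = late[late.cycle == cyc].sort_values("run").value.to_numpy()
            b = ni[ni.cycle == cyc].sort_values("run").value.to_numpy()
            np.testing.assert_allclose(a, b, atol=1e-12)
        # ... and diverge afterwards
        a = late[late.cycle == 8].sort_values("run").value.to_numpy()
        b = ni[ni.cycle == 8].sort_values("run").value.to_numpy()
        assert not np.allclose(a, b)


class TestVdSweep:
    def test_six_value_sweep_structure(self, tiny_conn):
        cfg = vt.TrialConfig(n_runs=2, n_cycles=3, base_seed=4,
                             metrics=("pli",), node_strength=False)
        values = [4.0, 4.5, 5.0, 5.5, 6.0, 6.5]
        df = vd_sweep(tiny_conn, "global_stim", values, cfg)
        assert sorted(df.vd_value.unique()) == values
        assert df.groupby("vd_value").size().nunique() == 1

    def test_out_of_range_refused(self, tiny_conn):
        cfg = vt.TrialConfig(n_runs=2, n_cycles=2, metrics=("pli",),
                             node_strength=False)
        with pytest.raises(ValueError, match="plausible"):
            vd_sweep(tiny_conn, "stim_excitatory", [3.0], cfg)

    def test_single_value_matches_run_condition(self, tiny_conn):
        cfg = vt.TrialConfig(n_runs=2, n_cycles=3, base_seed=4,
                             metrics=("pli",), node_strength=False)
        df = vd_sweep(tiny_conn, "stim_excitatory", [5.0], cfg)
        ref, _ = vt.run_condition(
            tiny_conn, vt.Strategy("stim_excitatory[5.0]", 5.0, 7.0, 11, True),
            cfg)
        np.testing.assert_allclose(
            df.sort_values(["run", "cycle"]).value.to_numpy(),
            ref.sort_values(["run", "cycle"]).value.to_numpy())
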