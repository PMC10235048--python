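"""Behavioral metrics: efficiency, curves, comparisons, consistency, learning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from infodemand.cohort import AgentSpec
from infodemand.metrics import (
    efficiency_summary,
    obey_analysis,
    psychometric_curve,
    sequential_effect,
    sequential_effect_report,
    strategy_consistency,
    task_comparisons,
    within_block_learning,
    within_block_learning_report,
)
from infodemand.task import DELTA_EV_SET

DSET = np.array(DELTA_EV_SET, dtype=float)


def _frame(pid, block, devs, reveals, observed_high=None, post_action=None,
           trial_index=None):
    """Minimal trial-record table for metric functions (vectorized)."""
    devs = np.asarray(devs, dtype=float)
    reveals = np.asarray(reveals, dtype=bool)
    n = len(devs)
    hi_ev, lo_ev = (500 + devs) / 2, (500 - devs) / 2
    if observed_high is None:
        observed_high = np.ones(n, dtype=bool)
    revealed_high_prize = np.where(reveals, hi_ev + 60, lo_ev + 15)
    revealed_low_prize = np.where(reveals, hi_ev - 60, lo_ev - 15)
    observed = np.where(observed_high, revealed_high_prize, revealed_low_prize)
    return pd.DataFrame({
        "participant_id": pid, "block": block,
        "trial_index": np.arange(n) if trial_index is None else trial_index,
        "delta_ev": devs,
        "hi_prize_high": hi_ev + 60, "hi_prize_low": hi_ev - 60,
        "lo_prize_high": lo_ev + 15, "lo_prize_low": lo_ev - 15,
        "reveal": np.where(reveals, "hiVar", "loVar"),
        "observed_prize": observed,
        "post_action": "none" if post_action is None else post_action,
        "valid": True,
    })


def _policy_frame(pid, block, agent, n_trials, rng):
    devs = DSET[rng.integers(len(DSET), size=n_trials)]
    reveals = rng.random(n_trials) < agent.reveal_probability(devs, block)
    high = rng.random(n_trials) < 0.5
    return _frame(pid, block, devs, reveals, observed_high=high)


class TestEfficiencySummary:
    def test_simple_ratio(self):
        devs = np.repeat(DSET, 6)
        reveals = np.zeros(126, dtype=bool)
        reveals[:100] = True
        eff = efficiency_summary(_frame("p0", "Observe1", devs, reveals))
        assert eff.loc[0, "pct_reveal_hivar"] == pytest.approx(79.365, abs=0.01)

    def test_optimal_agent(self):
        devs = np.repeat(DSET, 6)
        eff = efficiency_summary(_frame("p0", "Observe1", devs, np.ones(126, bool)))
        row = eff.iloc[0]
        assert row["pct_reveal_hivar"] == 100.0
        assert row["uncertainty_shortfall"] == 0.0 and row["ev_cost"] == 0.0

    def test_decomposition_identity(self, fitted_cohort):
        cohort, *_ = fitted_cohort
        eff = efficiency_summary(cohort.trials)
        ok = eff[~eff["no_deltaev0_trials"]]
        np.testing.assert_allclose(
            ok["uncertainty_shortfall"] + ok["ev_cost"],
            100.0 - ok["pct_reveal_hivar"], atol=1e-9)

    def test_ev_cost_positive_for_positive_slopes(self):
        # value-sensitive sampling costs efficiency beyond the dEV=0 shortfall
        rng = np.random.default_rng(0)
        signs = []
        for i in range(100):
            agent = AgentSpec(f"p{i}", "EV_sensitive", a=float(rng.normal(0.5, 0.3)),
                              b=float(rng.uniform(3, 7)))
            frame = _policy_frame(f"p{i}", "Observe1", agent, 126, rng)
            eff = efficiency_summary(frame)
            signs.append(eff.loc[0, "ev_cost"] > 0)
        assert stats.binomtest(sum(signs), 100, 0.5).pvalue < 0.01
        assert np.mean(signs) > 0.5

    def test_no_deltaev0_flagged(self):
        devs = np.repeat(DSET[DSET != 0], 3)
        eff = efficiency_summary(_frame("p0", "Observe1", devs,
                                        np.ones(len(devs), bool)))
        assert eff.loc[0, "no_deltaev0_trials"]
        assert np.isnan(eff.loc[0, "pct_at_deltaev0"])

    def test_hiev_excludes_zero_delta(self):
        devs = np.array([0.0] * 50 + [110.0] * 50)
        reveals = np.array([False] * 50 + [True] * 50)
        eff = efficiency_summary(_frame("p0", "Observe1", devs, reveals))
        assert eff.loc[0, "pct_reveal_hiev"] == 100.0


class TestPsychometricCurve:
    def test_flat_for_optimal_agent(self):
        devs = np.repeat(DSET, 6)
        curve = psychometric_curve(_frame("p0", "Observe1", devs, np.ones(126, bool)))
        assert (curve["frac_reveal_hivar"] == 1.0).all()

    def test_monotone_for_positive_slope(self):
        rng = np.random.default_rng(1)
        agent = AgentSpec("p0", "EV_sensitive", a=0.3, b=5.0)
        frame = _policy_frame("p0", "Observe1", agent, 5000, rng)
        curve = psychometric_curve(frame, a=0.3, b=5.0)
        rho, _ = stats.spearmanr(curve["delta_ev"], curve["frac_reveal_hivar"])
        assert rho > 0.9
        assert np.all(np.abs(curve["fitted"] - curve["frac_reveal_hivar"])
                      < 4 * np.maximum(curve["se"], 0.01))

    def test_cohort_rate_is_binweighted_mean(self, fitted_cohort):
        cohort, *_ = fitted_cohort
        sub = cohort.trials[cohort.trials["valid"]
                            & (cohort.trials["block"] == "Observe1")]
        curve = psychometric_curve(sub)
        weighted = np.average(curve["frac_reveal_hivar"], weights=curve["n"])
        assert weighted == pytest.approx((sub["reveal"] == "hiVar").mean())


def _fits_frame(n, rng, shift_a=0.4, shift_b=0.0, label="EV_sensitive",
                noise=0.25):
    """Parametric model of a fits table: per-participant a/b per block."""
    rows = []
    for i in range(n):
        base_a = rng.normal(0.5, 0.4)
        base_b = rng.normal(5.0, 1.0)
        for block in ("Observe1", "Estimate", "Intervene", "Observe2"):
            inst = block in ("Estimate", "Intervene")
            rows.append({
                "participant_id": f"p{i:03d}", "block": block,
                "a": base_a + (shift_a if inst else 0) + rng.normal(0, noise),
                "b": base_b + (shift_b if inst else 0) + rng.normal(0, noise),
                "c": rng.normal(0, 0.2), "label": label,
            })
    return pd.DataFrame(rows)


class TestTaskComparisons:
    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(2)
        fits = _fits_frame(265, rng, shift_a=0.4)
        order = pd.Series("EstimateFirst", index=[f"p{i:03d}" for i in range(265)])
        order.iloc[1::2] = "InterveneFirst"
        rep = task_comparisons(fits, order=order)
        for blk in ("Estimate", "Intervene"):
            entry = rep[f"{blk}_vs_Observe1"]["a"]
            assert 0.2 < entry["mean"] < 0.6
            assert entry["wilcoxon_p"] < 0.001
        assert rep["order_anova"]["order_p"] > 0.001  # no planted order effect

    def test_identical_fits_give_zero_differences(self):
        rng = np.random.default_rng(3)
        fits = _fits_frame(20, rng, shift_a=0.0, noise=0.0)
        rep = task_comparisons(fits)
        for blk in ("Estimate", "Intervene"):
            assert rep[f"{blk}_vs_Observe1"]["a"]["mean"] == 0.0
            assert rep[f"{blk}_vs_Observe1"]["a"]["wilcoxon_p"] == 1.0

    def test_null_calibration_wilcoxon(self):
        # no planted shift: the paired Wilcoxon p-values are uniform
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(100 + seed)
            fits = _fits_frame(40, rng, shift_a=0.0)
            rep = task_comparisons(fits)
            pvals.append(rep["Estimate_vs_Observe1"]["a"]["wilcoxon_p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_slope_contrast_between_instrumental_tasks(self):
        rng = np.random.default_rng(4)
        fits = _fits_frame(100, rng, shift_a=0.0)
        inter = fits["block"] == "Intervene"
        fits.loc[inter, "b"] += 1.7  # the Intervene > Estimate slope effect
        rep = task_comparisons(fits)
        assert rep["Intervene_vs_Estimate_b"]["mean"] == pytest.approx(1.7, abs=0.3)
        assert rep["Intervene_vs_Estimate_b"]["wilcoxon_p"] < 0.001

    def test_requires_consistent_ev_sensitive_participants(self):
        rng = np.random.default_rng(5)
        fits = _fits_frame(10, rng, label="Random")
        with pytest.raises(ValueError):
            task_comparisons(fits)


def _labels_frame(first, second, observe1=None, observe2=None):
    n = len(first)
    pids = [f"p{i:03d}" for i in range(n)]
    rows = []
    for i in range(n):
        rows.append({"participant_id": pids[i], "block": "Observe1",
                     "label": (observe1 or ["EV_sensitive"] * n)[i]})
        rows.append({"participant_id": pids[i], "block": "Estimate", "label": first[i]})
        rows.append({"participant_id": pids[i], "block": "Intervene", "label": second[i]})
        rows.append({"participant_id": pids[i], "block": "Observe2",
                     "label": (observe2 or ["EV_sensitive"] * n)[i]})
    fits = pd.DataFrame(rows)
    order = pd.Series("EstimateFirst", index=pids)
    return fits, order


class TestStrategyConsistency:
    def test_perfectly_consistent_cohort(self):
        first = ["Uncertainty_only"] * 30 + ["EV_sensitive"] * 70
        fits, order = _labels_frame(first, first)
        rep = strategy_consistency(fits, order)
        assert rep["repetition"]["p_repeat_uncertainty_only"] == 1.0
        assert rep["repetition"]["p_repeat_ev_sensitive"] == 1.0
        assert sum(rep["group_counts"].values()) == 100
        assert rep["group_counts"]["011"] == 30  # Unc-only in both instrumental

    def test_empty_conditioning_cell_withheld(self):
        first = ["EV_sensitive"] * 50
        fits, order = _labels_frame(first, first)
        assert strategy_consistency(fits, order)["repetition"]["withheld"]

    def test_null_calibration_chi_square(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            first = np.where(rng.random(200) < 0.3, "Uncertainty_only", "EV_sensitive")
            repeat = rng.random(200) < 0.6  # repetition independent of start
            second = np.where(repeat, first,
                              np.where(first == "Uncertainty_only",
                                       "EV_sensitive", "Uncertainty_only"))
            fits, order = _labels_frame(list(first), list(second))
            p = strategy_consistency(fits, order)["repetition"]["p"]
            pvals.append(p)
        # discrete statistic: check the rejection rate rather than exact uniformity
        assert abs(np.mean(np.array(pvals) < 0.05) - 0.05) < 0.05

    def test_power_for_planted_asymmetry(self):
        # repetition probability 0.55 vs 0.75 at n=450 (~V=0.2): power >= 0.8
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            first = np.where(rng.random(450) < 0.4, "Uncertainty_only", "EV_sensitive")
            p_rep = np.where(first == "Uncertainty_only", 0.55, 0.75)
            repeat = rng.random(450) < p_rep
            second = np.where(repeat, first,
                              np.where(first == "Uncertainty_only",
                                       "EV_sensitive", "Uncertainty_only"))
            fits, order = _labels_frame(list(first), list(second))
            rep = strategy_consistency(fits, order)["repetition"]
            hits += rep["p"] < 0.05
        assert hits / 50 >= 0.8


class TestSequentialEffect:
    def test_memoryless_agents_show_no_effect(self):
        rng = np.random.default_rng(6)
        frames = [_policy_frame(f"p{i}", "Observe1",
                                AgentSpec(f"p{i}", "EV_sensitive", a=0.5, b=4.0),
                                252, rng) for i in range(60)]
        eff = sequential_effect(pd.concat(frames, ignore_index=True))
        vals = eff["effect"].dropna().to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_planted_win_stay_detected(self):
        # +0.15 stay bias after a high observed prize
        rng = np.random.default_rng(7)
        frames = []
        for i in range(100):
            devs = DSET[rng.integers(len(DSET), size=252)]
            reveals = np.empty(252, dtype=bool)
            high = rng.random(252) < 0.5
            reveals[0] = rng.random() < 0.7
            for t in range(1, 252):
                p = 0.7 + (0.15 if high[t - 1] else -0.15) * \
                    (1 if reveals[t - 1] else -1)
                reveals[t] = rng.random() < np.clip(p, 0, 1)
            frames.append(_frame(f"p{i}", "Observe1", devs, reveals,
                                 observed_high=high))
        eff = sequential_effect(pd.concat(frames, ignore_index=True))
        vals = eff["effect"].dropna().to_numpy()
        assert vals.mean() > 0.1
        assert stats.wilcoxon(vals).pvalue < 0.01

    def test_few_transitions_flagged(self):
        frame = _frame("p0", "Observe1", DSET[:10], np.ones(10, bool))
        eff = sequential_effect(frame)
        assert eff.loc[0, "flagged"]

    def test_null_correlation_with_slope(self, fitted_cohort):
        cohort, fits, *_ = fitted_cohort
        rep = sequential_effect_report(cohort.trials, fits)
        # memoryless generative agents: no prior-outcome effect, no b coupling
        assert abs(rep["mean_effect"]) < 3 * rep["sem_effect"] + 0.02
        assert abs(rep["corr_with_b"]["r"]) < 3 / np.sqrt(rep["n"])


class TestWithinBlockLearning:
    def test_stationary_agents_centered_at_zero(self):
        rng = np.random.default_rng(8)
        frames = [_policy_frame(f"p{i}", "Observe1",
                                AgentSpec(f"p{i}", "Uncertainty_only", c=1.0),
                                126, rng) for i in range(60)]
        trend = within_block_learning(pd.concat(frames, ignore_index=True))
        vals = trend["half_diff_pct"].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_drifting_rate_detected(self):
        # c drifting +0.01/trial: efficiency rises within the block
        rng = np.random.default_rng(9)
        frames = []
        for i in range(60):
            devs = DSET[rng.integers(len(DSET), size=126)]
            c = 0.5 + 0.01 * np.arange(126)
            reveals = rng.random(126) < 1 / (1 + np.exp(-c))
            frames.append(_frame(f"p{i}", "Estimate", devs, reveals))
        trend = within_block_learning(pd.concat(frames, ignore_index=True))
        vals = trend["half_diff_pct"].to_numpy()
        assert vals.mean() > 2.0
        assert stats.wilcoxon(vals).pvalue < 0.01
        assert trend["logistic_slope"].mean() > 0

    def test_instrumental_only_drift_interaction(self):
        rng = np.random.default_rng(10)
        frames = []
        for i in range(40):
            for block, drift in (("Observe1", 0.0), ("Estimate", 0.01)):
                devs = DSET[rng.integers(len(DSET), size=126)]
                c = 0.5 + drift * np.arange(126)
                reveals = rng.random(126) < 1 / (1 + np.exp(-c))
                frames.append(_frame(f"p{i}", block, devs, reveals))
        trials = pd.concat(frames, ignore_index=True)
        fits = pd.DataFrame([
            {"participant_id": f"p{i}", "block": blk, "label": "Uncertainty_only"}
            for i in range(40) for blk in ("Observe1", "Estimate")])
        rep = within_block_learning_report(trials, fits)
        assert rep["Uncertainty_only/instrumental"]["mean_half_diff_pct"] > \
            rep["Uncertainty_only/observe"]["mean_half_diff_pct"] + 2.0
        assert rep["Uncertainty_only/instrumental"]["wilcoxon_p"] < 0.01


class TestObeyAnalysis:
    def _estimate_frame(self, pid, p_lovar, obey_prob, rng, n=126):
        devs = DSET[rng.integers(len(DSET), size=n)]
        reveals = rng.random(n) > p_lovar          # True = hiVar
        high = rng.random(n) < 0.5
        obey = rng.random(n) < obey_prob
        action = np.where(high == obey, "guess_above", "guess_below")
        return _frame(pid, "Estimate", devs, reveals, observed_high=high,
                      post_action=action)

    def test_perfect_obedience(self):
        rng = np.random.default_rng(11)
        frame = self._estimate_frame("p0", 0.5, 1.0, rng)
        rep = obey_analysis(frame)
        assert rep["per_participant"].loc[0, "obey_rate"] == 1.0

    def test_planted_negative_coupling_recovered(self):
        rng = np.random.default_rng(12)
        frames = []
        for i in range(80):
            p_lovar = rng.uniform(0.1, 0.9)
            obey = 1.0 - 0.6 * p_lovar             # more loVar sampling, less obeying
            frames.append(self._estimate_frame(f"p{i}", p_lovar, obey, rng))
        rep = obey_analysis(pd.concat(frames, ignore_index=True))
        assert rep["spearman_r"] < -0.5 and rep["p"] < 0.001

    def test_uncoupled_cohort_near_zero(self):
        rng = np.random.default_rng(13)
        frames = [self._estimate_frame(f"p{i}", rng.uniform(0.2, 0.8), 0.8, rng)
                  for i in range(80)]
        rep = obey_analysis(pd.concat(frames, ignore_index=True))
        assert abs(rep["spearman_r"]) < 4 / np.sqrt(rep["n"])

    def test_all_hivar_participant_excluded(self):
        rng = np.random.default_rng(14)
        frames = [self._estimate_frame("p0", 0.0, 1.0, rng),
                  self._estimate_frame("p1", 0.5, 1.0, rng)]
        rep = obey_analysis(pd.concat(frames, ignore_index=True))
        assert rep["n"] == 1
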