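"""Model-free behavioral measures and cohort-level analyses.

Everything here works on the trial-record table (one row per trial) and,
where labels or parameters are needed, on the fits table produced by
:func:`infodemand.fitting.fit_cohort`.  The central model-free quantity is
%reveal hiVar — the percentage of trials on which a participant inspected
the high-variance lottery (100% is the uncertainty-minimizing policy).  Its
shortfall decomposes exactly into an uncertainty term (100 minus the value
at dEV = 0, where only uncertainty can drive the choice) and an EV term
(the value at dEV = 0 minus the overall value, the additional loss from
value-dependent sampling).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dip import DipTestResult, dip_statistic, dip_test  # noqa: F401  (re-exported)
from .fitting import sigmoid, DELTA_EV_SCALE

INSTRUMENTAL_BLOCKS = ("Estimate", "Intervene")


def _valid(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["valid"]] if "valid" in trials else trials


def efficiency_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant-block efficiency measures and their decomposition.

    Columns: pct_reveal_hivar, pct_reveal_hiev (dEV = 0 trials excluded —
    no higher-EV lottery exists there), pct_at_deltaev0 (NaN and flagged
    when no dEV = 0 trials survive), uncertainty_shortfall and ev_cost
    (which sum to 100 - pct_reveal_hivar exactly).
    """
    rows = []
    for (pid, block), grp in _valid(trials).groupby(["participant_id", "block"]):
        hivar = (grp["reveal"] == "hiVar").to_numpy()
        pct = 100.0 * hivar.mean()
        nonzero = grp["delta_ev"] != 0
        if nonzero.any():
            hiev_chosen = np.where(grp.loc[nonzero, "delta_ev"] > 0,
                                   grp.loc[nonzero, "reveal"] == "hiVar",
                                   grp.loc[nonzero, "reveal"] == "loVar")
            pct_hiev = 100.0 * hiev_chosen.mean()
        else:
            pct_hiev = np.nan
        at0 = grp[grp["delta_ev"] == 0]
        if len(at0):
            pct0 = 100.0 * (at0["reveal"] == "hiVar").mean()
            flagged = False
        else:
            pct0, flagged = np.nan, True
        rows.append({
            "participant_id": pid, "block": block, "n_valid": len(grp),
            "pct_reveal_hivar": pct, "pct_reveal_hiev": pct_hiev,
            "pct_at_deltaev0": pct0,
            "uncertainty_shortfall": 100.0 - pct0 if not flagged else np.nan,
            "ev_cost": pct0 - pct if not flagged else np.nan,
            "no_deltaev0_trials": flagged,
        })
    return pd.DataFrame(rows)


def psychometric_curve(trials: pd.DataFrame, a: float | None = None,
                       b: float | None = None, c: float | None = None) -> pd.DataFrame:
    """Empirical reveal fractions per dEV level with binomial SEs.

    If (a, b) or c is given, the corresponding fitted curve is evaluated at
    the bin centers in a ``fitted`` column.
    """
    grp = _valid(trials).groupby("delta_ev")["reveal"]
    frac = grp.apply(lambda s: (s == "hiVar").mean())
    n = grp.size()
    out = pd.DataFrame({"delta_ev": frac.index.to_numpy(), "n": n.to_numpy(),
                        "frac_reveal_hivar": frac.to_numpy()})
    out["se"] = np.sqrt(out["frac_reveal_hivar"] * (1 - out["frac_reveal_hivar"])
                        / out["n"].clip(lower=1))
    x = out["delta_ev"].to_numpy() / DELTA_EV_SCALE
    if a is not None and b is not None:
        out["fitted"] = sigmoid(b * (a + x))
    elif c is not None:
        out["fitted"] = sigmoid(np.full_like(x, c))
    return out


def _paired_wilcoxon(diffs: np.ndarray) -> float:
    diffs = np.asarray(diffs, dtype=float)
    if np.allclose(diffs, 0.0):
        return 1.0
    return float(stats.wilcoxon(diffs).pvalue)


def task_comparisons(fits: pd.DataFrame, order: Mapping[str, str] | pd.Series | None = None,
                     efficiency: pd.DataFrame | None = None,
                     reference_block: str = "Observe1") -> dict:
    """Paired task effects for participants EV-sensitive in all three tasks.

    For each instrumental block vs the reference Observe block: paired
    differences in a and b (mean, SEM, two-sided Wilcoxon signed-rank p),
    and in %reveal hiVar when an efficiency table is supplied.  Also the
    Intervene-vs-Estimate slope contrast, the Spearman correlation between
    the task effects on a and on b, and — when the instrumental order is
    known — a two-way ANOVA (order x task) on parameter a.
    """
    blocks = (reference_block,) + INSTRUMENTAL_BLOCKS
    wide = fits.pivot(index="participant_id", columns="block",
                      values=["a", "b", "label"])
    keep = np.all([wide[("label", blk)] == "EV_sensitive" for blk in blocks], axis=0)
    wide = wide[keep]
    if len(wide) < 2:
        raise ValueError("need at least 2 participants EV-sensitive in all blocks")
    report: dict = {"n": int(len(wide)), "reference_block": reference_block}
    eff_wide = None
    if efficiency is not None:
        eff_wide = efficiency.pivot(index="participant_id", columns="block",
                                    values="pct_reveal_hivar").loc[wide.index]
    for blk in INSTRUMENTAL_BLOCKS:
        entry = {}
        for par in ("a", "b"):
            d = (wide[(par, blk)] - wide[(par, reference_block)]).to_numpy(float)
            entry[par] = {"mean": float(d.mean()),
                          "sem": float(d.std(ddof=1) / np.sqrt(len(d))),
                          "median": float(np.median(d)),
                          "wilcoxon_p": _paired_wilcoxon(d)}
        if eff_wide is not None:
            d = (eff_wide[blk] - eff_wide[reference_block]).to_numpy(float)
            entry["pct_reveal_hivar"] = {"mean": float(d.mean()),
                                         "median": float(np.median(d)),
                                         "wilcoxon_p": _paired_wilcoxon(d)}
        report[f"{blk}_vs_{reference_block}"] = entry
    db = (wide[("b", "Intervene")] - wide[("b", "Estimate")]).to_numpy(float)
    da = (wide[("a", "Intervene")] - wide[("a", "Estimate")]).to_numpy(float)
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        rho, rho_p = np.nan, np.nan
    else:
        rho, rho_p = stats.spearmanr(da, db)
    report["Intervene_vs_Estimate_b"] = {
        "mean": float(db.mean()), "sem": float(db.std(ddof=1) / np.sqrt(len(db))),
        "wilcoxon_p": _paired_wilcoxon(db)}
    report["delta_a_vs_delta_b_spearman"] = {"r": float(rho), "p": float(rho_p)}
    if order is not None:
        report["order_anova"] = _order_anova(wide, order)
    return report


def _order_anova(wide: pd.DataFrame, order) -> dict:
    """Two-way ANOVA of parameter a on task order and instrumental task."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    order = pd.Series(order)
    for pid in wide.index:
        for blk in INSTRUMENTAL_BLOCKS:
            rows.append({"a": wide.loc[pid, ("a", blk)], "task": blk,
                         "order": order.get(pid, "unknown")})
    frame = pd.DataFrame(rows)
    model = ols("a ~ C(order) * C(task)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "order_F": float(table.loc["C(order)", "F"]),
        "order_p": float(table.loc["C(order)", "PR(>F)"]),
        "interaction_F": float(table.loc["C(order):C(task)", "F"]),
        "interaction_p": float(table.loc["C(order):C(task)", "PR(>F)"]),
    }


def strategy_consistency(fits: pd.DataFrame, order: Mapping[str, str] | pd.Series) -> dict:
    """Cross-block strategy stability.

    Groups participants by the pattern of Uncertainty-only strategies over
    (first Observe block, first instrumental, second instrumental) — eight
    binary patterns; the second Observe block is summarized separately.
    The repetition analysis conditions on the first instrumental block's
    strategy and compares P(repeat Uncertainty-only) with P(repeat
    EV-sensitive) via a chi-square test (df = 1) on the repeat/non-repeat
    counts of the two starting groups, with Cramer's V = sqrt(chi2 / n).
    """
    order = pd.Series(order)
    labels = fits.pivot(index="participant_id", columns="block", values="label")
    first = np.where(order.loc[labels.index] == "EstimateFirst", "Estimate", "Intervene")
    second = np.where(first == "Estimate", "Intervene", "Estimate")
    lab_first = np.array([labels.loc[pid, blk] for pid, blk in zip(labels.index, first)])
    lab_second = np.array([labels.loc[pid, blk] for pid, blk in zip(labels.index, second)])

    unc = "Uncertainty_only"
    pattern = (
        (labels["Observe1"] == unc).astype(int).astype(str)
        + pd.Series((lab_first == unc).astype(int).astype(str), index=labels.index)
        + pd.Series((lab_second == unc).astype(int).astype(str), index=labels.index)
    )
    group_counts = pattern.value_counts().to_dict()
    report: dict = {
        "n": int(len(labels)),
        "group_counts": {f"{i:03b}": int(group_counts.get(f"{i:03b}", 0)) for i in range(8)},
        "observe2_uncertainty_only": int((labels.get("Observe2") == unc).sum())
        if "Observe2" in labels else None,
    }

    started_unc = lab_first == unc
    started_ev = lab_first == "EV_sensitive"
    n_unc, n_ev = int(started_unc.sum()), int(started_ev.sum())
    if n_unc == 0 or n_ev == 0:
        report["repetition"] = {"withheld": True, "n_started_unc": n_unc,
                                "n_started_ev": n_ev}
        return report
    rep_unc = int((lab_second[started_unc] == unc).sum())
    rep_ev = int((lab_second[started_ev] == "EV_sensitive").sum())
    table = np.array([[rep_unc, n_unc - rep_unc],
                      [rep_ev, n_ev - rep_ev]], dtype=float)
    if table.sum(axis=0).min() == 0:   # all repeats or all switches: no test
        chi2, p = np.nan, np.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n_tot = n_unc + n_ev
    report["repetition"] = {
        "withheld": False,
        "p_repeat_uncertainty_only": rep_unc / n_unc,
        "p_repeat_ev_sensitive": rep_ev / n_ev,
        "n_started_unc": n_unc, "n_started_ev": n_ev,
        "chi2": float(chi2), "df": 1, "p": float(p),
        "cramers_v": float(np.sqrt(chi2 / n_tot)) if np.isfinite(chi2) else np.nan,
    }
    return report


def sequential_effect(trials: pd.DataFrame, min_transitions: int = 20) -> pd.DataFrame:
    """Prior-outcome effect on the next sampling choice, per participant.

    Effect = P(reveal the same lottery at t | high prize observed at t-1)
    minus the same probability after a low prize.  Transitions are counted
    within blocks over consecutive valid trials.
    """
    rows = []
    t = _valid(trials)
    hi_prize = np.where(t["reveal"] == "hiVar", t["hi_prize_high"], t["lo_prize_high"])
    t = t.assign(observed_high=t["observed_prize"].to_numpy() == hi_prize)
    for pid, part in t.groupby("participant_id"):
        same_after_high: list[bool] = []
        same_after_low: list[bool] = []
        for _, blk in part.groupby("block"):
            blk = blk.sort_values("trial_index")
            idx = blk["trial_index"].to_numpy()
            consecutive = np.diff(idx) == 1
            same = (blk["reveal"].to_numpy()[1:] == blk["reveal"].to_numpy()[:-1])[consecutive]
            after_high = blk["observed_high"].to_numpy()[:-1][consecutive]
            same_after_high.extend(same[after_high])
            same_after_low.extend(same[~after_high])
        n_tr = len(same_after_high) + len(same_after_low)
        effect = (np.mean(same_after_high) - np.mean(same_after_low)
                  if same_after_high and same_after_low else np.nan)
        rows.append({"participant_id": pid, "effect": effect,
                     "n_transitions": n_tr, "flagged": n_tr < min_transitions})
    return pd.DataFrame(rows)


def sequential_effect_report(trials: pd.DataFrame, fits: pd.DataFrame,
                             block: str = "Observe1") -> dict:
    """Cohort summary: mean prior-outcome effect and its correlation with b."""
    eff = sequential_effect(trials)
    eff = eff[~eff["flagged"] & eff["effect"].notna()]
    b = fits[fits["block"] == block].set_index("participant_id")["b"]
    merged = eff.set_index("participant_id").join(b, how="inner").dropna()
    effs = merged["effect"].to_numpy(float)
    wilcoxon_p = _paired_wilcoxon(effs) if len(effs) >= 10 else np.nan
    if len(merged) >= 3:
        rho, rho_p = stats.spearmanr(merged["effect"], merged["b"])
    else:
        rho, rho_p = np.nan, np.nan
    return {"n": int(len(merged)), "mean_effect": float(np.mean(effs)),
            "sem_effect": float(np.std(effs, ddof=1) / np.sqrt(len(effs))) if len(effs) > 1 else np.nan,
            "wilcoxon_p": float(wilcoxon_p),
            "corr_with_b": {"r": float(rho), "p": float(rho_p)}}


def within_block_learning(trials: pd.DataFrame) -> pd.DataFrame:
    """Within-block efficiency trend per participant-block.

    The primary statistic is the half-split difference (second-half minus
    first-half %reveal hiVar); a logistic-regression slope of reveal on the
    standardized trial index is reported alongside.
    """
    from sklearn.linear_model import LogisticRegression

    rows = []
    for (pid, block), grp in _valid(trials).groupby(["participant_id", "block"]):
        grp = grp.sort_values("trial_index")
        y = (grp["reveal"] == "hiVar").to_numpy(int)
        half = len(grp) // 2
        half_diff = 100.0 * (y[half:].mean() - y[:half].mean()) if half >= 1 else np.nan
        slope = np.nan
        if len(np.unique(y)) == 2 and len(y) >= 10:
            xi = grp["trial_index"].to_numpy(float)
            xi = (xi - xi.mean()) / max(xi.std(), 1e-9)
            clf = LogisticRegression(C=10.0).fit(xi[:, None], y)
            slope = float(clf.coef_[0, 0])
        rows.append({"participant_id": pid, "block": block,
                     "half_diff_pct": half_diff, "logistic_slope": slope})
    return pd.DataFrame(rows)


def within_block_learning_report(trials: pd.DataFrame, fits: pd.DataFrame) -> dict:
    """Group-level learning trends by strategy class and block type."""
    trend = within_block_learning(trials)
    merged = trend.merge(fits[["participant_id", "block", "label"]],
                         on=["participant_id", "block"], how="left")
    merged["block_type"] = np.where(merged["block"].isin(INSTRUMENTAL_BLOCKS),
                                    "instrumental", "observe")
    out: dict = {}
    for (label, btype), grp in merged.groupby(["label", "block_type"]):
        d = grp["half_diff_pct"].dropna().to_numpy(float)
        if len(d) < 5:
            continue
        out[f"{label}/{btype}"] = {
            "n": int(len(d)), "mean_half_diff_pct": float(d.mean()),
            "wilcoxon_p": _paired_wilcoxon(d)}
    return out


def obey_analysis(trials: pd.DataFrame) -> dict:
    """Estimate-task coupling between loVar sampling and obeying its prize.

    A guess "obeys" the observation when it matches the valence of the
    observed prize (above after a high prize, below after a low one).
    Participants with no loVar reveals in the Estimate block are excluded.
    Returns the per-participant table and the Spearman correlation between
    %inspect loVar and the obey rate.
    """
    est = _valid(trials)
    est = est[est["block"] == "Estimate"]
    if est.empty:
        raise ValueError("no Estimate-block trials")
    rows = []
    for pid, grp in est.groupby("participant_id"):
        lov = grp[grp["reveal"] == "loVar"]
        if lov.empty:
            continue
        is_high = lov["observed_prize"].to_numpy() == lov["lo_prize_high"].to_numpy()
        obeyed = np.where(is_high, lov["post_action"] == "guess_above",
                          lov["post_action"] == "guess_below")
        rows.append({"participant_id": pid,
                     "pct_inspect_lovar": 100.0 * (grp["reveal"] == "loVar").mean(),
                     "obey_rate": float(obeyed.mean()),
                     "n_lovar_reveals": int(len(lov))})
    table = pd.DataFrame(rows)
    if len(table) >= 3:
        rho, p = stats.spearmanr(table["pct_inspect_lovar"], table["obey_rate"])
    else:
        rho, p = np.nan, np.nan
    return {"per_participant": table, "spearman_r": float(rho), "p": float(p),
            "n": int(len(table))}
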