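"""End-to-end orchestration: simulate -> fit -> analyze -> decode -> report.

A run is driven by a plain-dict config (validated field by field) and a
single master seed; named child streams keep the cohort, the decoding
bootstrap, and ancillary randomness independent, so a stage can be rerun
without perturbing the others.  Every JSON artifact embeds the config for
provenance, and identical (config, seed) pairs produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, simulate_cohort
from .decoding import decode
from .fitting import fit_cohort
from .metrics import (
    dip_test,
    efficiency_summary,
    obey_analysis,
    sequential_effect_report,
    strategy_consistency,
    task_comparisons,
)
from .task import DELTA_EV_SET, RT_WINDOW, TOTAL_EV

log = logging.getLogger("infodemand")

TRIAL_COLUMNS = (
    "participant_id", "block", "block_position", "trial_index",
    "hi_prize_high", "hi_prize_low", "lo_prize_high", "lo_prize_low",
    "delta_ev", "draw_hivar", "draw_lovar", "reveal", "observed_prize",
    "post_action", "payoff", "rt_reveal", "rt_post", "valid",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "cohort": {},                # overrides for CohortConfig fields
    "fitting": {"prior_sd": 5.0, "criterion": 4.6, "penalized": True},
    "analysis": {"dip_n_boot": 500, "comparisons": True, "consistency": True,
                 "sequential": True, "obey": True},
    "decode": {"enabled": True, "method": "svm_linear", "n_boot": 100,
               "blocks": ["Observe1", "Estimate", "Intervene"]},
}


class ConfigError(ValueError):
    """Run config failed validation."""


def validate_config(config: dict) -> dict:
    """Merge with defaults and type-check every known field."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, value in config.items():
        if section not in merged:
            raise ConfigError(f"unknown config section {section!r}")
        if section == "seed":
            if not isinstance(value, int):
                raise ConfigError("seed must be an integer")
            merged["seed"] = value
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        if section == "cohort":
            valid = {f.name for f in dataclasses.fields(CohortConfig)}
            bad = set(value) - valid
            if bad:
                raise ConfigError(f"unknown cohort fields: {sorted(bad)}")
            merged["cohort"] = dict(value)
        else:
            bad = set(value) - set(merged[section])
            if bad:
                raise ConfigError(f"unknown {section} fields: {sorted(bad)}")
            merged[section].update(value)
    for key, typ in (("prior_sd", (int, float)), ("criterion", (int, float))):
        if not isinstance(merged["fitting"][key], typ):
            raise ConfigError(f"fitting.{key} must be numeric")
    return merged


def _dump(obj, path: Path, config: dict) -> None:
    payload = {"config": config, "infodemand_version": __version__, "result": obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run",
                 seed: int | None = None) -> Path:
    """Execute a full reproducible run; returns the output directory.

    Stages: simulate the cohort, fit and classify every participant-block,
    compute behavioral metrics and cohort analyses, decode personality, and
    write a summary report.  A stage failure raises with the stage name.
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(cfg["seed"]).spawn(3)

    stage = "simulate"
    try:
        cohort_cfg = CohortConfig(**cfg["cohort"], seed=cfg["seed"]) \
            if "seed" not in cfg["cohort"] else CohortConfig(**cfg["cohort"])
        cohort = simulate_cohort(cohort_cfg)
        cohort.trials.to_csv(out / "trials.csv", index=False)
        cohort.personality.to_csv(out / "personality.csv", index=False)
        agents = [dataclasses.asdict(a) for a in cohort.agents]
        _dump(agents, out / "agents.json", cfg)
        log.info("simulated %d participants", cohort_cfg.n_participants)

        stage = "fit"
        fits, _ = fit_cohort(cohort.trials, prior_sd=cfg["fitting"]["prior_sd"],
                             criterion=cfg["fitting"]["criterion"],
                             penalized=cfg["fitting"]["penalized"])
        fits.to_csv(out / "fits.csv", index=False)
        _dump(fits, out / "fits.json", cfg)

        stage = "analyze"
        eff = efficiency_summary(cohort.trials)
        eff.to_csv(out / "metrics.csv", index=False)
        order = _instrumental_order(cohort.trials)
        analyses: dict[str, Any] = {}
        an_cfg = cfg["analysis"]
        rng_misc = np.random.default_rng(streams[2])
        for block in ("Observe1", "Estimate", "Intervene"):
            vals = eff[eff["block"] == block]["pct_reveal_hivar"].to_numpy() / 100.0
            if len(vals) >= 10:
                res = dip_test(vals, n_boot=an_cfg["dip_n_boot"], rng=rng_misc)
                analyses[f"dip_{block}"] = {"dip": res.dip, "p": res.pvalue, "n": res.n}
        if an_cfg["comparisons"]:
            try:
                analyses["task_comparisons"] = task_comparisons(fits, order=order,
                                                                efficiency=eff)
            except ValueError as exc:
                analyses["task_comparisons"] = {"skipped": str(exc)}
        if an_cfg["consistency"]:
            analyses["strategy_consistency"] = strategy_consistency(fits, order)
        if an_cfg["sequential"]:
            analyses["sequential_effect"] = sequential_effect_report(cohort.trials, fits)
        if an_cfg["obey"]:
            ob = obey_analysis(cohort.trials)
            analyses["obey"] = {"spearman_r": ob["spearman_r"], "p": ob["p"], "n": ob["n"]}
        _dump(analyses, out / "comparisons.json", cfg)

        stage = "decode"
        if cfg["decode"]["enabled"]:
            rng_dec = np.random.default_rng(streams[1])
            dec_out = {}
            for block in cfg["decode"]["blocks"]:
                target = eff[eff["block"] == block].set_index(
                    "participant_id")["pct_reveal_hivar"]
                res = decode(cohort.personality, target,
                             target_name=f"pct_reveal_hivar[{block}]",
                             method=cfg["decode"]["method"],
                             n_boot=cfg["decode"]["n_boot"], rng=rng_dec)
                dec_out[block] = {
                    "excess_mean": res.excess_mean, "excess_ci": res.excess_ci,
                    "significant": res.excess_significant,
                    "class_balance": res.class_balance,
                    "coefficients": res.coefficients,
                }
            _dump(dec_out, out / "decoding.json", cfg)

        stage = "report"
        label_counts = fits.groupby(["block", "label"]).size()
        report = {
            "n_participants": int(cohort.trials["participant_id"].nunique()),
            "labels_per_block": {f"{b}/{l}": int(v) for (b, l), v in label_counts.items()},
            "mean_pct_reveal_hivar": {
                b: float(g["pct_reveal_hivar"].mean())
                for b, g in eff.groupby("block")},
        }
        _dump(report, out / "report.json", cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _instrumental_order(trials: pd.DataFrame) -> pd.Series:
    pos = trials.groupby(["participant_id", "block"])["block_position"].first().unstack()
    return pd.Series(np.where(pos["Estimate"] < pos["Intervene"],
                              "EstimateFirst", "InterveneFirst"), index=pos.index)


def validate_trials(source: str | Path | pd.DataFrame) -> dict:
    """Schema and invariant checks on a trial-record table.

    Checks: required columns, lottery EVs summing to 500, prize ranges of
    120/30, draws belonging to their lottery, dEV consistency and set
    membership, reveal/observed-prize agreement, and RT-window/valid-flag
    agreement.  Returns a report with per-rule violation rows.
    """
    if isinstance(source, (str, Path)):
        try:
            trials = pd.read_csv(source)
        except Exception as exc:
            raise ValueError(f"malformed CSV {source}: {exc}") from exc
    else:
        trials = source
    report: dict[str, Any] = {"n_rows": int(len(trials)), "violations": {}, "warnings": []}
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        report["violations"]["missing_columns"] = missing
        report["ok"] = False
        return report
    extra = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    if extra:
        report["warnings"].append(f"extra columns accepted: {extra}")

    def _record(rule: str, bad_mask) -> None:
        idx = trials.index[np.asarray(bad_mask)].tolist()
        if idx:
            report["violations"][rule] = idx[:100]

    hi_ev = (trials["hi_prize_high"] + trials["hi_prize_low"]) / 2
    lo_ev = (trials["lo_prize_high"] + trials["lo_prize_low"]) / 2
    _record("total_ev_500", ~np.isclose(hi_ev + lo_ev, TOTAL_EV))
    _record("hivar_range_120", ~np.isclose(trials["hi_prize_high"] - trials["hi_prize_low"], 120))
    _record("lovar_range_30", ~np.isclose(trials["lo_prize_high"] - trials["lo_prize_low"], 30))
    _record("delta_ev_consistent", ~np.isclose(hi_ev - lo_ev, trials["delta_ev"]))
    _record("delta_ev_in_set", ~trials["delta_ev"].isin(DELTA_EV_SET))
    _record("draw_hivar_member", ~(np.isclose(trials["draw_hivar"], trials["hi_prize_high"])
                                   | np.isclose(trials["draw_hivar"], trials["hi_prize_low"])))
    _record("draw_lovar_member", ~(np.isclose(trials["draw_lovar"], trials["lo_prize_high"])
                                   | np.isclose(trials["draw_lovar"], trials["lo_prize_low"])))
    observed_expected = np.where(trials["reveal"] == "hiVar",
                                 trials["draw_hivar"], trials["draw_lovar"])
    _record("observed_prize_matches_reveal",
            ~np.isclose(trials["observed_prize"], observed_expected))
    lo_w, hi_w = RT_WINDOW
    rt_ok = trials["rt_reveal"].between(lo_w, hi_w) & (
        trials["rt_post"].isna() | trials["rt_post"].between(lo_w, hi_w))
    _record("valid_flag_matches_rt_window", trials["valid"].astype(bool) != rt_ok)
    report["ok"] = not report["violations"]
    return report
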