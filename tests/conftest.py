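"""Shared fixtures: small fitted cohorts and fast vectorized summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from infodemand.cohort import (
    CohortConfig,
    decoding_cohort_config,
    sample_agent,
    sample_personality,
    simulate_cohort,
    simulate_reveals,
)
from infodemand.fitting import fit_cohort
from infodemand.pipeline import _instrumental_order


@pytest.fixture(scope="session")
def fitted_cohort():
    """A 60-participant default-condition cohort with all blocks fitted."""
    cfg = CohortConfig(n_participants=60, seed=101)
    cohort = simulate_cohort(cfg)
    fits, full = fit_cohort(cohort.trials)
    order = _instrumental_order(cohort.trials)
    return cohort, fits, full, order


def behavioral_summaries(cfg: CohortConfig, seed: int, n_trials: int = 126,
                         block: str = "Observe1", fit: bool = False):
    """Vectorized per-agent empirical summaries without full trial records.

    Returns (agents, profiles, summary frame with pct_reveal_hivar,
    pct_reveal_hiev, the generative parameters, and — when ``fit`` is set —
    the MAP slope b_hat fitted to the simulated block).
    """
    from infodemand.fitting import StandardizedChoices, fit_bivariate

    master = np.random.SeedSequence(seed)
    children = master.spawn(cfg.n_participants + 2)
    assign = np.random.default_rng(children[-2])
    classes = list(cfg.class_mixture)
    probs = np.array([cfg.class_mixture[c] for c in classes])
    labels = assign.choice(classes, size=cfg.n_participants, p=probs)
    agents, rows = [], []
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(children[i])
        ag = sample_agent(cfg, str(labels[i]), f"p{i:04d}", rng)
        devs, revealed = simulate_reveals(ag, n_trials, rng, block=block)
        nz = devs != 0
        hiev = np.where(devs[nz] > 0, revealed[nz], ~revealed[nz])
        row = {
            "participant_id": ag.participant_id,
            "strategy_class": ag.strategy_class,
            "a": ag.a, "b": ag.b, "c": ag.c,
            "pct_reveal_hivar": 100.0 * revealed.mean(),
            "pct_reveal_hiev": 100.0 * hiev.mean() if nz.any() else np.nan,
        }
        if fit:
            row["b_hat"] = fit_bivariate(
                StandardizedChoices.from_arrays(devs, revealed)).b
        rows.append(row)
        agents.append(ag)
    profiles = sample_personality(agents, cfg, np.random.default_rng(children[-1]))
    return agents, profiles, pd.DataFrame(rows).set_index("participant_id")


@pytest.fixture(scope="session")
def decoding_cohort():
    """500 EV-sensitive agents with planted personality loadings."""
    cfg = decoding_cohort_config(n_participants=500, seed=404)
    return behavioral_summaries(cfg, seed=404, fit=True)
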