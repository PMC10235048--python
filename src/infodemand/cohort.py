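"""Synthetic participants: choice policies, instrumental decisions, personality.

Agents belong to one of three strategy classes mirroring the behavioral
taxonomy the analysis is built to recover:

* ``EV_sensitive`` — reveals the high-variance lottery with probability
  sigma(b (a + x)), x = dEV/110: sensitive to both uncertainty (a) and
  relative value (b).
* ``Random`` — constant reveal rate sigma(c) with c ~ 0 (disengaged).
* ``Uncertainty_only`` — constant rate sigma(c) with c well above 0
  (near-normative sampling).

Instrumental behavior: Estimate guesses follow the valence of the observed
prize with probability ``obey_prob`` (after a high-variance reveal this is
the optimal guess); Intervene actions follow switch-iff-below-mean with a
lapse probability.  Instrumentality raises uncertainty sensitivity by a
configurable additive shift on a (or c) in the Estimate/Intervene blocks.

Personality profiles are 15 standardized questionnaire scores plus 3
demographic codes.  Planted scores are loading * z + noise, where z is the
standardized *expected* long-run %reveal-hiVar of the agent (a noiseless
function of its parameters); loadings live only on uncertainty sensitivity,
never on the EV slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import sigmoid, DELTA_EV_SCALE
from .task import (
    DELTA_EV_SET,
    TRIALS_PER_BLOCK,
    ChoiceRecord,
    SessionSchedule,
    build_schedule,
    records_to_frame,
    resolve_payoff,
)

STRATEGY_CLASSES = ("EV_sensitive", "Random", "Uncertainty_only")

#: 15 questionnaire scores (BIS/BAS, Big 5, Need for Cognition, 5DC subscales)
SCORE_COLUMNS = (
    "bis", "bas_drive", "bas_fun_seeking", "bas_reward",
    "big5_extraversion", "big5_agreeableness", "big5_conscientiousness",
    "big5_neuroticism", "big5_openness",
    "need_for_cognition",
    "fdc_joyous_exploration", "fdc_deprivation_sensitivity",
    "fdc_stress_tolerance", "fdc_social_curiosity", "fdc_thrill_seeking",
)
DEMOGRAPHIC_COLUMNS = ("age_band", "sex", "education")
PREDICTOR_COLUMNS = SCORE_COLUMNS + DEMOGRAPHIC_COLUMNS

#: planted associations with uncertainty sensitivity (none on the EV slope)
DEFAULT_LOADINGS: dict[str, float] = {
    "big5_extraversion": -0.5,
    "need_for_cognition": 0.4,
    "fdc_thrill_seeking": -0.3,
    "fdc_stress_tolerance": 0.3,
}


@dataclass(frozen=True)
class AgentSpec:
    """Generative policy parameters for one synthetic participant."""

    participant_id: str
    strategy_class: str
    a: float | None = None
    b: float | None = None
    c: float | None = None
    obey_prob: float = 0.95
    intervene_lapse: float = 0.05
    block_modifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy_class not in STRATEGY_CLASSES:
            raise ValueError(f"unknown strategy class {self.strategy_class!r}")
        if self.strategy_class == "EV_sensitive":
            if self.a is None or self.b is None:
                raise ValueError("EV_sensitive agents need (a, b)")
        elif self.c is None:
            raise ValueError(f"{self.strategy_class} agents need c")
        for p in (self.obey_prob, self.intervene_lapse):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def reveal_probability(self, delta_ev, block: str = "Observe1") -> np.ndarray:
        """p(reveal hiVar) at given dEV values under this agent's policy."""
        shift = float(self.block_modifiers.get(block, 0.0))
        x = np.asarray(delta_ev, dtype=float) / DELTA_EV_SCALE
        if self.strategy_class == "EV_sensitive":
            return sigmoid(self.b * (self.a + shift + x))
        return sigmoid(np.full_like(x, self.c + shift))

    def expected_pct_reveal_hivar(self, block: str = "Observe1",
                                  delta_ev_set: Sequence[float] = DELTA_EV_SET) -> float:
        """Long-run %reveal hiVar (the uncertainty-sensitivity summary)."""
        return float(np.mean(self.reveal_probability(np.asarray(delta_ev_set), block))) * 100.0


def _truncated_normal(rng, mean, sd, lower=None, upper=None):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if (lower is None or v >= lower) and (upper is None or v <= upper):
            return float(v)
    raise RuntimeError("truncated normal sampling failed; check bounds")


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the three-class structure of the reference task: a
    majority of EV-sensitive samplers, a disengaged Random minority, and a
    small near-normative Uncertainty-only group with well-separated
    parameters; instrumental blocks shift uncertainty sensitivity up by 0.4
    (the order of the observed instrumentality effect).
    """

    n_participants: int = 200
    class_mixture: dict = field(default_factory=lambda: {
        "EV_sensitive": 0.65, "Random": 0.15, "Uncertainty_only": 0.20})
    ev_sensitive_a: tuple[float, float] = (0.5, 0.4)      # mean, sd
    ev_sensitive_b: tuple[float, float] = (5.0, 1.0)      # truncated at >= b_min
    ev_sensitive_b_min: float = 3.0
    random_c: tuple[float, float] = (0.0, 0.15)
    uncertainty_c: tuple[float, float] = (3.0, 0.4)       # truncated at >= c_min
    uncertainty_c_min: float = 2.5
    instrumental_shift: float = 0.4                       # added to a (or c) in
                                                          # Estimate/Intervene blocks
    obey_prob: dict = field(default_factory=lambda: {
        "EV_sensitive": 0.95, "Random": 0.6, "Uncertainty_only": 0.95})
    intervene_lapse: dict = field(default_factory=lambda: {
        "EV_sensitive": 0.05, "Random": 0.4, "Uncertainty_only": 0.05})
    trials_per_block: int = TRIALS_PER_BLOCK
    delta_ev_set: Sequence[float] = DELTA_EV_SET
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    rt_lognorm: tuple[float, float] = (0.0, 0.4)          # log-mean, log-sd (seconds)
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.class_mixture.values())
        if not np.isclose(tot, 1.0):
            raise ValueError(f"class mixture must sum to 1, got {tot}")
        for k in self.class_mixture:
            if k not in STRATEGY_CLASSES:
                raise ValueError(f"unknown class {k!r} in mixture")
        unknown = set(self.loadings) - set(SCORE_COLUMNS)
        if unknown:
            raise ValueError(f"loadings on unknown scores: {sorted(unknown)}")


def decoding_cohort_config(n_participants: int = 500, seed: int = 0) -> CohortConfig:
    """Single-class cohort for decoding/selectivity analyses.

    All agents are EV-sensitive with independent heterogeneous (a, b), so a
    median split on any behavioral summary is not confounded with class
    membership and the EV slope varies independently of the planted
    uncertainty-sensitivity signal.
    """
    return CohortConfig(
        n_participants=n_participants,
        class_mixture={"EV_sensitive": 1.0, "Random": 0.0, "Uncertainty_only": 0.0},
        ev_sensitive_a=(0.8, 0.8),
        ev_sensitive_b=(5.0, 1.5),
        ev_sensitive_b_min=1.0,
        seed=seed,
    )


def sample_agent(cfg: CohortConfig, strategy_class: str, participant_id: str,
                 rng: np.random.Generator) -> AgentSpec:
    """Draw one agent's parameters from its class distribution."""
    shift = cfg.instrumental_shift
    mods = {"Estimate": shift, "Intervene": shift}
    common = dict(
        participant_id=participant_id, strategy_class=strategy_class,
        obey_prob=cfg.obey_prob[strategy_class],
        intervene_lapse=cfg.intervene_lapse[strategy_class],
        block_modifiers=mods,
    )
    if strategy_class == "EV_sensitive":
        a = rng.normal(*cfg.ev_sensitive_a)
        b = _truncated_normal(rng, *cfg.ev_sensitive_b, lower=cfg.ev_sensitive_b_min)
        return AgentSpec(a=float(a), b=float(b), **common)
    if strategy_class == "Random":
        return AgentSpec(c=float(rng.normal(*cfg.random_c)), **common)
    return AgentSpec(
        c=_truncated_normal(rng, *cfg.uncertainty_c, lower=cfg.uncertainty_c_min),
        **common)


def simulate_choices(agent: AgentSpec, schedule: SessionSchedule,
                     rng: np.random.Generator,
                     rt_lognorm: tuple[float, float] = (0.0, 0.4)) -> list[ChoiceRecord]:
    """Play a full session: reveal choices, instrumental actions, payoffs, RTs."""
    records: list[ChoiceRecord] = []
    mu, sd = rt_lognorm
    for block in schedule.block_order:
        for trial in schedule.trials[block]:
            p = float(agent.reveal_probability(trial.delta_ev, block))
            reveal = "hiVar" if rng.random() < p else "loVar"
            observed = trial.draw(reveal)
            revealed = trial.lottery(reveal)
            is_high = observed == revealed.prize_high
            rt_reveal = float(np.exp(rng.normal(mu, sd)))
            rt_post: float | None = float(np.exp(rng.normal(mu, sd)))
            if block in ("Observe1", "Observe2"):
                action = "none"
                rt_post = None
            elif block == "Estimate":
                obey = rng.random() < agent.obey_prob
                follow_valence = "guess_above" if is_high else "guess_below"
                against = "guess_below" if is_high else "guess_above"
                action = follow_valence if obey else against
            else:  # Intervene
                intended = "switch" if observed < revealed.ev else "keep"
                if rng.random() < agent.intervene_lapse:
                    intended = "keep" if intended == "switch" else "switch"
                action = intended
            payoff = resolve_payoff(trial, reveal, action)
            lo_w, hi_w = 0.5, 10.0
            valid = lo_w <= rt_reveal <= hi_w and (rt_post is None or lo_w <= rt_post <= hi_w)
            records.append(ChoiceRecord(
                participant_id=agent.participant_id, trial=trial, reveal=reveal,
                observed_prize=observed, post_action=action, payoff=payoff,
                rt_reveal=rt_reveal, rt_post=rt_post, valid=valid))
    return records


def simulate_reveals(agent: AgentSpec, n_trials: int, rng: np.random.Generator,
                     block: str = "Observe1",
                     delta_ev_set: Sequence[float] = DELTA_EV_SET
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: only the sampling choices of one block, vectorized.

    Returns (delta_ev values, revealed-hiVar booleans).  Used wherever the
    instrumental decisions and payoffs are not needed (fitting studies,
    recovery simulations) — orders of magnitude faster than simulating full
    trial records.
    """
    dset = np.asarray(delta_ev_set, dtype=float)
    devs = dset[rng.integers(len(dset), size=n_trials)]
    p = agent.reveal_probability(devs, block)
    return devs, rng.random(n_trials) < p


def sample_personality(agents: Sequence[AgentSpec], cfg: CohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Personality/demographic table with planted loadings.

    Planted score = loading * z + sqrt(1 - loading^2) * noise, with z the
    standardized expected %reveal hiVar across the cohort, so every score is
    (asymptotically) standardized.  Unplanted scores are pure noise and
    demographics are independent of behavior.
    """
    summary = np.array([ag.expected_pct_reveal_hivar() for ag in agents])
    sd = summary.std()
    z = (summary - summary.mean()) / (sd if sd > 0 else 1.0)
    out: dict[str, np.ndarray] = {
        "participant_id": np.array([ag.participant_id for ag in agents])}
    for col in SCORE_COLUMNS:
        lam = float(cfg.loadings.get(col, 0.0))
        noise = rng.standard_normal(len(agents))
        out[col] = lam * z + np.sqrt(max(1.0 - lam ** 2, 0.0)) * noise
    out["age_band"] = rng.integers(1, 13, size=len(agents)).astype(float)
    out["sex"] = rng.integers(0, 2, size=len(agents)).astype(float)
    out["education"] = rng.integers(1, 5, size=len(agents)).astype(float)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SyntheticCohort:
    """All artifacts of one simulated study."""

    trials: pd.DataFrame
    agents: tuple[AgentSpec, ...]
    personality: pd.DataFrame
    config: CohortConfig

    def agents_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(ag) for ag in self.agents])


def simulate_cohort(cfg: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Simulate a labeled cohort end to end.

    One master seed spawns independent child streams per participant (and
    one for personality), so cohorts are bit-reproducible and participants
    can be regenerated independently.
    """
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = master.spawn(cfg.n_participants + 2)
    classes = list(cfg.class_mixture.keys())
    probs = np.array([cfg.class_mixture[c] for c in classes])
    assign_rng = np.random.default_rng(children[-2])
    labels = assign_rng.choice(classes, size=cfg.n_participants, p=probs)

    agents: list[AgentSpec] = []
    frames: list[pd.DataFrame] = []
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(children[i])
        pid = f"p{i:04d}"
        agent = sample_agent(cfg, str(labels[i]), pid, rng)
        order = "EstimateFirst" if i % 2 == 0 else "InterveneFirst"
        schedule = build_schedule(pid, order, rng,
                                 trials_per_block=cfg.trials_per_block,
                                 delta_ev_set=cfg.delta_ev_set)
        recs = simulate_choices(agent, schedule, rng, rt_lognorm=cfg.rt_lognorm)
        frames.append(records_to_frame(recs))
        agents.append(agent)
    personality = sample_personality(agents, cfg, np.random.default_rng(children[-1]))
    trials = pd.concat(frames, ignore_index=True)
    return SyntheticCohort(trials=trials, agents=tuple(agents),
                           personality=personality, config=cfg)
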