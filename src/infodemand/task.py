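"""Two-lottery information-sampling task: trials, draws, payoffs, schedules.

Each trial presents two two-prize lotteries on a 500-point scale: a
high-variance lottery (120-point spread between its prizes) and a
low-variance lottery (30-point spread).  The lottery expected values always
sum to 500 points; their difference (dEV = EV(hiVar) - EV(loVar)) is drawn
uniformly from a fixed 21-value set.  One prize is drawn from each lottery
with equal probability and the trial payoff is built from the sum of the
draws according to the block rule:

* Observe  - no post-sampling action; payoff is the sum of the draws.
* Estimate - the participant guesses whether the sum is above or below 500;
  a correct guess pays the sum, an incorrect one pays 0.
* Intervene - the participant keeps the revealed draw or swaps it for the
  revealed lottery's EV; payoff is the (possibly swapped) revealed amount
  plus the unrevealed draw.

A session is four 126-trial blocks: Observe, the two instrumental blocks in
counterbalanced order, and a closing Observe block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

#: dEV values permitted by the task design (note +-100 is absent).
DELTA_EV_SET: tuple[int, ...] = (
    -110, -90, -80, -70, -60, -50, -40, -30, -20, -10,
    0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 110,
)

TOTAL_EV: float = 500.0
HIVAR_HALF_RANGE: float = 60.0   # hiVar prizes are EV +- 60 (range 120)
LOVAR_HALF_RANGE: float = 15.0   # loVar prizes are EV +- 15 (range 30)
TRIALS_PER_BLOCK: int = 126
POINTS_PER_DOLLAR: float = 2000.0
SHOWUP_FEE: float = 1.0
RT_WINDOW: tuple[float, float] = (0.5, 10.0)

Block = Literal["Observe1", "Estimate", "Intervene", "Observe2"]
BLOCKS: tuple[str, ...] = ("Observe1", "Estimate", "Intervene", "Observe2")
OBSERVE_BLOCKS: frozenset[str] = frozenset({"Observe1", "Observe2"})


class InvalidDeltaEVError(ValueError):
    """dEV outside the permitted set (and permissive mode not requested)."""


class ActionBlockMismatchError(ValueError):
    """Post-sampling action inconsistent with the block's rule."""


@dataclass(frozen=True)
class Lottery:
    """A two-prize lottery; prizes are equiprobable."""

    prize_high: float
    prize_low: float

    def __post_init__(self) -> None:
        if not self.prize_high > self.prize_low:
            raise ValueError("prize_high must exceed prize_low")

    @property
    def ev(self) -> float:
        return (self.prize_high + self.prize_low) / 2.0

    @property
    def range(self) -> float:
        return self.prize_high - self.prize_low

    @property
    def prizes(self) -> tuple[float, float]:
        return (self.prize_high, self.prize_low)


@dataclass(frozen=True)
class TrialSpec:
    """One trial's lottery pair and (optionally) its realized draws."""

    trial_id: str
    block: str
    hivar: Lottery
    lovar: Lottery
    delta_ev: float
    draw_hivar: float | None = None
    draw_lovar: float | None = None

    @property
    def realized_sum(self) -> float:
        if self.draw_hivar is None or self.draw_lovar is None:
            raise ValueError("draws not realized for this trial")
        return self.draw_hivar + self.draw_lovar

    def lottery(self, side: str) -> Lottery:
        if side == "hiVar":
            return self.hivar
        if side == "loVar":
            return self.lovar
        raise ValueError(f"unknown side {side!r}")

    def draw(self, side: str) -> float:
        d = self.draw_hivar if side == "hiVar" else self.draw_lovar
        if d is None:
            raise ValueError("draws not realized for this trial")
        return d


@dataclass(frozen=True)
class ChoiceRecord:
    """A participant's sampling choice and post-sampling action on one trial."""

    participant_id: str
    trial: TrialSpec
    reveal: str                      # "hiVar" | "loVar"
    observed_prize: float
    post_action: str                 # none | guess_above | guess_below | keep | switch
    payoff: float
    rt_reveal: float
    rt_post: float | None = None
    valid: bool = True


@dataclass(frozen=True)
class SessionSchedule:
    """Block order and per-block trial lists for one participant session."""

    participant_id: str
    block_order: tuple[str, ...]
    trials_per_block: int
    instrumental_order: str          # "EstimateFirst" | "InterveneFirst"
    trials: dict[str, tuple[TrialSpec, ...]] = field(repr=False, default_factory=dict)


def make_lottery_pair(delta_ev: float, *, permissive: bool = False) -> tuple[Lottery, Lottery]:
    """Construct the (hiVar, loVar) pair for a given dEV.

    EVs are (500 + dEV)/2 and (500 - dEV)/2 with prizes EV +- 60 and EV +- 15.
    ``permissive`` lifts the membership check on :data:`DELTA_EV_SET` (used
    for worked examples outside the experimental set, e.g. dEV = -100).
    """
    if not permissive and delta_ev not in DELTA_EV_SET:
        raise InvalidDeltaEVError(
            f"delta_ev={delta_ev} is not in the permitted set {DELTA_EV_SET}; "
            "pass permissive=True to construct it anyway"
        )
    ev_hi = (TOTAL_EV + delta_ev) / 2.0
    ev_lo = (TOTAL_EV - delta_ev) / 2.0
    hivar = Lottery(ev_hi + HIVAR_HALF_RANGE, ev_hi - HIVAR_HALF_RANGE)
    lovar = Lottery(ev_lo + LOVAR_HALF_RANGE, ev_lo - LOVAR_HALF_RANGE)
    return hivar, lovar


def make_trial(delta_ev: float, block: str = "Observe1", trial_id: str = "t0",
               *, permissive: bool = False) -> TrialSpec:
    """Convenience constructor for a single (undrawn) trial."""
    hivar, lovar = make_lottery_pair(delta_ev, permissive=permissive)
    return TrialSpec(trial_id=trial_id, block=block, hivar=hivar, lovar=lovar,
                     delta_ev=float(delta_ev))


def draw_outcomes(trial: TrialSpec, rng: np.random.Generator) -> TrialSpec:
    """Realize both lotteries' draws (independent, each high/low with p = 1/2)."""
    hi = trial.hivar.prize_high if rng.random() < 0.5 else trial.hivar.prize_low
    lo = trial.lovar.prize_high if rng.random() < 0.5 else trial.lovar.prize_low
    return replace(trial, draw_hivar=hi, draw_lovar=lo)


def _is_observe(block: str) -> bool:
    return block in OBSERVE_BLOCKS or block == "Observe"


def resolve_payoff(trial: TrialSpec, reveal: str, post_action: str) -> float:
    """Apply the block's payoff rule to a realized trial.

    Raises :class:`ActionBlockMismatchError` when the action does not belong
    to the block (e.g. a guess in an Observe block).
    """
    total = trial.realized_sum
    block = trial.block
    if _is_observe(block):
        if post_action != "none":
            raise ActionBlockMismatchError(
                f"Observe blocks take post_action='none', got {post_action!r}")
        return total
    if block == "Estimate":
        if post_action not in ("guess_above", "guess_below"):
            raise ActionBlockMismatchError(
                f"Estimate blocks take guess_above/guess_below, got {post_action!r}")
        correct = (total > TOTAL_EV) == (post_action == "guess_above")
        return total if correct else 0.0
    if block == "Intervene":
        if post_action not in ("keep", "switch"):
            raise ActionBlockMismatchError(
                f"Intervene blocks take keep/switch, got {post_action!r}")
        revealed = trial.lottery(reveal)
        observed = trial.draw(reveal)
        unrevealed_side = "loVar" if reveal == "hiVar" else "hiVar"
        own = observed if post_action == "keep" else revealed.ev
        return own + trial.draw(unrevealed_side)
    raise ActionBlockMismatchError(f"unknown block {block!r}")


def select_bonus(block_records: Sequence[ChoiceRecord], rng: np.random.Generator) -> float:
    """Bonus for one block: a uniformly chosen trial's payoff at 2000 points/$."""
    if len(block_records) == 0:
        raise ValueError("cannot select a bonus trial from an empty block")
    rec = block_records[int(rng.integers(len(block_records)))]
    return rec.payoff / POINTS_PER_DOLLAR


def session_bonus(records_by_block: dict[str, Sequence[ChoiceRecord]],
                  rng: np.random.Generator) -> float:
    """Total session payment: one bonus trial per block plus the show-up fee."""
    return SHOWUP_FEE + sum(select_bonus(v, rng) for v in records_by_block.values())


def build_schedule(participant_id: str, instrumental_order: str,
                   rng: np.random.Generator, *,
                   trials_per_block: int = TRIALS_PER_BLOCK,
                   delta_ev_set: Sequence[float] = DELTA_EV_SET,
                   draw: bool = True) -> SessionSchedule:
    """Build a 4-block session with dEV drawn uniformly from the design set.

    The first and last blocks are Observe; the middle two are Estimate and
    Intervene ordered by ``instrumental_order``.  When ``draw`` is true the
    lottery outcomes are realized up front (they are independent of behavior).
    """
    if instrumental_order == "EstimateFirst":
        middle = ("Estimate", "Intervene")
    elif instrumental_order == "InterveneFirst":
        middle = ("Intervene", "Estimate")
    else:
        raise ValueError("instrumental_order must be 'EstimateFirst' or 'InterveneFirst'")
    block_order = ("Observe1",) + middle + ("Observe2",)
    dset = np.asarray(delta_ev_set, dtype=float)
    trials: dict[str, tuple[TrialSpec, ...]] = {}
    for block in block_order:
        devs = dset[rng.integers(len(dset), size=trials_per_block)]
        block_trials = []
        for i, dev in enumerate(devs):
            t = make_trial(dev, block=block, trial_id=f"{block}_{i:03d}",
                           permissive=dev not in DELTA_EV_SET)
            if draw:
                t = draw_outcomes(t, rng)
            block_trials.append(t)
        trials[block] = tuple(block_trials)
    return SessionSchedule(participant_id=participant_id, block_order=block_order,
                           trials_per_block=trials_per_block,
                           instrumental_order=instrumental_order, trials=trials)


def records_to_frame(records: Iterable[ChoiceRecord]):
    """Flatten choice records into the trial-record table (one row per trial)."""
    import pandas as pd

    rows = []
    per_block_index: dict[tuple[str, str], int] = {}
    block_position: dict[tuple[str, str], int] = {}
    for r in records:
        t = r.trial
        key = (r.participant_id, t.block)
        if key not in block_position:  # position = order of first appearance
            block_position[key] = sum(1 for k in block_position if k[0] == r.participant_id)
        idx = per_block_index.get(key, 0)
        per_block_index[key] = idx + 1
        rows.append({
            "participant_id": r.participant_id,
            "block": t.block,
            "block_position": block_position[key],
            "trial_index": idx,
            "hi_prize_high": t.hivar.prize_high,
            "hi_prize_low": t.hivar.prize_low,
            "lo_prize_high": t.lovar.prize_high,
            "lo_prize_low": t.lovar.prize_low,
            "delta_ev": t.delta_ev,
            "draw_hivar": t.draw_hivar,
            "draw_lovar": t.draw_lovar,
            "reveal": r.reveal,
            "observed_prize": r.observed_prize,
            "post_action": r.post_action,
            "payoff": r.payoff,
            "rt_reveal": r.rt_reveal,
            "rt_post": r.rt_post if r.rt_post is not None else np.nan,
            "valid": r.valid,
        })
    return pd.DataFrame(rows)
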