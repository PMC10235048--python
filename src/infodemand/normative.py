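"""Normative observer: what an ideal sampler gains from each reveal.

Because the two lotteries are independent and each has two equiprobable
prizes, everything an ideal observer needs follows from enumeration of the
four draw combinations.  After revealing one lottery, the residual
uncertainty about the sum equals the *unrevealed* lottery's range, so
revealing the high-variance lottery (range 120) always leaves the smaller
residual range (30) — and in the Estimate task it pins the sum to one side
of the 500-point criterion, doubling expected guess accuracy from 50% to
100%.  In the Intervene task a low draw can be swapped for the lottery
mean, recovering 60 points on the high-variance side versus 15 on the
low-variance side (a 4x ratio).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

from .task import (
    DELTA_EV_SET,
    TOTAL_EV,
    TRIALS_PER_BLOCK,
    TrialSpec,
    make_trial,
)

RevealRule = Callable[[TrialSpec], str]


@dataclass(frozen=True)
class RevealOutcome:
    """Post-reveal belief state about the sum of the draws."""

    possible_sums: tuple[float, ...]
    sum_range: float
    optimal_guess: str          # "above" | "below" | "indifferent"
    guess_accuracy: float       # probability the optimal guess is correct


def possible_sums(trial: TrialSpec, reveal: str, observed_prize: float) -> RevealOutcome:
    """Enumerate the sums consistent with one observed prize.

    The possible sums are the observed prize plus each prize of the
    unrevealed lottery; their range is exactly the unrevealed lottery's
    range.  The optimal above/below-500 guess is certain when both sums lie
    on the same side of 500 and indifferent (accuracy 1/2) when they
    straddle it.
    """
    revealed = trial.lottery(reveal)
    if observed_prize not in revealed.prizes:
        raise ValueError(
            f"observed prize {observed_prize} is not a prize of the revealed "
            f"lottery {revealed.prizes}")
    other = trial.lottery("loVar" if reveal == "hiVar" else "hiVar")
    sums = tuple(sorted(observed_prize + p for p in other.prizes))
    if min(sums) > TOTAL_EV:
        guess, acc = "above", 1.0
    elif max(sums) < TOTAL_EV:
        guess, acc = "below", 1.0
    else:
        guess, acc = "indifferent", 0.5
    return RevealOutcome(possible_sums=sums, sum_range=max(sums) - min(sums),
                         optimal_guess=guess, guess_accuracy=acc)


def expected_estimate_accuracy(trial: TrialSpec, reveal: str) -> float:
    """Expected accuracy of the optimal guess, averaged over the revealed draws."""
    revealed = trial.lottery(reveal)
    return sum(
        possible_sums(trial, reveal, p).guess_accuracy for p in revealed.prizes
    ) / 2.0


def expected_intervene_recuperation(trial: TrialSpec, reveal: str) -> tuple[float, float]:
    """(points recovered by swapping a low draw, expected gain per trial).

    Swapping a low draw for the lottery mean gains EV - prize_low; the draw
    is low half the time, so the per-trial expected gain of the
    switch-if-below-mean rule is half that.
    """
    revealed = trial.lottery(reveal)
    low_draw_gain = revealed.ev - revealed.prize_low
    return low_draw_gain, 0.5 * low_draw_gain


def _reveal_rule(policy: str | RevealRule) -> RevealRule:
    if callable(policy):
        return policy
    if policy == "hivar":
        return lambda t: "hiVar"
    if policy == "lovar":
        return lambda t: "loVar"
    raise ValueError("reveal policy must be 'hivar', 'lovar', or a callable")


def expected_earnings(block: str, reveal_policy: str | RevealRule = "hivar",
                      post_policy: str = "optimal",
                      delta_ev_set: Sequence[float] = DELTA_EV_SET,
                      tie_break: str = "average") -> float:
    """Exact expected points per trial under a deterministic policy.

    Enumerates every dEV in the design set crossed with the four equiprobable
    draw combinations.  ``post_policy`` is ``"optimal"`` (best guess in
    Estimate, switch-iff-below-mean in Intervene) or ``"always_keep"``
    (Intervene only).  When the Estimate guess is indifferent, ``tie_break``
    chooses ``"average"`` (average the two guesses' payoffs, i.e. accuracy
    1/2 applied to the expected sum), ``"above"`` or ``"below"``.
    """
    rule = _reveal_rule(reveal_policy)
    total = 0.0
    count = 0
    for dev in delta_ev_set:
        base = make_trial(dev, block=block, permissive=True)
        for hi, lo in itertools.product(base.hivar.prizes, base.lovar.prizes):
            trial = TrialSpec(base.trial_id, block, base.hivar, base.lovar,
                              base.delta_ev, draw_hivar=hi, draw_lovar=lo)
            reveal = rule(trial)
            total += _policy_payoff(trial, reveal, post_policy, tie_break)
            count += 1
    return total / count


def _policy_payoff(trial: TrialSpec, reveal: str, post_policy: str, tie_break: str) -> float:
    from .task import resolve_payoff  # local import avoids cycle at module load

    block = trial.block
    if block in ("Observe1", "Observe2", "Observe"):
        return resolve_payoff(trial, reveal, "none")
    observed = trial.draw(reveal)
    if block == "Estimate":
        out = possible_sums(trial, reveal, observed)
        if out.optimal_guess == "above":
            return resolve_payoff(trial, reveal, "guess_above")
        if out.optimal_guess == "below":
            return resolve_payoff(trial, reveal, "guess_below")
        if tie_break == "average":
            return 0.5 * (resolve_payoff(trial, reveal, "guess_above")
                          + resolve_payoff(trial, reveal, "guess_below"))
        return resolve_payoff(trial, reveal, f"guess_{tie_break}")
    if block == "Intervene":
        if post_policy == "always_keep":
            action = "keep"
        else:
            action = "switch" if observed < trial.lottery(reveal).ev else "keep"
        return resolve_payoff(trial, reveal, action)
    raise ValueError(f"unknown block {block!r}")


def missed_earnings(block: str, reveal_policy: str | RevealRule,
                    post_policy: str = "optimal") -> float:
    """Optimal-policy expectation minus the given policy's expectation."""
    best = expected_earnings(block, "hivar", "optimal")
    return best - expected_earnings(block, reveal_policy, post_policy)


def normative_report(trials_per_block: int = TRIALS_PER_BLOCK) -> dict:
    """JSON-able summary of the task's normative constants per block/policy."""
    report: dict = {"per_trial": {}, "per_block": {}, "constants": {}}
    ref = make_trial(0)
    report["constants"] = {
        "total_ev": TOTAL_EV,
        "estimate_accuracy_hivar": expected_estimate_accuracy(ref, "hiVar"),
        "estimate_accuracy_lovar": expected_estimate_accuracy(ref, "loVar"),
        "recuperation_hivar": expected_intervene_recuperation(ref, "hiVar")[0],
        "recuperation_lovar": expected_intervene_recuperation(ref, "loVar")[0],
        "recuperation_ratio": (expected_intervene_recuperation(ref, "hiVar")[0]
                               / expected_intervene_recuperation(ref, "loVar")[0]),
    }
    for block in ("Observe", "Estimate", "Intervene"):
        for policy in ("hivar", "lovar"):
            val = expected_earnings(block if block != "Observe" else "Observe1", policy)
            report["per_trial"][f"{block}_{policy}"] = val
            report["per_block"][f"{block}_{policy}"] = val * trials_per_block
    return report
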