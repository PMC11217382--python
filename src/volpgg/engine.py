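"""Finite-session mechanics: group formation, payoff realization, bonuses.

Players who opt in are shuffled into groups of ``group_size``; any
remainder goes to the individual option.  Under a loner externality
``rho`` each leaver independently enters the assignment pool with
probability rho and, if seated, occupies a chair while contributing
nothing (and still earns the loner payoff).  Bonus rules mirror the
experimental incentive scheme: either estimation accuracy or acquired
points, the branch selected at random per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .game import Action, GameSpec, Regime, realized_payoff

__all__ = [
    "GroupAssignment",
    "BonusResult",
    "assign_groups",
    "realize_outcomes",
    "estimation_bonus",
    "points_bonus",
]

ESTIMATION_BONUS_MAX = 800.0
ESTIMATION_BONUS_SLOPE = 80.0 / 6.0
POINTS_BONUS_RATE = 20.0
ESTIMATE_TOTAL = 30


@dataclass(frozen=True)
class GroupAssignment:
    """Outcome of one round of group formation.

    ``groups`` lists exactly ``group_size`` members each; ``individual``
    collects everyone at the individual option (leavers not seated, plus
    opt-ins bumped by the remainder rule); ``included_loners`` marks
    leavers who were seated in groups under rho > 0.
    """

    groups: tuple[tuple[Hashable, ...], ...]
    individual: tuple[Hashable, ...]
    included_loners: frozenset = field(default_factory=frozenset)
    seed: int | None = None

    def all_participants(self) -> list[Hashable]:
        out: list[Hashable] = []
        for g in self.groups:
            out.extend(g)
        out.extend(self.individual)
        return out


@dataclass(frozen=True)
class BonusResult:
    branch: str  # "estimation" or "points"
    amount: float

    def __post_init__(self) -> None:
        if self.branch not in ("estimation", "points"):
            raise ValueError("branch must be 'estimation' or 'points'")


def assign_groups(
    opt_in_ids: Sequence[Hashable],
    leaver_ids: Sequence[Hashable],
    rho: float,
    spec: GameSpec,
    seed: int | None = None,
) -> GroupAssignment:
    """Form groups of ``group_size`` from opt-ins plus rho-included leavers.

    Each leaver independently joins the pool with probability ``rho``.
    The pool is shuffled under ``seed``, filled into groups, and the
    remainder (pool size mod group_size) — uniformly random because of the
    shuffle — is sent to the individual option.
    """
    if set(opt_in_ids) & set(leaver_ids):
        raise ValueError("opt-in and leaver id sets must be disjoint")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    leavers = list(leaver_ids)
    included = [pid for pid in leavers if rng.random() < rho]
    excluded = [pid for pid in leavers if pid not in set(included)]

    pool = list(opt_in_ids) + included
    rng.shuffle(pool)
    g = spec.group_size
    n_groups = len(pool) // g
    groups = tuple(tuple(pool[i * g : (i + 1) * g]) for i in range(n_groups))
    remainder = pool[n_groups * g :]
    return GroupAssignment(
        groups=groups,
        individual=tuple(remainder + excluded),
        included_loners=frozenset(included),
        seed=seed,
    )


def realize_outcomes(
    assignment: GroupAssignment,
    actions: Mapping[Hashable, Action],
    spec: GameSpec,
) -> pd.DataFrame:
    """Per-participant payoffs for one realized round.

    Group success counts only cooperate actions against the threshold;
    seated leavers earn the loner payoff while occupying a seat.  Anyone
    at the individual option — a leaver or a bumped opt-in — earns the
    loner payoff.  Returns a table with one row per participant:
    participant_id, group_id (empty for the individual option), action,
    success flag, payoff.
    """
    rows = []
    for pid in assignment.all_participants():
        if pid not in actions:
            raise ValueError(f"no action recorded for participant {pid!r}")
        a = Action(actions[pid])
        if a is Action.LEAVE and spec.regime is Regime.MANDATORY:
            raise ValueError(f"participant {pid!r} left under mandatory participation")

    for gid, members in enumerate(assignment.groups):
        n_coop = sum(1 for pid in members if Action(actions[pid]) is Action.COOPERATE)
        success = n_coop >= spec.threshold
        for pid in members:
            a = Action(actions[pid])
            if a is Action.LEAVE:
                if pid not in assignment.included_loners:
                    raise ValueError(f"leaver {pid!r} seated without inclusion flag")
                payoff = spec.loner_payoff
            else:
                payoff = realized_payoff(a, n_coop, spec)
            rows.append(
                {
                    "participant_id": pid,
                    "group_id": gid,
                    "action": a.value,
                    "success": success,
                    "payoff": payoff,
                }
            )
    for pid in assignment.individual:
        rows.append(
            {
                "participant_id": pid,
                "group_id": pd.NA,
                "action": Action(actions[pid]).value,
                "success": pd.NA,
                "payoff": spec.loner_payoff,
            }
        )
    return pd.DataFrame(rows)


def estimation_bonus(
    est_counts: Mapping[Action, int],
    realized_actions: Iterable[Action],
    available_actions: Sequence[Action] | None = None,
) -> BonusResult:
    """Accuracy bonus: 800 - (80/6) * L1 distance between estimated and
    realized action proportions.

    Estimates are integer counts of :data:`ESTIMATE_TOTAL` (30) imagined
    others; realized proportions are taken over the actual co-participants.
    A perfect match pays the full 800 JPY.
    """
    realized = [Action(a) for a in realized_actions]
    if not realized:
        raise ValueError("need at least one other participant")
    if available_actions is None:
        available_actions = sorted({Action(a) for a in est_counts}, key=lambda a: a.value)
    counts = {Action(a): int(c) for a, c in est_counts.items()}
    if sum(counts.get(a, 0) for a in available_actions) != ESTIMATE_TOTAL:
        raise ValueError(f"estimated counts must sum to {ESTIMATE_TOTAL}")
    n = len(realized)
    l1 = 0.0
    for a in available_actions:
        share = sum(1 for r in realized if r is a) / n
        l1 += abs(counts.get(a, 0) / ESTIMATE_TOTAL - share)
    return BonusResult(branch="estimation", amount=ESTIMATION_BONUS_MAX - ESTIMATION_BONUS_SLOPE * l1)


def points_bonus(points: float) -> BonusResult:
    """Points bonus: 20 JPY per acquired point."""
    if points < 0:
        raise ValueError("points must be non-negative")
    return BonusResult(branch="points", amount=POINTS_BONUS_RATE * points)
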