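"""One-shot decision model for the threshold public goods game with an outside option.

A group of ``group_size`` players each hold an endowment and simultaneously
choose to cooperate (invest the endowment in the group project), defect
(keep it), or — when participation is voluntary — leave for a certain
individual option.  If at least ``threshold`` members cooperate, every
member receives ``group_reward`` extra points; otherwise cooperators lose
their investment.  A player who holds a subjective belief ``gamma`` that
any given co-player cooperates can rank the actions by expected payoff;
everything downstream (population shares, equilibria, simulated sessions)
is built on these pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy import stats

__all__ = [
    "Action",
    "Regime",
    "GameSpec",
    "tail_prob_others",
    "expected_payoffs",
    "best_response",
    "pivotal_probability",
    "realized_payoff",
]


class Regime(str, Enum):
    """Whether group participation is forced or opt-in."""

    MANDATORY = "mandatory"
    VOLUNTARY = "voluntary"


class Action(str, Enum):
    """Cooperate within the group, defect within the group, or leave for the
    individual option (leaving only exists under voluntary participation)."""

    COOPERATE = "C"
    DEFECT = "D"
    LEAVE = "L"


#: Tie-break preference at exact expected-payoff indifference.  Boundaries
#: between best-response regions are measure zero under continuous beliefs,
#: so the rule only pins down which region owns its endpoint; the prosocial
#: ordering keeps region boundaries reproducible.
TIE_BREAK_ORDER = (Action.COOPERATE, Action.LEAVE, Action.DEFECT)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class GameSpec:
    """Constants of one game condition.

    Parameters
    ----------
    threshold
        Minimum number of cooperators (``q``) for the group to succeed.
    regime
        ``mandatory`` (actions C/D) or ``voluntary`` (actions C/D/L).
    group_size
        Number of seats per group (default 5).
    endowment
        Points every player starts with (default 10).
    group_reward
        Points added to every group member on success (default 30).
    outside_payoff
        Extra points secured by the individual option (default 10), on top
        of the endowment, so a loner's total is ``endowment + outside_payoff``.
    """

    threshold: int
    regime: Regime = Regime.VOLUNTARY
    group_size: int = 5
    endowment: float = 10.0
    group_reward: float = 30.0
    outside_payoff: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regime", Regime(self.regime))
        if not 1 <= self.threshold <= self.group_size:
            raise ValueError(
                f"threshold must lie in [1, group_size]; got {self.threshold} "
                f"with group_size={self.group_size}"
            )
        for name in ("endowment", "group_reward", "outside_payoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_others(self) -> int:
        """Number of co-players a group member faces."""
        return self.group_size - 1

    @property
    def loner_payoff(self) -> float:
        """Total points of a player at the individual option."""
        return self.endowment + self.outside_payoff

    def available_actions(self) -> tuple[Action, ...]:
        if self.regime is Regime.MANDATORY:
            return (Action.COOPERATE, Action.DEFECT)
        return (Action.COOPERATE, Action.DEFECT, Action.LEAVE)


def _check_gamma(gamma: float) -> None:
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"belief gamma must lie in [0, 1]; got {gamma}")


def tail_prob_others(gamma: float, k: int, n_others: int) -> float:
    """Probability that at least ``k`` of ``n_others`` co-players cooperate.

    Co-players cooperate independently with probability ``gamma``; the tail
    is the binomial upper tail sum_{j>=k} C(n_others, j) gamma^j (1-gamma)^(n-j).
    Returns 1 for ``k <= 0`` and 0 for ``k > n_others``.
    """
    _check_gamma(gamma)
    if k <= 0:
        return 1.0
    if k > n_others:
        return 0.0
    return float(stats.binom.sf(k - 1, n_others, gamma))


def expected_payoffs(gamma: float, spec: GameSpec) -> dict[Action, float]:
    """Expected total payoff of each available action under belief ``gamma``.

    With reward R, endowment e, outside option o and tail probabilities
    G_k over the ``group_size - 1`` others:

    * cooperate: ``R * G_{q-1}`` (the endowment is invested and lost on
      failure; on success the member nets the reward),
    * defect: ``e + R * G_q`` (keeps the endowment, free-rides on success),
    * leave: ``e + o`` — a constant, independent of the belief.
    """
    _check_gamma(gamma)
    q = spec.threshold
    n = spec.n_others
    out = {
        Action.COOPERATE: spec.group_reward * tail_prob_others(gamma, q - 1, n),
        Action.DEFECT: spec.endowment + spec.group_reward * tail_prob_others(gamma, q, n),
    }
    if spec.regime is Regime.VOLUNTARY:
        out[Action.LEAVE] = spec.loner_payoff
    return out


def best_response(gamma: float, spec: GameSpec) -> Action:
    """Action maximizing expected payoff under belief ``gamma``.

    Exact indifference is broken by :data:`TIE_BREAK_ORDER` (C over L over D).
    """
    payoffs = expected_payoffs(gamma, spec)
    best = max(payoffs.values())
    for action in TIE_BREAK_ORDER:
        if action in payoffs and payoffs[action] >= best - _TIE_TOL:
            return action
    raise AssertionError("unreachable")  # pragma: no cover


def pivotal_probability(gamma: float, spec: GameSpec) -> float:
    """Probability the focal player's cooperation is decisive.

    This is the chance that exactly ``threshold - 1`` of the other
    ``group_size - 1`` members cooperate, so the focal contribution is both
    necessary and sufficient for group success.
    """
    _check_gamma(gamma)
    return float(stats.binom.pmf(spec.threshold - 1, spec.n_others, gamma))


def realized_payoff(action: Action, n_cooperators_in_group: int, spec: GameSpec) -> float:
    """Total points after the round for one group member.

    ``n_cooperators_in_group`` counts all cooperators in the group,
    including the focal player when ``action`` is cooperate.  A loner's
    payoff ignores the group outcome entirely.
    """
    action = Action(action)
    if action is Action.LEAVE:
        if spec.regime is Regime.MANDATORY:
            raise ValueError("leave is unavailable under mandatory participation")
        return spec.loner_payoff
    if not 0 <= n_cooperators_in_group <= spec.group_size:
        raise ValueError(
            f"cooperator count must lie in [0, {spec.group_size}]; "
            f"got {n_cooperators_in_group}"
        )
    if action is Action.COOPERATE and n_cooperators_in_group < 1:
        raise ValueError("count includes the focal cooperator and cannot be 0")
    success = n_cooperators_in_group >= spec.threshold
    if action is Action.COOPERATE:
        return spec.group_reward if success else 0.0
    return spec.endowment + (spec.group_reward if success else 0.0)
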