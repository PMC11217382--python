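"""Population-level predictions from a belief distribution.

Heterogeneous players each hold a subjective belief gamma about others'
cooperativeness; the population distribution of beliefs phi(gamma) is
modelled as a Beta distribution.  Integrating the best-response partition
of [0, 1] against phi gives the population shares r_C, r_D, r_L of each
action, from which the within-group cooperation rate, group success
probability, efficiency, and the loner-externality variants follow.

Shares are computed analytically: region boundaries are located by
root-finding on pairwise expected-payoff differences and the Beta
cumulative mass of each region is summed — quadrature over the indicator
in the defining integral is unnecessary.  Monte-Carlo integration is kept
as an independent oracle in the test-suite only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache as _lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .game import Action, GameSpec, Regime, best_response, expected_payoffs

__all__ = [
    "UndefinedRateError",
    "BeliefDistribution",
    "ActionShares",
    "Region",
    "Equilibrium",
    "PopulationPrediction",
    "best_response_regions",
    "action_shares",
    "cooperation_rate",
    "effective_cooperation_rate",
    "group_success_rate",
    "expected_efficiency",
    "predict",
    "default_belief_grid",
    "sweep_beta",
    "find_symmetric_equilibria",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate whose denominator is empty (e.g. everyone left the group pool)."""


@dataclass(frozen=True)
class BeliefDistribution:
    """Beta(alpha, beta) distribution of beliefs gamma over [0, 1]."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")

    @property
    def frozen(self) -> stats.distributions.rv_frozen:
        return stats.beta(self.alpha, self.beta)

    def cdf(self, x: float) -> float:
        return float(self.frozen.cdf(x))

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @classmethod
    def from_mean_concentration(cls, mean: float, concentration: float) -> "BeliefDistribution":
        """Parameterize by mean mu and concentration nu: alpha = mu*nu, beta = (1-mu)*nu."""
        if not 0 < mean < 1:
            raise ValueError("mean must lie strictly inside (0, 1)")
        if concentration <= 0:
            raise ValueError("concentration must be positive")
        return cls(mean * concentration, (1.0 - mean) * concentration)


@dataclass(frozen=True)
class ActionShares:
    """Population fractions whose best response is each action."""

    r_C: float
    r_D: float
    r_L: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_C", "r_D", "r_L"):
            if not -1e-9 <= getattr(self, name) <= 1 + 1e-9:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def total(self) -> float:
        return self.r_C + self.r_D + self.r_L


@dataclass(frozen=True)
class Region:
    """Maximal belief interval on which one action is the best response."""

    lo: float
    hi: float
    action: Action

    @property
    def length(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class Equilibrium:
    """A self-consistent within-group cooperation rate.

    ``gamma`` is a fixed point of the consistency map: if every group
    participant holds belief gamma and best-responds, the resulting
    within-group cooperation probability is gamma again.  ``kind`` is
    ``pure`` at 0/1 plateaus and ``mixed`` at indifference boundaries
    (players mix between cooperation and defection).  ``stable`` annotates
    whether naive belief adjustment is attracted to the point.
    """

    gamma: float
    kind: str
    stable: bool


@dataclass(frozen=True)
class PopulationPrediction:
    shares: ActionShares
    p_coop: float
    p_success: float
    efficiency_within: float
    efficiency_population: float


_BOUNDARY_XTOL = 1e-12


def _tail_vec(gammas: np.ndarray, k: int, n_others: int) -> np.ndarray:
    if k <= 0:
        return np.ones_like(gammas)
    if k > n_others:
        return np.zeros_like(gammas)
    return stats.binom.sf(k - 1, n_others, gammas)


def _best_response_grid(gammas: np.ndarray, spec: GameSpec) -> list[Action]:
    """Vectorized best responses with the same tie-break as best_response."""
    from .game import TIE_BREAK_ORDER, _TIE_TOL

    q, n = spec.threshold, spec.n_others
    payoffs = {
        Action.COOPERATE: spec.group_reward * _tail_vec(gammas, q - 1, n),
        Action.DEFECT: spec.endowment + spec.group_reward * _tail_vec(gammas, q, n),
    }
    if spec.regime is Regime.VOLUNTARY:
        payoffs[Action.LEAVE] = np.full_like(gammas, spec.loner_payoff)
    best = np.max(np.column_stack(list(payoffs.values())), axis=1)
    out = np.empty(gammas.size, dtype=object)
    out.fill(None)
    for action in reversed(TIE_BREAK_ORDER):  # earlier preferences overwrite
        if action in payoffs:
            out[payoffs[action] >= best - _TIE_TOL] = action
    return list(out)


def best_response_regions(spec: GameSpec, n_grid: int = 8193) -> list[Region]:
    """See :func:`_best_response_regions_cached`; returns a fresh list."""
    return list(_best_response_regions_cached(spec, n_grid))


@_lru_cache(maxsize=None)
def _best_response_regions_cached(spec: GameSpec, n_grid: int) -> tuple[Region, ...]:
    """Partition [0, 1] into maximal intervals labelled by the best response.

    The best response is sampled on a uniform grid; each sign change is
    refined by Brent root-finding on the expected-payoff difference of the
    two adjacent actions (falling back to bisection on the best-response
    label if the difference does not bracket a root).  Boundaries are
    located to ~1e-12; a region narrower than the grid spacing would be
    missed, which cannot happen for the piecewise-monotone payoffs of the
    default game.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    labels = _best_response_grid(grid, spec)

    boundaries: list[float] = []
    cut_labels: list[Action] = [labels[0]]
    for i in range(n_grid - 1):
        if labels[i] is labels[i + 1]:
            continue
        a_left, a_right = labels[i], labels[i + 1]

        def payoff_gap(g: float) -> float:
            p = expected_payoffs(g, spec)
            return p[a_left] - p[a_right]

        lo, hi = grid[i], grid[i + 1]
        try:
            b = float(optimize.brentq(payoff_gap, lo, hi, xtol=_BOUNDARY_XTOL))
        except ValueError:
            # label bisection: shrink the bracket keeping the switch inside
            while hi - lo > _BOUNDARY_XTOL:
                mid = 0.5 * (lo + hi)
                if best_response(mid, spec) is a_left:
                    lo = mid
                else:
                    hi = mid
            b = 0.5 * (lo + hi)
        boundaries.append(b)
        cut_labels.append(a_right)

    edges = [0.0, *boundaries, 1.0]
    return tuple(
        Region(edges[i], edges[i + 1], cut_labels[i]) for i in range(len(cut_labels))
    )


def action_shares(dist: BeliefDistribution, spec: GameSpec) -> ActionShares:
    """Population action shares: Beta mass of each best-response region."""
    mass = {Action.COOPERATE: 0.0, Action.DEFECT: 0.0, Action.LEAVE: 0.0}
    for region in best_response_regions(spec):
        mass[region.action] += dist.cdf(region.hi) - dist.cdf(region.lo)
    total = sum(mass.values())
    if abs(total - 1.0) > 1e-9:  # partition property
        raise AssertionError(f"region masses sum to {total}, expected 1")
    return ActionShares(
        r_C=mass[Action.COOPERATE], r_D=mass[Action.DEFECT], r_L=mass[Action.LEAVE]
    )


def cooperation_rate(shares: ActionShares) -> float:
    """Within-group cooperation rate r_C / (r_C + r_D) among opt-ins."""
    denom = shares.r_C + shares.r_D
    if denom <= 0.0:
        raise UndefinedRateError("no one opts in: cooperation rate undefined")
    return shares.r_C / denom


def effective_cooperation_rate(shares: ActionShares, rho: float) -> float:
    """Cooperation rate r_C / (r_C + r_D + rho * r_L) under loner externality rho.

    ``rho`` in [0, 1] is the probability that a loner still occupies a group
    seat (contributing nothing).  At rho = 0 this is the plain within-group
    rate; at rho = 1 loners dilute groups exactly like defectors.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    denom = shares.r_C + shares.r_D + rho * shares.r_L
    if denom <= 0.0:
        raise UndefinedRateError("empty effective pool: rate undefined")
    return shares.r_C / denom


def group_success_rate(p_coop: float, spec: GameSpec) -> float:
    """Probability a group of ``group_size`` i.i.d.-cooperating members succeeds.

    Binomial upper tail: sum_{k>=q} C(G, k) p^k (1-p)^(G-k).
    """
    if not 0.0 <= p_coop <= 1.0:
        raise ValueError("p_coop must lie in [0, 1]")
    return float(stats.binom.sf(spec.threshold - 1, spec.group_size, p_coop))


def max_feasible_payoff(spec: GameSpec) -> float:
    """Per-capita payoff of the most efficient group: exactly q cooperators.

    q members net the reward, the rest keep the endowment and free-ride;
    under default payoffs this is (40 - 2q) points per person.
    """
    q, g = spec.threshold, spec.group_size
    total = q * spec.group_reward + (g - q) * (spec.endowment + spec.group_reward)
    return total / g


def expected_efficiency(
    shares: ActionShares, spec: GameSpec, include_loners: bool = False
) -> float:
    """Mean payoff per person, normalized by the exact-threshold optimum.

    Group participants' expected payoffs come from the expected-payoff
    model with the belief replaced by the realized within-group cooperation
    rate — each opt-in's co-members cooperate i.i.d. with probability
    p_coop (the same independent-composition approximation under which
    group success is computed from p_coop).  Loners contribute their sure
    payoff when ``include_loners`` is set.
    """
    opt_in = shares.r_C + shares.r_D
    if opt_in <= 0.0:
        if not include_loners:
            raise UndefinedRateError("no group participants: efficiency undefined")
        group_term = 0.0
    else:
        p = cooperation_rate(shares)
        payoffs = expected_payoffs(p, spec)
        group_term = (
            shares.r_C * payoffs[Action.COOPERATE] + shares.r_D * payoffs[Action.DEFECT]
        )
    if include_loners:
        mean = group_term + shares.r_L * spec.loner_payoff
        mean /= shares.total
    else:
        mean = group_term / opt_in
    return mean / max_feasible_payoff(spec)


def predict(dist: BeliefDistribution, spec: GameSpec, rho: float = 0.0) -> PopulationPrediction:
    """Full population prediction for one belief distribution and game."""
    shares = action_shares(dist, spec)
    p = effective_cooperation_rate(shares, rho)
    return PopulationPrediction(
        shares=shares,
        p_coop=p,
        p_success=group_success_rate(p, spec),
        efficiency_within=expected_efficiency(shares, spec, include_loners=False),
        efficiency_population=expected_efficiency(shares, spec, include_loners=True),
    )


def default_belief_grid() -> list[tuple[float, float]]:
    """Default sweep grid of Beta (alpha, beta) pairs.

    Parameterized by mean mu in {0.05, 0.10, ..., 0.95} and concentration
    nu in {1, 2, 5, 10, 20}; alpha = mu*nu, beta = (1-mu)*nu.
    """
    means = np.round(np.arange(0.05, 0.951, 0.05), 2)
    concentrations = (1.0, 2.0, 5.0, 10.0, 20.0)
    return [(float(m * n), float((1 - m) * n)) for n in concentrations for m in means]


def sweep_beta(
    pairs: Iterable[tuple[float, float]],
    mandatory_spec: GameSpec,
    voluntary_spec: GameSpec,
) -> pd.DataFrame:
    """Cooperation rates under both regimes across a grid of Beta beliefs.

    Returns one row per (alpha, beta) with columns ``p_coop_mandatory``,
    ``p_coop_voluntary`` and ``delta_p_coop``.  Cells where the voluntary
    rate is undefined (everyone leaves) are flagged ``defined = False``
    and carry NaN rates rather than being dropped.
    """
    if mandatory_spec.regime is not Regime.MANDATORY:
        raise ValueError("mandatory_spec must have the mandatory regime")
    if voluntary_spec.regime is not Regime.VOLUNTARY:
        raise ValueError("voluntary_spec must have the voluntary regime")
    rows = []
    for alpha, beta in pairs:
        dist = BeliefDistribution(alpha, beta)
        p_mand = cooperation_rate(action_shares(dist, mandatory_spec))
        try:
            p_vol = cooperation_rate(action_shares(dist, voluntary_spec))
            defined = True
        except UndefinedRateError:
            p_vol = float("nan")
            defined = False
        rows.append(
            {
                "alpha": alpha,
                "beta": beta,
                "p_coop_mandatory": p_mand,
                "p_coop_voluntary": p_vol,
                "delta_p_coop": p_vol - p_mand if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def _consistency(gamma: float, spec: GameSpec) -> float | None:
    """Within-group cooperation rate when everyone believes gamma and
    best-responds; None when no one participates (voluntary all-leave)."""
    br = best_response(gamma, spec)
    if br is Action.LEAVE:
        return None
    return 1.0 if br is Action.COOPERATE else 0.0


def find_symmetric_equilibria(spec: GameSpec, tol: float = 1e-8) -> list[Equilibrium]:
    """Fixed points of the symmetric belief-consistency map.

    Pure equilibria sit at gamma in {0, 1} where the unanimous best
    response reproduces the belief.  Mixed equilibria sit at interior
    boundaries between cooperate and defect regions, where players are
    indifferent and can mix with the boundary probability.  Under
    voluntary participation, beliefs whose best response is to leave
    support no group at all, so the all-defect point is eliminated
    whenever leaving dominates defection there (as it does for default
    payoffs: a sure loner payoff beats the endowment alone).
    """
    regions = best_response_regions(spec)
    out: list[Equilibrium] = []

    for g in (0.0, 1.0):
        m = _consistency(g, spec)
        if m is not None and abs(m - g) <= tol:
            # stable if the map points toward the endpoint from inside
            eps = 1e-6
            inner = _consistency(abs(g - eps), spec)
            stable = inner is not None and (
                (g == 0.0 and inner - eps < 0) or (g == 1.0 and inner - (1 - eps) > 0)
            )
            out.append(Equilibrium(gamma=g, kind="pure", stable=stable))

    for left, right in zip(regions, regions[1:]):
        pair = {left.action, right.action}
        if pair != {Action.COOPERATE, Action.DEFECT}:
            continue  # L boundaries: joiners are unanimous, no interior fix point
        b = left.hi
        if not tol < b < 1 - tol:
            continue
        # upward jump (D below, C above) is repelling; downward is attracting
        stable = left.action is Action.COOPERATE
        out.append(Equilibrium(gamma=b, kind="mixed", stable=stable))

    return sorted(out, key=lambda e: e.gamma)
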