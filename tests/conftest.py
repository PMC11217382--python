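"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: expected
payoffs are brute-forced by enumerating every co-player profile, and
population shares are Monte-Carlo integrated with a from-scratch argmax
over explicit binomial formulas.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from volpgg import Action, GameSpec, Regime


@pytest.fixture(scope="session")
def default_specs() -> dict[tuple[int, str], GameSpec]:
    return {
        (q, regime.value): GameSpec(threshold=q, regime=regime)
        for q in (2, 4, 5)
        for regime in (Regime.MANDATORY, Regime.VOLUNTARY)
    }


def brute_force_expected_payoffs(gamma: float, spec: GameSpec) -> dict[Action, float]:
    """Expected payoffs by enumerating all 2^(group_size-1) co-player profiles.

    Each profile of cooperating/defecting co-players is weighted by its
    binomial probability under gamma; the focal player's realized payoff is
    applied profile by profile, straight from the game rules.
    """
    n = spec.group_size - 1
    e_coop = 0.0
    e_defect = 0.0
    for profile in itertools.product((0, 1), repeat=n):
        k = sum(profile)
        w = gamma**k * (1 - gamma) ** (n - k)
        # focal cooperates: k+1 cooperators in the group
        success_c = (k + 1) >= spec.threshold
        e_coop += w * (spec.group_reward if success_c else 0.0)
        # focal defects: k cooperators
        success_d = k >= spec.threshold
        e_defect += w * (spec.endowment + (spec.group_reward if success_d else 0.0))
    out = {Action.COOPERATE: e_coop, Action.DEFECT: e_defect}
    if spec.regime is Regime.VOLUNTARY:
        out[Action.LEAVE] = spec.endowment + spec.outside_payoff
    return out


def monte_carlo_shares(
    alpha: float, beta: float, spec: GameSpec, n_draws: int, seed: int
) -> dict[Action, float]:
    """Population shares by Monte-Carlo: draw beliefs, argmax explicit payoffs.

    Uses closed-form binomial tails written out with math.comb rather than
    any library routine, so it is independent of the implementation.
    """
    rng = np.random.default_rng(seed)
    gammas = rng.beta(alpha, beta, size=n_draws)
    n = spec.group_size - 1

    def tail(g: np.ndarray, k: int) -> np.ndarray:
        if k <= 0:
            return np.ones_like(g)
        if k > n:
            return np.zeros_like(g)
        return sum(
            math.comb(n, j) * g**j * (1 - g) ** (n - j) for j in range(k, n + 1)
        )

    q = spec.threshold
    e = {
        Action.COOPERATE: spec.group_reward * tail(gammas, q - 1),
        Action.DEFECT: spec.endowment + spec.group_reward * tail(gammas, q),
    }
    if spec.regime is Regime.VOLUNTARY:
        e[Action.LEAVE] = np.full(n_draws, spec.endowment + spec.outside_payoff)
    actions = list(e)
    stacked = np.column_stack([e[a] for a in actions])
    best = stacked.argmax(axis=1)
    return {a: float(np.mean(best == i)) for i, a in enumerate(actions)}
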