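"""Synthetic participant cohorts with the statistical structure the analysis assumes.

The generator emulates a within-subject session experiment: ~30-person
sessions, a 2 (mandatory/voluntary) x 3 (threshold q = 2, 4, 5) design
— or the 3-level loner-externality design (q = 4, rho in {0, 0.5, 1}) —
with beliefs about 30 others elicited as integer counts per action,
condition-dependent Beta-distributed latent beliefs, an optional optimism
shift when moving from mandatory to voluntary play, and noisy
best-response action choice (softmax over expected payoffs).

Every generative default here is a synthetic stand-in chosen to produce
qualitatively realistic patterns (pessimists defect or leave, optimism
rises under voluntary play); none is an estimate fitted to experimental
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .game import Action, GameSpec, Regime

__all__ = [
    "CohortConfig",
    "RECORD_COLUMNS",
    "DEFAULT_BELIEF_MODEL",
    "DEFAULT_RHO_BELIEF_MODEL",
    "generate_cohort",
    "generate_externality_cohort",
    "effective_belief_from_counts",
    "fit_beta_binomial_mom",
]

#: Canonical tidy-table schema, one row per participant x condition.
RECORD_COLUMNS = [
    "participant_id",
    "session_id",
    "regime",
    "threshold",
    "rho",
    "est_C",
    "est_D",
    "est_L",
    "confidence",
    "action",
    "condition_order",
]

ESTIMATE_TOTAL = 30

#: Mandatory-condition belief distributions per threshold, Beta(alpha, beta).
#: Means around 0.6-0.7 with moderate concentration give mixed cooperation
#: and both fear- and greed-driven defection at the low thresholds.
DEFAULT_BELIEF_MODEL: dict[int, tuple[float, float]] = {
    2: (3.9, 2.1),
    4: (3.6, 2.4),
    5: (4.2, 1.8),
}

#: Logit-scale optimism shift applied (to a subset of participants) when
#: moving from the mandatory to the voluntary condition of a threshold.
DEFAULT_OPTIMISM_SHIFT: dict[int, float] = {2: 1.0, 4: 1.2, 5: 2.0}

#: Externality-design belief distributions per rho level, over the believed
#: *effective* cooperation rate (the quantity that design elicits and that
#: drives decisions): participants grow more pessimistic as rho rises.
DEFAULT_RHO_BELIEF_MODEL: dict[float, tuple[float, float]] = {
    0.0: (4.2, 1.8),
    0.5: (3.6, 2.4),
    1.0: (3.0, 3.0),
}

_GAMMA_EPS = 1e-6


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and generative parameters for one synthetic cohort.

    Parameters
    ----------
    n_participants
        Cohort size (main design default 191; the externality design uses 182).
    n_sessions
        Sessions the cohort is split into; sizes are as equal as possible.
    session_sizes
        Explicit per-session sizes; must sum to ``n_participants``.
    thresholds
        Threshold values of the main 2x3 design.
    belief_model
        Mandatory-condition Beta(alpha, beta) per threshold (main design)
        or Beta per rho level (externality design).
    optimism_shift
        Per-threshold additive logit shift delta applied to shifted
        participants' beliefs in the voluntary conditions.
    shift_fraction
        Fraction of participants who apply the optimism shift.
    belief_correlation
        Gaussian-copula correlation of a participant's latent belief
        quantile across conditions (stable individual differences).
    decision_noise
        Softmax temperature lambda (points) over expected payoffs;
        lambda = 0 is exact best response.
    rho_levels
        Externality levels of the additional design (ignored by the main
        design generator).
    threshold_rho_design
        Threshold used in the externality design.
    game
        Payoff constants; the regime field is overridden per condition.
    seed
        RNG seed; identical configs generate byte-identical tables.
    """

    n_participants: int = 191
    n_sessions: int = 6
    session_sizes: tuple[int, ...] | None = None
    thresholds: tuple[int, ...] = (2, 4, 5)
    belief_model: Mapping[int | float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BELIEF_MODEL)
    )
    optimism_shift: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OPTIMISM_SHIFT)
    )
    shift_fraction: float = 0.5
    belief_correlation: float = 0.6
    decision_noise: float = 2.0
    rho_levels: tuple[float, ...] = (0.0, 0.5, 1.0)
    threshold_rho_design: int = 4
    game: GameSpec = field(default_factory=lambda: GameSpec(threshold=4))
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ValueError("shift_fraction must lie in [0, 1]")
        if not 0.0 <= self.belief_correlation <= 1.0:
            raise ValueError("belief_correlation must lie in [0, 1]")
        if self.decision_noise < 0:
            raise ValueError("decision_noise must be non-negative")
        if self.session_sizes is not None and sum(self.session_sizes) != self.n_participants:
            raise ValueError("session_sizes must sum to n_participants")
        for rho in self.rho_levels:
            if not 0.0 <= rho <= 1.0:
                raise ValueError("rho levels must lie in [0, 1]")

    def resolved_session_sizes(self) -> tuple[int, ...]:
        if self.session_sizes is not None:
            return tuple(self.session_sizes)
        base, extra = divmod(self.n_participants, self.n_sessions)
        return tuple(base + (1 if i < extra else 0) for i in range(self.n_sessions))


def _spec_for(config: CohortConfig, threshold: int, regime: Regime) -> GameSpec:
    return replace(config.game, threshold=threshold, regime=regime)


def _choice_prob_matrix(
    gammas: np.ndarray, spec: GameSpec, lam: float
) -> tuple[list[Action], np.ndarray]:
    """Vectorized softmax choice probabilities, one row per belief.

    At lam = 0 rows are one-hot on the best response (same tie-break as
    the scalar path).
    """
    from .population import _best_response_grid, _tail_vec

    q, n = spec.threshold, spec.n_others
    cols = {
        Action.COOPERATE: spec.group_reward * _tail_vec(gammas, q - 1, n),
        Action.DEFECT: spec.endowment + spec.group_reward * _tail_vec(gammas, q, n),
    }
    if spec.regime is Regime.VOLUNTARY:
        cols[Action.LEAVE] = np.full_like(gammas, spec.loner_payoff)
    actions = list(cols)
    payoff = np.column_stack([cols[a] for a in actions])
    if lam == 0.0:
        labels = _best_response_grid(gammas, spec)
        probs = np.zeros_like(payoff)
        index = {a: j for j, a in enumerate(actions)}
        probs[np.arange(len(labels)), [index[a] for a in labels]] = 1.0
    else:
        w = np.exp((payoff - payoff.max(axis=1, keepdims=True)) / lam)
        probs = w / w.sum(axis=1, keepdims=True)
    return actions, probs


def _draw_from_probs(
    actions: list[Action], p: np.ndarray, rng: np.random.Generator
) -> Action:
    """One action draw; deterministic (no rng use) when the row is one-hot."""
    j = int(np.argmax(p))
    if p[j] >= 1.0:
        return actions[j]
    return actions[rng.choice(len(actions), p=p)]


def _correlated_quantiles(
    rng: np.random.Generator, n_participants: int, n_conditions: int, corr: float
) -> np.ndarray:
    """(n_participants, n_conditions) uniforms with a shared Gaussian factor."""
    z_shared = rng.standard_normal((n_participants, 1))
    z_cond = rng.standard_normal((n_participants, n_conditions))
    z = corr * z_shared + np.sqrt(1.0 - corr**2) * z_cond
    return norm.cdf(z)


def _expected_leave_share(
    gammas: np.ndarray, spec: GameSpec, lam: float
) -> float:
    """Population leave share implied by the generative decision rule.

    Participants project the cohort-level behaviour when estimating how
    many of 30 others will leave; this evaluates the softmax leave
    probability over a sample of latent beliefs.
    """
    if spec.regime is Regime.MANDATORY:
        return 0.0
    actions, probs = _choice_prob_matrix(gammas, spec, lam)
    return float(probs[:, actions.index(Action.LEAVE)].mean())


def _estimate_counts(
    gamma: float, leave_share: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Elicited integer counts of 30 others per action.

    Counts are multinomial around the participant's implied expectation:
    a fraction ``leave_share`` of others leave, and those who stay
    cooperate with probability ``gamma``.  Multinomial rounding gives the
    elicited data realistic integer noise.
    """
    p = np.array(
        [(1 - leave_share) * gamma, (1 - leave_share) * (1 - gamma), leave_share]
    )
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    c, d, l = rng.multinomial(ESTIMATE_TOTAL, p)
    return int(c), int(d), int(l)


def _session_ids(config: CohortConfig) -> list[str]:
    ids = []
    for s, size in enumerate(config.resolved_session_sizes(), start=1):
        ids.extend([f"s{s}"] * size)
    if len(ids) != config.n_participants:
        raise AssertionError("session sizes inconsistent with cohort size")
    return ids


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the main 2 (regime) x 3 (threshold) within-subject cohort.

    One row per participant per condition (6 rows each).  Latent beliefs
    are drawn per condition from the mandatory belief model through a
    shared participant-level quantile (Gaussian copula); voluntary-condition
    beliefs apply the logit-scale optimism shift to the shifted subset;
    actions are softmax draws over expected payoffs at the participant's
    belief; estimated counts are multinomial around the implied shares.
    """
    for q in config.thresholds:
        if q not in config.belief_model:
            raise ValueError(f"belief_model missing threshold {q}")
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    qs = list(config.thresholds)
    lam = config.decision_noise

    session_ids = _session_ids(config)
    shifted = rng.random(n) < config.shift_fraction
    # one latent quantile per participant per threshold, shared across regimes
    u = _correlated_quantiles(rng, n, len(qs), config.belief_correlation)

    gamma = {}  # (q, regime) -> per-participant beliefs
    for j, q in enumerate(qs):
        a, b = config.belief_model[q]
        g_mand = beta_dist.ppf(u[:, j], a, b)
        g_mand = np.clip(g_mand, _GAMMA_EPS, 1 - _GAMMA_EPS)
        delta = config.optimism_shift.get(q, 0.0)
        g_vol = expit(logit(g_mand) + delta * shifted)
        gamma[(q, Regime.MANDATORY)] = g_mand
        gamma[(q, Regime.VOLUNTARY)] = np.clip(g_vol, _GAMMA_EPS, 1 - _GAMMA_EPS)

    # cohort-level leave share participants project when estimating others,
    # and per-participant choice probabilities, both vectorized per condition
    leave_share = {}
    choice = {}
    for q in qs:
        for regime in (Regime.MANDATORY, Regime.VOLUNTARY):
            spec = _spec_for(config, q, regime)
            leave_share[(q, regime)] = _expected_leave_share(
                gamma[(q, regime)], spec, lam
            )
            choice[(q, regime)] = _choice_prob_matrix(gamma[(q, regime)], spec, lam)

    # condition order: half play all voluntary conditions first
    vol_first = np.zeros(n, dtype=bool)
    vol_first[rng.permutation(n)[: n // 2]] = True

    rows = []
    for i in range(n):
        pid = f"p{i + 1:04d}"
        blocks = (
            [Regime.VOLUNTARY, Regime.MANDATORY]
            if vol_first[i]
            else [Regime.MANDATORY, Regime.VOLUNTARY]
        )
        order = 0
        for regime in blocks:
            for q in rng.permutation(qs):
                q = int(q)
                order += 1
                g = float(gamma[(q, regime)][i])
                # leave_share is 0 under mandatory, so est_L is 0 there
                est_c, est_d, est_l = _estimate_counts(
                    g, leave_share[(q, regime)], rng
                )
                actions, probs = choice[(q, regime)]
                action = _draw_from_probs(actions, probs[i], rng)
                rows.append(
                    {
                        "participant_id": pid,
                        "session_id": session_ids[i],
                        "regime": regime.value,
                        "threshold": q,
                        "rho": np.nan,
                        "est_C": est_c,
                        "est_D": est_d,
                        "est_L": est_l,
                        "confidence": int(rng.integers(0, 101)),
                        "action": action.value,
                        "condition_order": order,
                    }
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def effective_belief_from_counts(
    est_C: int, est_D: int, est_L: int, rho: float
) -> float:
    """Effective cooperation rate implied by elicited counts under externality rho.

    ``est_C / (est_C + est_D + rho * est_L)``; an empty denominator (no one
    believed to matter for group outcomes) is treated as zero cooperation,
    the maximally pessimistic reading used by the generator's decision rule.
    """
    denom = est_C + est_D + rho * est_L
    if denom <= 0:
        return 0.0
    return est_C / denom


def generate_externality_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the 3-level loner-externality cohort (voluntary, q fixed).

    One row per participant per rho level, in randomized order.  Beliefs
    are drawn per rho level from ``config.belief_model`` keyed by rho;
    actions are chosen against expected payoffs evaluated at the effective
    cooperation rate implied by the participant's own reported counts
    (so the elicitation, not the latent belief, drives the decision).
    """
    levels = tuple(config.rho_levels)
    if len(levels) < 1:
        raise ValueError("need at least one rho level")
    for rho in levels:
        if rho not in config.belief_model:
            raise ValueError(f"belief_model missing rho level {rho}")
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    q = config.threshold_rho_design
    lam = config.decision_noise
    spec = _spec_for(config, q, Regime.VOLUNTARY)

    session_ids = _session_ids(config)
    u = _correlated_quantiles(rng, n, len(levels), config.belief_correlation)

    gamma = {}
    counts = {}
    choice = {}
    for j, rho in enumerate(levels):
        a, b = config.belief_model[rho]
        # latent belief about the EFFECTIVE cooperation rate at this level
        g = np.clip(beta_dist.ppf(u[:, j], a, b), _GAMMA_EPS, 1 - _GAMMA_EPS)
        gamma[rho] = g
        ls = _expected_leave_share(g, spec, lam)
        # counts consistent with the effective-rate belief: with believed
        # leave share ls, p_C solves p_C / (p_C + p_D + rho*ls) = gamma
        p_c = np.clip(g * (1 - ls + rho * ls), 0.0, 1 - ls)
        p_d = np.clip(1 - ls - p_c, 0.0, None)
        pmat = np.column_stack([p_c, p_d, np.full(n, ls)])
        pmat /= pmat.sum(axis=1, keepdims=True)
        counts[rho] = rng.multinomial(ESTIMATE_TOTAL, pmat)
        g_eff = np.array(
            [effective_belief_from_counts(c, d, l, rho) for c, d, l in counts[rho]]
        )
        choice[rho] = _choice_prob_matrix(g_eff, spec, lam)

    rows = []
    for i in range(n):
        pid = f"p{i + 1:04d}"
        for order, level_idx in enumerate(rng.permutation(len(levels)), start=1):
            rho = levels[int(level_idx)]
            est_c, est_d, est_l = (int(x) for x in counts[rho][i])
            actions, probs = choice[rho]
            action = _draw_from_probs(actions, probs[i], rng)
            rows.append(
                {
                    "participant_id": pid,
                    "session_id": session_ids[i],
                    "regime": Regime.VOLUNTARY.value,
                    "threshold": q,
                    "rho": rho,
                    "est_C": est_c,
                    "est_D": est_d,
                    "est_L": est_l,
                    "confidence": int(rng.integers(0, 101)),
                    "action": action.value,
                    "condition_order": order,
                }
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def fit_beta_binomial_mom(counts: Sequence[int], n_trials: int = ESTIMATE_TOTAL) -> tuple[float, float]:
    """Method-of-moments Beta fit to elicited integer counts.

    Counts of cooperators among ``n_trials`` imagined others are
    beta-binomial when latent beliefs are Beta(alpha, beta): the binomial
    rounding noise is part of the model, so matching the beta-binomial
    mean and variance deconvolves it and recovers the latent shape
    parameters.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two counts")
    m = x.mean()
    v = x.var(ddof=1)
    pi = m / n_trials
    if not 0 < pi < 1:
        raise ValueError("degenerate counts: mean at the boundary")
    base = n_trials * pi * (1 - pi)
    if v <= base / n_trials:
        raise ValueError("counts underdispersed relative to any Beta mixture")
    # Var = n pi (1-pi) (theta + n) / (theta + 1) with theta = alpha + beta
    ratio = v / base
    theta = (n_trials - ratio) / (ratio - 1.0)
    if theta <= 0:
        raise ValueError("counts overdispersed beyond the beta-binomial family")
    return pi * theta, (1 - pi) * theta
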