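"""Statistical pipeline for participant-level choice/belief tables.

Implements the study's analysis surface: elicited-count-to-belief
conversion, per-condition summaries (cooperation rate, analytic group
success, normalized efficiencies), participant-resampled percentile
bootstrap confidence intervals, random-intercept logistic regressions,
rank-based ROC comparison of raw beliefs versus pivotal probabilities,
and the paired mandatory/voluntary belief- and action-change table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .cohort import RECORD_COLUMNS
from .game import Action, GameSpec, Regime, pivotal_probability
from .population import (
    ActionShares,
    UndefinedRateError,
    expected_efficiency,
    group_success_rate,
)

__all__ = [
    "ConditionSummary",
    "BootstrapCI",
    "RegressionResult",
    "ROCResult",
    "elicited_belief_to_gamma",
    "add_gamma_column",
    "summarize_conditions",
    "bootstrap_ci",
    "fit_random_intercept_logit",
    "roc_compare",
    "belief_action_change",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Counts and aggregate rates for one experimental condition."""

    regime: str
    threshold: int
    rho: float | None
    n_C: int
    n_D: int
    n_L: int
    p_coop: float
    p_success: float
    efficiency_within: float
    efficiency_population: float

    @property
    def n(self) -> int:
        return self.n_C + self.n_D + self.n_L


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for one statistic.

    The point estimate comes from the original data; the interval is the
    2.5/97.5 percentile range of the statistic over participant-level
    resamples.  ``n_undefined`` counts resamples where the statistic was
    undefined (NaN) and therefore excluded from the percentiles.
    """

    label: str
    point: float
    ci_low: float
    ci_high: float
    n_iterations: int
    n_undefined: int
    seed: int | None

    def __post_init__(self) -> None:
        if not np.isnan(self.ci_low) and self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    @property
    def significant(self) -> bool:
        """Primary decision rule: the 95% CI does not contain zero."""
        return bool(self.ci_low > 0 or self.ci_high < 0)


@dataclass(frozen=True)
class RegressionResult:
    """Random-intercept logistic fit: coefficient table and metadata."""

    label: str
    params: pd.DataFrame  # index: term; columns: coef, sd, z, p, ci_low, ci_high
    random_intercept_sd: float
    n_obs: int
    n_groups: int
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])


@dataclass(frozen=True)
class ROCResult:
    """Rank-based AUC of one predictor of within-group cooperation."""

    predictor: str
    auc: float
    n: int
    threshold: int
    regime: str


def elicited_belief_to_gamma(
    est_C: int, est_D: int, est_L: int, regime: str | Regime, rho: float | None = None
) -> float:
    """Convert elicited counts of 30 others to a cooperativeness belief.

    Mandatory conditions: ``est_C / 30`` (everyone is in a group).
    Voluntary main-design conditions: ``est_C / (est_C + est_D)`` — the
    believed cooperation rate among those who opt in, the quantity that
    determines group outcomes.  Externality conditions (``rho`` given):
    ``est_C / (est_C + est_D + rho * est_L)``, the believed effective
    cooperation rate.  Returns NaN when the denominator is empty.
    """
    regime = Regime(regime)
    if regime is Regime.MANDATORY:
        return est_C / 30.0
    if rho is not None and not np.isnan(rho):
        denom = est_C + est_D + rho * est_L
    else:
        denom = est_C + est_D
    if denom <= 0:
        return float("nan")
    return est_C / denom


def add_gamma_column(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the tidy table with a ``gamma`` belief column."""
    out = records.copy()
    rho = out["rho"] if "rho" in out else pd.Series(np.nan, index=out.index)
    out["gamma"] = [
        elicited_belief_to_gamma(c, d, l, reg, r)
        for c, d, l, reg, r in zip(
            out["est_C"], out["est_D"], out["est_L"], out["regime"], rho
        )
    ]
    return out


def _validate_schema(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"tidy table missing columns: {missing}")


def _condition_groups(records: pd.DataFrame):
    """Group rows by condition: (regime, threshold) or rho level."""
    if records["rho"].notna().any():
        return records.groupby(["regime", "threshold", "rho"], dropna=False)
    return records.groupby(["regime", "threshold"], dropna=False)


def summarize_conditions(
    records: pd.DataFrame, game: GameSpec | None = None
) -> list[ConditionSummary]:
    """Per-condition counts, cooperation rate, success rate and efficiencies.

    The cooperation rate is the empirical #C/(#C+#D) (effective rate
    #C/(#C+#D+rho*#L) in externality conditions); group success is the
    analytic binomial tail at that rate; efficiencies use the analytic
    efficiency model at the empirical action shares.  Conditions with no
    opt-ins carry NaN rates rather than being dropped.
    """
    _validate_schema(records)
    base = game if game is not None else GameSpec(threshold=4)
    out: list[ConditionSummary] = []
    for key, block in _condition_groups(records):
        regime = str(block["regime"].iloc[0])
        q = int(block["threshold"].iloc[0])
        rho_val = block["rho"].iloc[0]
        rho = None if pd.isna(rho_val) else float(rho_val)
        counts = block["action"].value_counts()
        n_c, n_d, n_l = (int(counts.get(a, 0)) for a in ("C", "D", "L"))
        n = n_c + n_d + n_l
        spec = GameSpec(
            threshold=q,
            regime=Regime(regime),
            group_size=base.group_size,
            endowment=base.endowment,
            group_reward=base.group_reward,
            outside_payoff=base.outside_payoff,
        )
        shares = ActionShares(n_c / n, n_d / n, n_l / n) if n else ActionShares(0, 0, 0)
        denom = n_c + n_d + (rho if rho is not None else 0.0) * n_l
        if denom > 0:
            p_coop = n_c / denom
            p_success = group_success_rate(p_coop, spec)
        else:
            p_coop = float("nan")
            p_success = float("nan")
        try:
            eff_within = expected_efficiency(shares, spec, include_loners=False)
        except UndefinedRateError:
            eff_within = float("nan")
        eff_pop = (
            expected_efficiency(shares, spec, include_loners=True)
            if n
            else float("nan")
        )
        out.append(
            ConditionSummary(
                regime=regime,
                threshold=q,
                rho=rho,
                n_C=n_c,
                n_D=n_d,
                n_L=n_l,
                p_coop=p_coop,
                p_success=p_success,
                efficiency_within=eff_within,
                efficiency_population=eff_pop,
            )
        )
    return out


Statistic = Callable[[pd.DataFrame], float]


def bootstrap_ci(
    records: pd.DataFrame,
    statistic: Statistic | Mapping[str, Statistic],
    n_iterations: int = 1000,
    seed: int | None = None,
    participant_col: str = "participant_id",
) -> BootstrapCI | dict[str, BootstrapCI]:
    """Participant-resampled percentile bootstrap.

    Participants are resampled with replacement; all of a participant's
    condition rows move together, and each draw is relabelled as a new
    participant so repeated draws of the same person count as distinct
    clusters.  When ``statistic`` is a mapping of labelled statistics, one
    shared resampling stream drives all of them jointly (the statistics
    are computed on the same resamples rather than independently).
    Resamples where a statistic is undefined (NaN) are excluded from its
    percentiles and counted in ``n_undefined``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    stats_map: Mapping[str, Statistic]
    single = callable(statistic)
    stats_map = {"statistic": statistic} if single else dict(statistic)

    ids = records[participant_col].to_numpy()
    unique_ids, inverse = np.unique(ids, return_inverse=True)
    n_participants = unique_ids.size
    # positional row indices per participant, resampled as whole blocks
    row_idx: list[np.ndarray] = [
        np.flatnonzero(inverse == k) for k in range(n_participants)
    ]
    rng = np.random.default_rng(seed)

    points = {label: float(fn(records)) for label, fn in stats_map.items()}
    draws: dict[str, list[float]] = {label: [] for label in stats_map}
    for _ in range(n_iterations):
        chosen = rng.integers(0, n_participants, size=n_participants)
        take = np.concatenate([row_idx[k] for k in chosen])
        resampled = records.take(take).reset_index(drop=True)
        # relabel: each draw is a fresh participant
        resampled[participant_col] = np.repeat(
            np.arange(n_participants), [row_idx[k].size for k in chosen]
        )
        for label, fn in stats_map.items():
            draws[label].append(float(fn(resampled)))

    out: dict[str, BootstrapCI] = {}
    for label in stats_map:
        values = np.asarray(draws[label])
        defined = values[~np.isnan(values)]
        n_undef = int(values.size - defined.size)
        if defined.size:
            lo, hi = np.percentile(defined, [2.5, 97.5])
        else:
            lo = hi = float("nan")
        out[label] = BootstrapCI(
            label=label,
            point=points[label],
            ci_low=float(lo),
            ci_high=float(hi),
            n_iterations=n_iterations,
            n_undefined=n_undef,
            seed=seed,
        )
    return out["statistic"] if single else out


def _glmm_negloglik(
    theta: np.ndarray,
    y: np.ndarray,
    exog: np.ndarray,
    group_starts: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Negative marginal log-likelihood of a random-intercept logit.

    The participant intercept is integrated out with Gauss-Hermite
    quadrature: for node z_k the intercept offset is sqrt(2)*sigma*z_k and
    the group's conditional log-likelihoods are mixed with weights
    w_k / sqrt(pi).
    """
    beta, sigma = theta[:-1], abs(theta[-1])
    eta = exog @ beta  # (n,)
    offsets = np.sqrt(2.0) * sigma * nodes  # (K,)
    # log p(y_i | eta_i + off_k), shape (n, K); logaddexp form is stable
    lp = -np.logaddexp(0.0, -(eta[:, None] + offsets[None, :]))
    lq = -np.logaddexp(0.0, eta[:, None] + offsets[None, :])
    ll_obs = np.where(y[:, None] > 0.5, lp, lq)
    ll_group = np.add.reduceat(ll_obs, group_starts, axis=0)  # (G, K)
    logw = np.log(weights / np.sqrt(np.pi))
    from scipy.special import logsumexp

    return -float(np.sum(logsumexp(ll_group + logw[None, :], axis=1)))


def fit_random_intercept_logit(
    data: pd.DataFrame,
    outcome: str,
    fixed_effects: Sequence[str],
    group: str = "participant_id",
    label: str | None = None,
    n_quad: int = 21,
) -> RegressionResult:
    """Random-intercept logistic regression (one intercept per participant).

    Maximum-likelihood fit with the participant intercept integrated out
    by ``n_quad``-point Gauss-Hermite quadrature (the classical mixed-logit
    likelihood); standard errors come from the numerical Hessian at the
    optimum.  Coefficient point values are estimation-backend-dependent;
    the stable surface is sign and interval coverage.  Apparent
    non-convergence (e.g. complete separation) is reported through
    ``converged`` and a warning, never silently ignored.
    """
    from scipy.optimize import minimize
    from statsmodels.tools.numdiff import approx_hess

    d = data.dropna(subset=[outcome, *fixed_effects, group])
    codes, groups = pd.factorize(d[group])
    order = np.argsort(codes, kind="stable")
    d = d.iloc[order]
    codes = codes[order]
    y = d[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    exog = np.column_stack(
        [np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in fixed_effects]
    )
    names = ["intercept", *fixed_effects]
    group_starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    from statsmodels.api import Logit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = Logit(y, exog).fit(disp=0, maxiter=200).params
        except Exception:  # plain logit may fail outright under separation
            beta0 = np.zeros(exog.shape[1])
    theta0 = np.r_[beta0, 0.5]

    args = (y, exog, group_starts, nodes, weights)
    res = minimize(_glmm_negloglik, theta0, args=args, method="BFGS")
    theta = res.x
    # BFGS with numerical gradients often stops on "precision loss" at a
    # genuine optimum; a near-zero score is the meaningful criterion
    converged = bool(res.success) or (
        res.jac is not None and float(np.max(np.abs(res.jac))) < 0.5
    )

    k = exog.shape[1]
    coefs = np.asarray(theta[:k], dtype=float)
    hess = approx_hess(theta, _glmm_negloglik, args=args)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        var = np.diag(cov)[:k]
        sds = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
    if np.any(np.abs(coefs) > 15) or np.any(~np.isfinite(sds)):
        converged = False
    if not converged:
        warnings.warn(
            "mixed logistic fit did not converge cleanly (possible separation)",
            RuntimeWarning,
            stacklevel=2,
        )
    z = coefs / sds
    p = 2 * norm.sf(np.abs(z))
    params = pd.DataFrame(
        {
            "coef": coefs,
            "sd": sds,
            "z": z,
            "p": p,
            "ci_low": coefs - 1.96 * sds,
            "ci_high": coefs + 1.96 * sds,
        },
        index=names,
    )
    return RegressionResult(
        label=label or outcome,
        params=params,
        random_intercept_sd=float(abs(theta[-1])),
        n_obs=int(len(d)),
        n_groups=int(groups.size),
        converged=converged,
    )


def roc_compare(records: pd.DataFrame, spec: GameSpec) -> tuple[ROCResult, ROCResult]:
    """AUC of raw beliefs vs. pivotal probabilities for predicting cooperation.

    Rows must belong to a single condition; loners are excluded.  Both
    predictors are ranked against the binary cooperate/defect outcome with
    midrank tie handling.  Because the pivotal probability is a strictly
    increasing transform of the belief when the threshold equals the group
    size, the two AUCs coincide exactly there.
    """
    d = add_gamma_column(records)
    d = d[d["action"].isin(["C", "D"])].dropna(subset=["gamma"])
    if d.empty or d["action"].nunique() < 2:
        raise ValueError("need both cooperators and defectors among opt-ins")
    y = (d["action"] == "C").to_numpy(dtype=int)
    gamma = d["gamma"].to_numpy(dtype=float)
    pivotal = np.array([pivotal_probability(g, spec) for g in gamma])
    regime = str(d["regime"].iloc[0])
    return (
        ROCResult(
            predictor="raw_belief",
            auc=float(roc_auc_score(y, gamma)),
            n=int(len(d)),
            threshold=spec.threshold,
            regime=regime,
        ),
        ROCResult(
            predictor="pivotal_probability",
            auc=float(roc_auc_score(y, pivotal)),
            n=int(len(d)),
            threshold=spec.threshold,
            regime=regime,
        ),
    )


def belief_action_change(records: pd.DataFrame) -> pd.DataFrame:
    """Pair each participant's mandatory/voluntary rows at equal threshold.

    Returns one row per participant x threshold with the two actions, the
    loner flag (left in the voluntary condition), the belief change
    ``delta_gamma = gamma_voluntary - gamma_mandatory`` (NaN for loners,
    who are excluded from belief-change analyses), and the action-change
    class: ``positive`` (D to C), ``negative`` (C to D), ``none``
    otherwise.  Participants missing either regime row are flagged.
    """
    _validate_schema(records)
    d = add_gamma_column(records)
    rows = []
    for (pid, q), block in d.groupby(["participant_id", "threshold"]):
        mand = block[block["regime"] == Regime.MANDATORY.value]
        vol = block[block["regime"] == Regime.VOLUNTARY.value]
        if len(mand) != 1 or len(vol) != 1:
            rows.append(
                {
                    "participant_id": pid,
                    "threshold": int(q),
                    "action_mandatory": None,
                    "action_voluntary": None,
                    "is_loner": None,
                    "delta_gamma": float("nan"),
                    "change": "missing_pair",
                }
            )
            continue
        a_m = str(mand["action"].iloc[0])
        a_v = str(vol["action"].iloc[0])
        is_loner = a_v == Action.LEAVE.value
        if is_loner:
            delta = float("nan")
        else:
            delta = float(vol["gamma"].iloc[0] - mand["gamma"].iloc[0])
        if a_m == "D" and a_v == "C":
            change = "positive"
        elif a_m == "C" and a_v == "D":
            change = "negative"
        else:
            change = "none"
        rows.append(
            {
                "participant_id": pid,
                "threshold": int(q),
                "action_mandatory": a_m,
                "action_voluntary": a_v,
                "is_loner": is_loner,
                "delta_gamma": delta,
                "change": change,
            }
        )
    return pd.DataFrame(rows)
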