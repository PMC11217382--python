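"""Statistical pipeline: belief conversion, summaries, bootstrap, GLMM, ROC."""

import warnings

import numpy as np
import pandas as pd
import pytest

from volpgg import (
    CohortConfig,
    GameSpec,
    Regime,
    belief_action_change,
    bootstrap_ci,
    elicited_belief_to_gamma,
    fit_random_intercept_logit,
    generate_cohort,
    roc_compare,
    summarize_conditions,
)
from volpgg.cohort import RECORD_COLUMNS


def make_records(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "participant_id": "p1",
        "session_id": "s1",
        "regime": "voluntary",
        "threshold": 5,
        "rho": np.nan,
        "est_C": 10,
        "est_D": 10,
        "est_L": 10,
        "confidence": 50,
        "action": "C",
        "condition_order": 1,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=RECORD_COLUMNS)


class TestBeliefConversion:
    @pytest.mark.parametrize(
        "counts, regime, rho, expected",
        [
            ((15, 15, 0), "mandatory", None, 0.5),
            ((10, 10, 10), "voluntary", 1.0, 1 / 3),
            ((10, 10, 10), "voluntary", None, 0.5),
            ((12, 6, 12), "voluntary", 0.0, 12 / 18),  # rho=0 equals main design
        ],
    )
    def test_values(self, counts, regime, rho, expected):
        c, d, l = counts
        assert elicited_belief_to_gamma(c, d, l, regime, rho) == pytest.approx(expected)

    def test_undefined_when_no_opt_ins_believed(self):
        assert np.isnan(elicited_belief_to_gamma(0, 0, 30, "voluntary"))


class TestSummaries:
    def test_unanimous_cooperation(self):
        rec = make_records(
            [{"participant_id": f"p{i}", "action": "C"} for i in range(10)]
        )
        (s,) = summarize_conditions(rec)
        assert s.p_coop == 1.0 and s.p_success == 1.0

    def test_even_split_full_threshold(self):
        rec = make_records(
            [{"participant_id": f"p{i}", "action": "C" if i < 5 else "D"} for i in range(10)]
        )
        (s,) = summarize_conditions(rec)
        assert s.p_coop == 0.5
        assert s.p_success == pytest.approx(0.03125)

    def test_matches_generator_prediction(self):
        # empirical summaries of a large noiseless cohort sit within
        # sampling error of the analytic shares-driven prediction
        from volpgg import BeliefDistribution, action_shares, cooperation_rate

        n = 4000
        rec = generate_cohort(
            CohortConfig(
                n_participants=n,
                seed=2,
                decision_noise=0.0,
                thresholds=(4,),
                belief_model={4: (3, 3)},
                optimism_shift={4: 0},
            )
        )
        summaries = {(s.regime, s.threshold): s for s in summarize_conditions(rec)}
        spec = GameSpec(threshold=4, regime=Regime.VOLUNTARY)
        p = cooperation_rate(action_shares(BeliefDistribution(3, 3), spec))
        got = summaries[("voluntary", 4)].p_coop
        se = np.sqrt(p * (1 - p) / n)
        assert abs(got - p) < 4 * se


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        rec = make_records([{"participant_id": f"p{i}"} for i in range(20)])
        ci = bootstrap_ci(rec, lambda df: 3.25, n_iterations=50, seed=0)
        assert (ci.point, ci.ci_low, ci.ci_high) == (3.25, 3.25, 3.25)

    def test_invariant_to_row_order_and_relabeling(self):
        rec = make_records(
            [
                {"participant_id": f"p{i}", "est_C": 5 + i % 20}
                for i in range(40)
            ]
        )
        stat = lambda df: df["est_C"].mean()  # noqa: E731
        ci1 = bootstrap_ci(rec, stat, n_iterations=200, seed=3)
        shuffled = rec.sample(frac=1, random_state=9).reset_index(drop=True)
        shuffled["participant_id"] = shuffled["participant_id"].map(
            lambda s: f"relabel_{s}"
        )
        ci2 = bootstrap_ci(shuffled, stat, n_iterations=200, seed=3)
        assert ci1.ci_low == pytest.approx(ci2.ci_low)
        assert ci1.ci_high == pytest.approx(ci2.ci_high)

    def test_undefined_resamples_counted_not_dropped_silently(self):
        rec = make_records([{"participant_id": f"p{i}"} for i in range(5)])

        def sometimes_nan(df):
            return float("nan") if "p0" in set(df["participant_id"]) else 1.0

        # relabelling means the statistic sees fresh ids, so force NaN always
        ci = bootstrap_ci(rec, lambda df: float("nan"), n_iterations=20, seed=0)
        assert ci.n_undefined == 20
        assert np.isnan(ci.ci_low)

    def test_joint_statistics_share_the_resampling_stream(self):
        rec = make_records(
            [{"participant_id": f"p{i}", "est_C": i % 25} for i in range(30)]
        )
        stats = {
            "mean": lambda df: df["est_C"].mean(),
            "mean_plus_one": lambda df: df["est_C"].mean() + 1.0,
        }
        out = bootstrap_ci(rec, stats, n_iterations=100, seed=5)
        # identical resamples: the two intervals differ by exactly the offset
        assert out["mean_plus_one"].ci_low == pytest.approx(out["mean"].ci_low + 1.0)
        assert out["mean_plus_one"].ci_high == pytest.approx(out["mean"].ci_high + 1.0)

    def test_rejects_zero_iterations(self):
        rec = make_records([{"participant_id": "p1"}])
        with pytest.raises(ValueError):
            bootstrap_ci(rec, lambda df: 1.0, n_iterations=0)

    def test_coverage_near_nominal(self):
        # 95% percentile CI for a mean of 200 standard-normal "participants"
        # covers the true mean approximately 95% of the time
        reps = 400
        n = 200
        rng = np.random.default_rng(12)
        covered = 0
        for _ in range(reps):
            values = rng.standard_normal(n)
            df = pd.DataFrame(
                {"participant_id": [f"p{i}" for i in range(n)], "x": values}
            )
            ci = bootstrap_ci(
                df,
                lambda d: d["x"].mean(),
                n_iterations=1000,
                seed=int(rng.integers(2**31)),
            )
            covered += ci.ci_low <= 0.0 <= ci.ci_high
        assert abs(covered / reps - 0.95) < 0.03


class TestRandomInterceptLogit:
    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 - 2.0 * x)))).astype(int)
        df = pd.DataFrame(
            {"participant_id": [f"p{i}" for i in range(n)], "y": y, "x": x}
        )
        res = fit_random_intercept_logit(df, "y", ["x"])
        assert res.converged
        row = res.params.loc["x"]
        assert row["ci_low"] <= -2.0 <= row["ci_high"]
        assert row["p"] < 0.001

    def test_recovers_random_intercept_sd(self):
        rng = np.random.default_rng(1)
        G, m = 600, 5
        u = rng.normal(scale=1.0, size=G)
        x = rng.normal(size=(G, m))
        eta = 0.3 + 1.5 * x + u[:, None]
        y = (rng.random((G, m)) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([f"g{i}" for i in range(G)], m),
                "y": y.ravel(),
                "x": x.ravel(),
            }
        )
        res = fit_random_intercept_logit(df, "y", ["x"])
        assert res.converged
        assert res.params.loc["x", "ci_low"] <= 1.5 <= res.params.loc["x", "ci_high"]
        assert 0.6 < res.random_intercept_sd < 1.4

    def test_null_covariate_rarely_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 30
        for _ in range(reps):
            n = 400
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.5).astype(int)
            df = pd.DataFrame(
                {"participant_id": [f"p{i}" for i in range(n)], "y": y, "x": x}
            )
            res = fit_random_intercept_logit(df, "y", ["x"])
            hits += abs(res.params.loc["x", "z"]) >= 1.96
        # nominal 5% false-positive rate; allow binomial slack at 30 reps
        assert hits <= 5

    def test_pessimism_predicts_defection_on_synthetic_cohort(self):
        # the pipeline's first regression contract: mandatory-condition
        # defection against elicited belief and threshold — more pessimistic
        # participants defect more, so the belief coefficient is negative
        from volpgg.analysis import add_gamma_column

        rec = generate_cohort(CohortConfig(n_participants=800, seed=6))
        mand = add_gamma_column(rec[rec["regime"] == "mandatory"]).dropna(
            subset=["gamma"]
        )
        mand = mand.assign(defect=(mand["action"] == "D").astype(int))
        res = fit_random_intercept_logit(mand, "defect", ["gamma", "threshold"])
        assert res.converged
        assert res.params.loc["gamma", "coef"] < 0
        assert res.params.loc["gamma", "ci_high"] < 0

    def test_separation_is_flagged(self):
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(20)],
                "y": [0] * 10 + [1] * 10,
                "x": list(range(10)) + list(range(10, 20)),
            }
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = fit_random_intercept_logit(df, "y", ["x"])
        assert not res.converged
        assert any(issubclass(w.category, RuntimeWarning) for w in caught)


class TestROC:
    def _records(self, gammas: np.ndarray, actions: list[str], q: int) -> pd.DataFrame:
        # mandatory rows so gamma = est_C/30 reproduces the predictor exactly
        return make_records(
            [
                {
                    "participant_id": f"p{i}",
                    "regime": "mandatory",
                    "threshold": q,
                    "est_C": int(round(g * 30)),
                    "est_D": 30 - int(round(g * 30)),
                    "est_L": 0,
                    "action": a,
                }
                for i, (g, a) in enumerate(zip(gammas, actions))
            ]
        )

    def test_full_threshold_predictors_coincide_exactly(self):
        # pivotal probability is gamma^4 at q=5: a monotone transform, and
        # AUC is a rank statistic
        rng = np.random.default_rng(4)
        g = rng.random(200)
        actions = ["C" if rng.random() < gg else "D" for gg in g]
        rec = self._records(g, actions, q=5)
        raw, piv = roc_compare(rec, GameSpec(threshold=5, regime=Regime.MANDATORY))
        assert raw.auc == piv.auc

    def test_low_threshold_predictors_can_differ(self):
        # at q=2 the pivotal probability is non-monotone in gamma, so the
        # rankings genuinely diverge
        rng = np.random.default_rng(8)
        g = rng.random(300)
        actions = ["C" if rng.random() < gg else "D" for gg in g]
        rec = self._records(g, actions, q=2)
        raw, piv = roc_compare(rec, GameSpec(threshold=2, regime=Regime.MANDATORY))
        assert raw.auc != piv.auc

    def test_independent_predictor_is_chance_level(self):
        rng = np.random.default_rng(6)
        g = rng.random(4000)
        actions = ["C" if rng.random() < 0.5 else "D" for _ in g]
        rec = self._records(g, actions, q=4)
        raw, _ = roc_compare(rec, GameSpec(threshold=4, regime=Regime.MANDATORY))
        assert raw.auc == pytest.approx(0.5, abs=0.03)

    def test_noiseless_threshold_rule_is_perfect(self):
        # beliefs on the elicitation grid k/30 so rounding cannot blur ranks
        g = np.array([k / 30 for k in range(31)])
        actions = ["C" if gg > 0.5 else "D" for gg in g]
        rec = self._records(g, actions, q=5)
        raw, _ = roc_compare(rec, GameSpec(threshold=5, regime=Regime.MANDATORY))
        assert raw.auc == 1.0

    def test_single_class_rejected(self):
        rec = self._records(np.array([0.2, 0.6]), ["C", "C"], q=4)
        with pytest.raises(ValueError):
            roc_compare(rec, GameSpec(threshold=4, regime=Regime.MANDATORY))


class TestBeliefActionChange:
    def test_positive_change_with_belief_gain(self):
        rec = make_records(
            [
                {"regime": "mandatory", "threshold": 4, "est_C": 9, "est_D": 21,
                 "est_L": 0, "action": "D"},
                {"regime": "voluntary", "threshold": 4, "est_C": 24, "est_D": 6,
                 "est_L": 0, "action": "C", "condition_order": 2},
            ]
        )
        (row,) = belief_action_change(rec).to_dict("records")
        assert row["change"] == "positive"
        assert row["delta_gamma"] == pytest.approx(0.8 - 0.3)
        assert not row["is_loner"]

    def test_no_change_zero_delta(self):
        rec = make_records(
            [
                {"regime": "mandatory", "threshold": 4, "est_C": 15, "est_D": 15,
                 "est_L": 0, "action": "C"},
                {"regime": "voluntary", "threshold": 4, "est_C": 15, "est_D": 15,
                 "est_L": 0, "action": "C", "condition_order": 2},
            ]
        )
        (row,) = belief_action_change(rec).to_dict("records")
        assert row["change"] == "none" and row["delta_gamma"] == 0.0

    def test_loners_flagged_and_excluded_from_belief_change(self):
        rec = make_records(
            [
                {"regime": "mandatory", "threshold": 4, "action": "D", "est_L": 0},
                {"regime": "voluntary", "threshold": 4, "action": "L",
                 "condition_order": 2},
            ]
        )
        (row,) = belief_action_change(rec).to_dict("records")
        assert row["is_loner"] and np.isnan(row["delta_gamma"])

    def test_missing_pair_flagged(self):
        rec = make_records([{"regime": "mandatory", "threshold": 4, "est_L": 0}])
        (row,) = belief_action_change(rec).to_dict("records")
        assert row["change"] == "missing_pair"
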