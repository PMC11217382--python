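# Methods

## Decision model

One round of a threshold public goods game in groups of `group_size` = 5.
Payoff constants (all configurable on `GameSpec`): endowment 10 points,
group reward 30, outside payoff 10, threshold q ∈ {1, …, 5}.  Payoffs are
accounted as **total points after the round**, endowment fate included: a
loner's expected and realized payoff is 10 + 10 = 20; a successful
cooperator nets 30 (endowment invested, reward received); a successful
defector 40.  The free-rider premium in a successful group therefore
equals the endowment.

A player's belief γ is the probability that any one co-player cooperates,
treated as i.i.d. across the four co-players, so the relevant uncertainty
is binomial.  `tail_prob_others` is the upper tail Γ_k; `expected_payoffs`
implements the three action values; `pivotal_probability` is the chance
that exactly q−1 others cooperate (own cooperation decisive).

**Tie-break.** At exact expected-payoff indifference the best response is
chosen by the fixed order C ≻ L ≻ D.  Boundaries are measure-zero under
any continuous belief distribution, so the rule has no effect on
population quantities; fixing it prosocially just makes region endpoints
reproducible.  The numerical indifference tolerance is 1e−12.

## Population layer

Beliefs in the population follow Beta(α, β).  Action shares are computed
**analytically**: the best-response partition of [0, 1] is located once
per game (vectorized grid of 8193 points, each switch refined by Brent
root-finding on the payoff difference of the two adjacent actions to
1e−12; results cached per `GameSpec`), and each region's Beta cumulative
mass is summed.  Monte-Carlo integration of the defining integral exists
only as an independent oracle in the test-suite.  A region narrower than
the grid spacing (≈1.2e−4) would be missed; the default game's payoff
curves are piecewise monotone with at most three regions, so this cannot
occur there.

`cooperation_rate` is r_C/(r_C + r_D); an empty opt-in pool raises
`UndefinedRateError` rather than returning a silent NaN, and callers that
aggregate (sweeps, bootstrap, summaries) convert it to a flagged NaN.
`group_success_rate` is the binomial upper tail at p_coop.

**Efficiency.** Mean payoff per person normalized by the per-capita payoff
of a group with exactly q cooperators ((40 − 2q) points under defaults).
Group participants' expected payoffs are evaluated at belief = p_coop —
the independent-composition approximation under which the success formula
itself operates: each opt-in's four co-members cooperate i.i.d. with
probability p_coop.  The exact finite-population alternative (realize
random group assignments and average actual payoffs) is available through
the session engine and agrees with the analytic value to ~1% at 10^5
agents; analytic is the default because it is deterministic and fast.

**Loner externality.** p_coop(ρ) = r_C/(r_C + r_D + ρ·r_L).  ρ = 0
reproduces the plain within-group rate; ρ = 1 counts loners like
defectors.  Monotone non-increasing in ρ whenever r_L > 0.

**Beta sweep.** The default grid is parameterized by mean
μ ∈ {0.05, …, 0.95 step 0.05} and concentration ν ∈ {1, 2, 5, 10, 20}
(α = μν, β = (1−μ)ν) — 95 cells spanning pessimistic to optimistic and
diffuse to concentrated beliefs.  Cells where everyone leaves under
voluntary play are flagged `defined = False`, never dropped.

A caution the sweep itself documents: voluntary participation does **not**
dominate pointwise.  At q = 5 the voluntary rate is identically 1 wherever
anyone opts in, so the comparison always favors (weakly) the voluntary
regime.  At q ∈ {2, 4}, however, belief distributions concentrated high
(e.g. Beta(4, 1) at q = 4, or most optimistic cells at q = 2) yield
*lower* voluntary within-group cooperation: the leave region strictly
contains the fear-defection region and additionally removes low-belief
cooperators, while greed defectors all stay.  This is an exact property of
the best-response model, cross-checked by Monte-Carlo in the tests, and
anyone asserting a uniform inequality over the full grid will find these
counterexamples.

**Symmetric equilibria.** The consistency map sends a common belief γ to
the within-group cooperation rate produced when everyone best-responds
(1 on cooperate regions, 0 on defect regions, undefined on leave regions
— no group forms).  Pure fixed points are detected at the endpoints;
mixed fixed points sit at interior cooperate/defect boundaries, where
indifferent players can mix with the boundary probability.  Stability
annotates whether naive belief adjustment is attracted (map above the
diagonal below the point and below it above).  Under voluntary play with
default payoffs the all-defect point is eliminated: at γ = 0 leaving
strictly dominates defection (20 > 10), so no participating population
can sustain it.

## Synthetic cohort generator

Emulates a within-subject session experiment so the full pipeline runs
without external data.  Defaults describe the study conditions: 191
participants in 6 sessions of 30–35, a 2 (regime) × 3 (q = 2, 4, 5)
design with half the cohort playing all voluntary conditions first and
thresholds shuffled within block; the externality design uses 182
participants, q = 4, ρ ∈ {0, 0.5, 1} in randomized order.

Generative structure, per participant i and condition:

- **Latent beliefs.** γ drawn from the condition's Beta via a Gaussian
  copula: a participant-level factor (correlation 0.6 by default) makes
  individual differences stable across conditions, which the paired
  mandatory/voluntary analyses require.
- **Optimism shift.** Moving mandatory → voluntary, a fraction
  `shift_fraction` (default 0.5) of participants shift their belief by δ_q
  on the logit scale (defaults 1.0 / 1.2 / 2.0 for q = 2 / 4 / 5),
  emulating the belief-updating pathway; the same participants shift at
  every threshold (an "updater" type).
- **Elicited counts.** Estimates of 30 others are multinomial around the
  participant's implied expectation — others leave at the cohort-level
  projected leave share and the rest cooperate with probability γ — so
  elicited data carry realistic integer rounding noise.  Mandatory
  conditions have est_L ≡ 0.
- **Choice rule.** Softmax over expected payoffs with temperature λ
  (points; default 2.0).  λ = 0 is the exact best response, which the
  consistency tests use.  Softmax preserves the payoff ordering, unlike
  ε-uniform noise.
- **Externality design.** The latent belief is about the *effective*
  cooperation rate (what that design elicits); counts are constructed to
  be consistent with it given the projected leave share, and actions are
  chosen against payoffs evaluated at the effective rate recomputed from
  the participant's own counts — the elicitation, not the latent value,
  drives the decision.  An all-leaver estimate (denominator 0) reads as
  maximal pessimism (rate 0).  Default Beta means fall from 0.7 to 0.5 as
  ρ rises.

Default belief means (0.6–0.7, concentration 6) were chosen once as
plausible moderate optimism producing mixed cooperation, fear- and
greed-defection, and 30–50% opting out under voluntary play.  They are
synthetic stand-ins, not estimates from any dataset.  Two known
departures from observed human behaviour follow from exact best-response
logic: voluntary q = 2 cooperation can fall *below* mandatory once the
optimism shift pushes beliefs into the greed region, and leaving saturates
near 100% at ρ ≥ 0.5.  Passing tests on these cohorts therefore validates
the pipeline's statistical machinery, not the behavioural realism of
best-response play.

Beta parameters are recoverable from the elicited counts by
beta-binomial method of moments (`fit_beta_binomial_mom`), which
deconvolves the multinomial rounding noise; recovery is within 10%
relative error at 5000 participants.

## Session engine

Group formation shuffles the pool (opt-ins plus each leaver independently
included with probability ρ) under a seed and fills groups of five; the
remainder — uniformly random via the shuffle — goes to the individual
option, as do leavers not included.  Bumped opt-ins receive the
individual-option payoff (20), a design choice where the rules only say
remainders are assigned to that option.  Seated leavers occupy a chair,
contribute nothing, and earn 20.

Bonuses: estimation branch v = 800 − (80/6)·Σ_x |e_x/30 − realized share
of x|, applied verbatim on proportions; points branch v = 20·π.  The
printed estimation formula has a floor of 800 − (80/6)·2 ≈ 773.3 for a
single condition (maximal L1 distance on proportions is 2); the 0 floor of
the stated 0–800 range is attainable only via the points branch.  The
formula is implemented exactly as printed.

## Statistical pipeline

- **Belief conversion.** Mandatory: est_C/30.  Voluntary main design:
  est_C/(est_C + est_D), the believed cooperation rate among opt-ins —
  the quantity that determines group outcomes; the "right" voluntary
  conversion is not uniquely dictated by the elicitation, and this is the
  natural choice.  Externality design: est_C/(est_C + est_D + ρ·est_L).
  Empty denominators yield flagged NaNs, not exceptions.
- **Bootstrap.** Participants are the resampling unit; all of a
  participant's rows move together and each draw is relabelled as a new
  participant (repeated draws count as distinct clusters).  One resampling
  stream drives all requested statistics jointly.  B = 1000 and 2.5/97.5
  percentiles by default; resamples where a statistic is undefined are
  excluded from the percentiles and counted in the result.  Significance
  convention: a 95% CI not containing 0.  Coverage is ≈95% ± 3% on
  Gaussian check data (400 replications in the tests).
- **Random-intercept logistic regression.** Marginal maximum likelihood
  with the participant intercept integrated out by 21-point Gauss-Hermite
  quadrature; BFGS optimization from a plain-logit start, standard errors
  from the numerical Hessian.  A near-zero score is accepted as
  convergence when the line search stops on precision loss.  Complete
  separation or runaway coefficients (|β| > 15) set `converged = False`
  and raise a RuntimeWarning; point estimates are backend-dependent and
  the supported surface is sign and CI coverage, verified by parameter
  recovery at n = 5000.
- **ROC comparison.** Rank-based AUC (midrank ties) of raw beliefs versus
  pivotal probabilities for predicting cooperation among opt-ins.  At
  q = 5 the pivotal probability is γ⁴ — strictly increasing — so the two
  AUCs coincide exactly; the comparison is informative only at q ∈ {2, 4},
  where pivotality is non-monotone in γ.
- **Change table.** Pairs each participant's mandatory/voluntary rows at
  equal q; action change classes positive (D→C), negative (C→D), none;
  loners flagged and excluded from belief-change deltas; missing pairs
  flagged rather than dropped.

## Problem sizes

Analytic quantities are exact and instant.  Simulation-backed checks use
10^5 agents (session ↔ model agreement, ~0.003 standard error on group
success), 2×10^5 draws for Monte-Carlo share oracles, cohorts of
2000–10000 for generator consistency, and 250–400 bootstrap-coverage
replications at B = 500–1000 — sizes at which three-standard-error bands
are decisive for every asserted property.

## Known limitations

- Best-response (even softened by softmax) understates human cooperation
  at low thresholds; the generator inherits this by design.
- The efficiency model's independent-composition approximation ignores
  finite-pool composition correlations (negligible beyond ~10^3 players).
- The equilibrium search characterizes symmetric equilibria only;
  asymmetric profiles are out of scope.
- Belief formation is not modelled; the optimism shift is a free knob, not
  a theory.
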