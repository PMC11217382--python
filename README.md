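# volpgg — voluntary threshold public goods games

`volpgg` models and analyzes collaboration as a **threshold public goods
game with an outside individual option**.  Five players each hold a
10-point endowment; members of a group choose to **cooperate** (invest the
endowment) or **defect** (keep it), and the group succeeds — paying every
member a 30-point reward — only if at least `q` members cooperate
(`q ∈ {2, 4, 5}`).  Under *voluntary* participation a third action,
**leave**, secures a certain 10-point outside payoff (20 points total)
before groups even form; under *mandatory* participation everyone is
grouped.

The package is aimed at behavioral game theorists and experimentalists who
want to (a) compute the model's predictions, (b) simulate whole
experimental sessions, and (c) run the standard statistical pipeline on
participant-level choice/belief tables — including synthetic ones, so every
stage is testable without access to any particular experiment's data.

## The model

A player holds a subjective belief γ ∈ [0, 1] that any given co-player
cooperates.  With Γ_k the binomial probability that at least k of the four
others cooperate, expected total payoffs are

    E[π | C] = 30 · Γ_{q−1}
    E[π | D] = 10 + 30 · Γ_q
    E[π | L] = 10 + 10            (voluntary only)

The best response partitions [0, 1] into intervals (fear-driven defection
at low γ, cooperation in the middle, greed-driven free-riding at high γ;
leaving replaces the low end under voluntary play).  Integrating this
partition against a population belief distribution φ(γ) — modelled as
Beta(α, β) — gives action shares r_C, r_D, r_L, the within-group
cooperation rate

    p_coop = r_C / (r_C + r_D),

the group success rate `p_success = Σ_{k=q}^{5} C(5,k) p_coop^k (1−p_coop)^{5−k}`,
and normalized efficiencies.  A **loner externality** parameter
ρ ∈ [0, 1] interpolates between flexible group formation (ρ = 0, loners
excluded at formation) and fixed group boundaries (ρ = 1, loners dilute
groups exactly like defectors):

    p_coop(ρ) = r_C / (r_C + r_D + ρ·r_L).

At q = 5, defection is never a best response under voluntary play (one's
own defection guarantees failure, and the sure outside option dominates),
so p_coop = 1 for *any* belief distribution with r_C > 0.

## Worked example

Population prediction for uniform-ish beliefs Beta(2, 2) at q = 5 under
voluntary participation:

```bash
$ volpgg model --threshold 5 --regime voluntary --alpha 2 --beta 2
best-response regions:
  [0.000000, 0.903602] -> L
  [0.903602, 1.000000] -> C
threshold,regime,alpha,beta,rho,r_C,r_D,r_L,p_coop,p_success,efficiency_within,efficiency_population
5,voluntary,2.0,2.0,0.0,0.02608615015058402,0.0,0.973913849849416,1.0,1.0,1.0,0.6753620500501947
```

Reading the output: beliefs below (2/3)^(1/4) ≈ 0.9036 make leaving
optimal and beliefs above it make cooperating optimal; there is **no
defection interval**.  Only r_C ≈ 2.6% of this pessimistic population
opts in, but everyone who does cooperates (p_coop = 1), every formed group
succeeds (p_success = 1), and within-group efficiency is maximal; the
population-wide efficiency 0.675 is dragged down by the many loners
earning 20 points against the 30-point per-capita optimum.

Symmetric belief-consistent equilibria of the mandatory q = 2 game — the
all-defect point, an unstable mixed point at the fear boundary, and a
stable mixed point at the greed boundary:

```bash
$ volpgg equilibria --threshold 2 --regime mandatory
gamma*=0.00000000  pure   stable
gamma*=0.12394283  mixed  unstable
gamma*=0.41389304  mixed  stable
```

Other subcommands: `volpgg sweep` (Beta-grid regime comparison),
`volpgg simulate` (synthetic cohort + realized session payoffs),
`volpgg analyze` (condition summaries and participant-resampled bootstrap
CIs from a tidy CSV; a YAML column-mapping adapts external schemas).
Everything is also available as a library:

```python
from volpgg import BeliefDistribution, GameSpec, action_shares, cooperation_rate
shares = action_shares(BeliefDistribution(2, 2), GameSpec(threshold=5, regime="voluntary"))
cooperation_rate(shares)   # -> 1.0
```

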