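# warmglow

Behavioral-economics analysis of incentivized survey games: who contributes
to a threshold public good, what beliefs and risk preferences rationalize
that choice, and how vaccination attitudes relate to both.

The package targets respondent-level data from a three-game incentivized
survey design:

* **Game 1 — risk elicitation.** Each respondent invests `q ∈ [0, 200]`
  tokens (1 token = €0.01) in a project returning `2.5 q` with probability
  ½ and nothing otherwise, keeping `200 − q` either way.
* **Game 2 — threshold public good.** Groups of `N` players each decide
  whether to contribute; the good is produced iff at least `T < N`
  contribute. Three treatment arms: T1 "small and risky" (`N=5, T=3`),
  T2 "large and risky" (`N=50, T=25`), and T3 "large and safe" (same as
  T2 but contributors are partially compensated on failure).
* **Game 3 — belief elicitation.** Each respondent guesses how many of the
  `N − 1` *others* contributed, paid by banded accuracy.

## The model

From Game 1, a CRRA coefficient ρ is calibrated from the first-order
condition of expected-utility maximization,
`ρ = ln 1.5 / ln((200 + 1.5q)/(200 − q))`, with censoring flags at the
corners. From Game 3, the guess `t` point-identifies an i.i.d. belief
`p = t/(N−1)` that any other member contributes, so the number of other
contributors is `X ~ Binomial(N−1, p)` and a selfish rational player
should contribute only when pivotal (`X = T − 1`).

The core statistic is the **warm-glow threshold C**: the minimal monetary
value (euros) a respondent must attach to the act of contributing for
contribution to maximize expected utility,

```
E[u(payoff_contribute + C)] = E[u(payoff_defect)],   u(x) = x^(1−ρ)/(1−ρ),
```

with exact binomial outcome probabilities on both sides. `C ≤ 0` means a
purely selfish rational player contributes. Comparing the observed Game 2
action with the selfish optimum partitions respondents into **type (i)**
(selfish-consistent), **type (ii)** (contributed although `C > 0`:
positive other-regarding preferences) and **type (iii)** (defected
although `C ≤ 0`: negative other-regarding preferences).

An inference layer fits the two survey regressions — OLS of the belief
fraction `G3` on the invested fraction `G1`, a no-vaxxer dummy, treatment
dummies and controls (age, 20-region categorical), and an LPM/probit of
the contribution `G2` on `G1`, `G3` and the same covariates, with probit
results reported as average marginal effects — plus chi-square and
Barnard exact unconditional tests for group comparisons. A synthetic
cohort generator plants all of this structure (including the
belief-mediated no-vaxxer contribution gap) with known ground truth.

## Worked example

The reference computation (also `warmglow worked-example` on the command
line): a respondent in T2 invests 100 of 200 tokens and guesses that 20
of the 49 others contributed.

```
$ warmglow worked-example
Game 1 investment q = 100 tokens  ->  CRRA rho = 0.3237
Game 3 guess t = 20 of 49 others  ->  belief p = 0.4082
P(pivotal) = P(X = 24) = 0.0583
P(success | contribute) = 0.1545, P(success | defect) = 0.0962
Warm-glow threshold C = EUR 0.86 (minimum monetary pleasure of contributing that rationalizes contribution)
```

Read: with ρ ≈ 0.32 and `p ≈ 0.41`, the chance the threshold is met is
only 15% even with her contribution, so defecting (€4 / €1) beats
contributing (€3 / €0) for a selfish player — she contributes only if the
act itself is worth at least €0.86 to her. If she did contribute, she is
classified type (ii).

The same chain in Python:

```python
from warmglow import (crra_from_investment, belief_from_guess,
                      outcome_probabilities, warm_glow_threshold)

rho = crra_from_investment(100).rho
beliefs = outcome_probabilities(belief_from_guess(20, "T2"), "T2")
print(warm_glow_threshold(rho, beliefs, "T2"))   # 0.8611...
```

Cohort-level workflow:

```
warmglow simulate --n 1482 --seed 42 --out cohort.csv
warmglow classify cohort.csv --out-prefix results
warmglow fit cohort.csv
warmglow recover --n-replicates 50 --seed 1
```

`classify` writes a per-respondent table (ρ, p, pivot probability, C,
type) and a type-share summary split by no-vaxxer status; `fit` prints
both regressions and the Game 1 group comparison; `recover` is a
Monte-Carlo check that the pipeline recovers the generator's planted
parameters (bias, empirical SE, CI coverage).

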