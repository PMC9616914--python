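# Methods

## Games and payoff conventions

Payoffs are stored in tokens and converted to euros at a fixed
1 token = €0.01 everywhere utilities are evaluated. Game 2 payoffs per
(action, outcome) cell are: contribute/success 300, defect/success 400,
defect/failure 100 in every arm; contribute/failure 0 in T1 and T2 and
200 in T3 (the "safe" arm partially compensates failed contributors).
Game 3 scoring bands are interpreted as inclusive nested intervals
(exact 300; error ≤ 1 → 150 and ≤ 2 → 100 in T1; error ≤ 2 → 150 and
≤ 10 → 100 in the large groups; 50 beyond) — the only monotone reading of
the band edges. The Game 3 guess counts *others only* (range
`0 … N−1`): the worked example's fraction 20/49 forces this reading.

## Risk preferences

Utility is CRRA over the game's own monetary payoff with zero background
wealth (narrow bracketing): `u(x) = x^(1−ρ)/(1−ρ)`, `u = ln x` at
`ρ = 1`, with `u(0) = −∞` for `ρ ≥ 1`. For interior investments the
first-order condition of `max_q ½u(200+1.5q) + ½u(200−q)` inverts in
closed form to `ρ = ln 1.5 / ln((200+1.5q)/(200−q))`, strictly
decreasing in `q`. Corners are censored, never silent: `q = 200` is
consistent with any `ρ ≤ 0` and is floored at 0
(`censoring="at_risk_neutral_floor"`); `q = 0` maps to a cap
`RHO_CAP = 20` (`"at_upper_cap"`). Any cap above roughly 5 is
behaviorally indistinguishable in this payoff range. Note that `q = 0`
is never an *interior* optimum at finite ρ — the marginal token gains
1.5 against a loss of 1 at identical wealth — so the brute-force optimum
at the cap itself is 2 tokens, and the inverse-consistency guarantee
(re-optimization recovers `q` within ±1 token) is stated for
`q ∈ {5, …, 195}`.

## Beliefs

The guess `t` point-identifies `p = t/(N−1)`; the number of other
contributors is `X ~ Binomial(N−1, p)` and all outcome probabilities
(`P(X = T−1)` pivotal, `P(X ≥ T−1)`, `P(X ≥ T)`) are exact binomial
tails (scipy), never normal approximations. Since an integer guess only
brackets the underlying belief, a half-unit sensitivity interval
`[t−½, t+½]/(N−1)` (clipped to [0, 1]) is exposed alongside the point
estimate; the classification uses the point estimate, which reproduces
the €0.86 reference value.

## Warm-glow threshold

Warm glow is modeled as money added to the contributor's payoff in both
outcome states, with utility evaluated over (money + C); the threshold
solves `E[u(contribute, C)] = E[u(defect)]`. The contribute side is
strictly increasing in C, so the root is unique; it is found with
Brent's method on the bracket `(1e−12, 10]` euros, `xtol = 1e−12`,
≤ 200 iterations (the payoff gap is bounded well inside €10). Under
risk neutrality the threshold has the closed form
`1 − 3·P(X = T−1)` (T1/T2) and `3·P(X ≥ T) − P(X ≥ T−1) − 1` (T3),
which the root-finder matches to 1e−9 and which serves as an oracle in
the tests.

When contribution is already weakly optimal at zero glow the threshold
is negative. Evaluating CRRA utility at `payoff_fail + C < 0` is
undefined in the risky arms (failure pays €0), so the negative branch is
computed as a compensating variation on the other action: find `m > 0`
with `E[u(contribute, 0)] = E[u(defect + m)]` and report `C = −m`. Under
risk neutrality this reproduces the closed form exactly, so the
convention is the natural extension of the positive branch. Ties
(`C = 0`) count contribution as the selfish-optimal action — a fixed,
measure-zero tie-break. With `ρ ≥ 1` in T1/T2 a failed contribution has
utility −∞ at zero glow, so `C > 0` always; the strictly positive
bracket start handles this without special-casing.

Per-(ρ, p, treatment) thresholds are memoized: cohort game choices live
on a small integer grid, so repeated classification across Monte-Carlo
replicates is cheap.

### Classification

type (i): observed action equals the selfish optimum; type (ii):
contributed with `C > 0`; type (iii): defected with `C ≤ 0`. Exactly one
label per respondent. The cohort summary follows the convention in which
type (i) is the selfish-consistent group (≈30% in cohorts like these)
and type (ii) the altruistic majority (≈65%); an alternative narrative
convention that swaps the two labels exists in the survey literature and
is deliberately not used here. C monotonicity: the threshold is a function of both binomial
tails, so it is strictly decreasing in the pivot probability along each
monotone branch of pivot(p); the global statement holds only under risk
neutrality, where `C = 1 − 3·pivot` exactly.

## Regressions

The belief regression is OLS of `G3 = t/(N−1)` on `G1 = q/200`, the
no-vaxxer dummy, treatment dummies and controls; the contribution model
regresses the binary `G2` on the same plus `G3`, as a linear probability
model or a probit. Design encoding: intercept; T2 as treatment reference
(the survey reports only T1 and T3 rows); age linear; 20-region
categorical with the alphabetically first observed region as reference
(T2 and the first region being the omitted baselines) — on a full cohort
this gives 24 regressors beside the intercept without
`G3` (residual df `n − 25`) and 25 with it — residual df 1457 and 1456
at `n = 1482`. Standard errors are classical
(homoskedastic) OLS errors. Probit results are reported as average
marginal effects: mean over observations of the density-weighted slope
for continuous regressors and of the discrete 0→1 change in predicted
probability for dummies; these are computed in-package and cross-checked
against statsmodels' `get_margeff` in the tests. Rank-deficient designs
abort with the collinear columns named. The LPM tracks the probit AMEs
closely for moderate effects and overshoots for the strong belief effect
(the usual behavior of a linear approximation to a probit away from the
mean), so no tighter LPM/probit agreement is asserted.

Group comparisons use the chi-square test of independence (no continuity
correction) and, for 2×2 tables, Barnard's exact unconditional test
(scipy), pooled score statistic, maximizing over a 200-point nuisance
grid; the two groups are the columns, whose totals are the fixed
binomial sample sizes. Game 1 distributional comparisons are supported
by binning investments into configurable equal-width bands (deciles by
default, empty bins dropped) and by an above/below-100-tokens 2×2 split.

## Synthetic cohorts

The generator emulates the survey table: uniform assignment over the
three arms, no-vaxxer share 12.1%, age truncated-normal 43 ± 11.8 on
[18, 73], uniform region over 20 categories, invested fraction
`clip(N(0.53, 0.26), 0, 1)` rounded to tokens, and latent trust drawn
per respondent from a Beta distribution moment-matched to mean
0.62 + shifts (no-vaxxer −0.046, T3 +0.065, T1 +0.016) and sd 0.27, then
rounded to an integer guess. Moment-matching is refused (domain error)
when the requested sd is infeasible for the mean.

Contribution behavior has two modes. In the default probit mode the
slopes are specified on the *average-marginal-effect* scale — the scale
on which the analysis reports them (G1 0.126, G3 0.690, T3 0.126,
T1 0.018, and a structurally zero direct no-vaxxer effect, so the
no-vaxxer contribution gap is mediated entirely through beliefs) — and
the latent probit index is derived by a fixed-point calibration
(`index slope = target AME / E[φ(index)]`, intercept set so the mean
contribution rate is 0.72). This makes the planted quantities exactly
the ones the estimators report. In the warm-glow mode each respondent
draws an explicit glow `N(0.5, 1.0)` euros and contributes exactly when
the glow covers her threshold (decided by direct expected-utility
comparisons, not by the root-finder), yielding exact ground-truth type
labels; the classifier must reproduce them verbatim.

Known departures from real survey data: treatment shares are exactly
uniform rather than 497/512/473; trust is conditionally Beta rather
than the mixed discrete-continuous empirical shape; G1 carries no direct
effect on beliefs (the generator's belief equation includes only the
no-vaxxer and treatment shifts, so the belief regression's G1
coefficient is centered at zero rather than at the published 0.129);
rounding the coarse T1 guesses (out of 4) induces a small attenuation
(≈0.0006 on the no-vaxxer contrast, negligible against Monte-Carlo
error). Passing recovery tests therefore demonstrates correctness of
the estimators under the planted mechanism, not distributional realism.

## Monte-Carlo scales and seeds

All randomness flows from `numpy.random.default_rng` seeded by a single
integer; replicate `r` of an experiment uses `seed + r`. Recovery checks
use 200 replicates at n = 1482 for the planted-effect recoveries (three
Monte-Carlo standard errors of the replicate mean as the criterion) and
500 replicates for the null rejection rate of the nominal-5% no-vaxxer
test (two binomial MC standard errors), sizes at which the checks are
sharp while the full suite stays in the tens of seconds. Classification
recovery uses cohorts of 800 in warm-glow mode and requires exact label
agreement.

## Limitations

* The CRRA inversion assumes the investment reflects a deterministic
  interior optimum; response noise or rounding by respondents is not
  modeled, and corner investments are only bounded, not identified.
* The belief point-identification ignores the elicitation's banded
  scoring incentives (which reward interval, not point, accuracy).
* C is a per-respondent bound, not a structural estimate of a population
  warm-glow distribution.
* The regression layer implements classical standard errors only.
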