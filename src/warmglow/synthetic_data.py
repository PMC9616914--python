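"""Synthetic survey cohorts with planted ground truth.

The generator emulates the respondent-level table the analysis expects:
uniform random assignment to the three treatments, a no-vaxxer indicator,
truncated-normal ages, uniform region of residence, a latent *trust*
variable (the believed probability that another group member contributes)
drawn from a moment-matched Beta distribution, the Game 1 investment, and
the binary Game 2 contribution.

The default parameters encode the study conditions the analysis targets:
a cohort of 1482 with a 12.1% no-vaxxer share, mean invested fraction
0.53 (sd 0.26), mean trust 0.62 (sd 0.27), a -0.046 shift of mean trust
for no-vaxxers, a +0.065 trust shift in the safe treatment T3 (+0.016 in
T1), and contribution behavior whose probit average marginal effects are
G1 0.126, G3 0.690, T3 0.126, T1 0.018 and — crucially — a zero *direct*
no-vaxxer effect: the no-vaxxer gap in contribution is mediated entirely
through beliefs.

Because marginal effects, not latent index coefficients, are the
quantities the analysis reports, contribution slopes are specified on the
marginal-effect scale and the underlying probit index is derived by a
fixed-point calibration on the realized cohort (see
:func:`_calibrate_probit_index`).

An alternative behavioral mode draws an explicit per-respondent warm glow
and lets each agent contribute exactly when her glow covers her
warm-glow threshold, yielding exact ground-truth type labels for
classification tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ITALIAN_REGIONS
from .games import ENDOWMENT, get_treatment
from .preferences import crra_from_investment, crra_utility
from .beliefs import belief_from_guess, outcome_probabilities
from .classify import _euro_payoffs, classify_cohort
from .inference import fit_eq1, fit_eq2

__all__ = ["CohortParams", "generate_cohort", "recovery_experiment", "RecoveryReport"]

_TREATMENT_IDS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults encode the study conditions."""

    n: int = 1482
    novax_share: float = 0.121
    g1_mean: float = 0.53
    g1_sd: float = 0.26
    trust_mean: float = 0.62
    trust_sd: float = 0.27
    novax_trust_shift: float = -0.046
    t3_trust_shift: float = 0.065
    t1_trust_shift: float = 0.016
    #: target probit average marginal effects on contribution
    contribution_ames: dict[str, float] = field(
        default_factory=lambda: {
            "G1": 0.126, "G3": 0.690, "T3": 0.126, "T1": 0.018, "novax": 0.0,
        }
    )
    #: target overall contribution rate
    g2_rate: float = 0.72
    age_mean: float = 43.0
    age_sd: float = 11.8
    age_range: tuple[float, float] = (18.0, 73.0)
    n_regions: int = 20
    #: share of non-no-vaxxers who are nonetheless unvaccinated
    other_unvaccinated_share: float = 0.033
    #: behavioral mode: "probit" (latent-index contribution) or
    #: "warm_glow" (explicit glow vs. threshold, with true type labels)
    behavior: str = "probit"
    glow_mean: float = 0.5
    glow_sd: float = 1.0
    seed: int = 0

    def null(self) -> "CohortParams":
        """Variant with every planted effect removed (for size checks)."""
        return replace(
            self,
            novax_trust_shift=0.0,
            t3_trust_shift=0.0,
            t1_trust_shift=0.0,
            contribution_ames={k: 0.0 for k in self.contribution_ames},
        )


def _beta_moment_match(mu: np.ndarray, sd: float) -> tuple[np.ndarray, np.ndarray]:
    var = sd * sd
    feasible = var < mu * (1.0 - mu)
    if not np.all(feasible):
        bad = mu[~feasible]
        raise ValueError(
            f"infeasible Beta moment matching: sd={sd} too large for means "
            f"such as {bad[:3]}"
        )
    nu = mu * (1.0 - mu) / var - 1.0
    return mu * nu, (1.0 - mu) * nu


def _calibrate_probit_index(
    x: np.ndarray, targets: np.ndarray, rate: float
) -> tuple[float, np.ndarray, float]:
    """Find probit index (intercept, slopes) whose AMEs hit the targets.

    Solves the fixed point gamma = targets / E[phi(gamma0 + x gamma)] with
    gamma0 chosen so the mean predicted probability equals ``rate``.
    """
    from scipy.optimize import brentq

    a = 1.0 / stats.norm.pdf(stats.norm.ppf(rate))  # risk-neutral start
    gamma0 = stats.norm.ppf(rate)
    for _ in range(100):
        gamma = a * targets
        z = x @ gamma
        gamma0 = brentq(
            lambda g0: stats.norm.cdf(g0 + z).mean() - rate, -12.0, 12.0, xtol=1e-13
        )
        mean_density = stats.norm.pdf(gamma0 + z).mean()
        a_new = 1.0 / mean_density
        if abs(a_new - a) < 1e-12:
            a = a_new
            break
        a = a_new
    return gamma0, a * targets, a


def _selfish_gain(rho: float, p: float, spec_id: str, glow: float) -> float:
    """EU(contribute with glow) - EU(defect), extended to negative glow.

    For ``glow < 0`` the comparison shifts the money to the defect side
    (contribute at zero glow vs. defection compensated by ``-glow``), which
    is the same ordering without evaluating utility at negative wealth.
    """
    spec = get_treatment(spec_id)
    bel = outcome_probabilities(p, spec)
    cs, cf, ds, df = _euro_payoffs(spec)
    pc, pd_ = bel.prob_success_if_contribute, bel.prob_success_if_defect
    g = max(glow, 0.0)
    m = max(-glow, 0.0)
    eu_c = pc * crra_utility(cs + g, rho) + (1.0 - pc) * crra_utility(cf + g, rho)
    eu_d = pd_ * crra_utility(ds + m, rho) + (1.0 - pd_) * crra_utility(df + m, rho)
    if eu_c == eu_d:  # +/- inf corner: defect
        return -1.0
    return eu_c - eu_d


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Draw one synthetic cohort and its ground-truth record.

    Returns the respondent table (survey schema) and a dict recording
    every planted parameter, each respondent's latent trust, the derived
    probit index, and — in warm-glow mode — the drawn glow and true type
    labels.
    """
    if params.n < 30:
        raise ValueError("cohort size must be at least 30")
    if params.behavior not in ("probit", "warm_glow"):
        raise ValueError("behavior must be 'probit' or 'warm_glow'")
    rng = np.random.default_rng(params.seed)
    n = params.n

    treatment = rng.choice(_TREATMENT_IDS, size=n)
    novax = rng.random(n) < params.novax_share
    lo, hi = params.age_range
    a, b = (lo - params.age_mean) / params.age_sd, (hi - params.age_mean) / params.age_sd
    age = np.round(
        stats.truncnorm.rvs(
            a, b, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
        )
    ).astype(int)
    region = rng.choice(ITALIAN_REGIONS[: params.n_regions], size=n)

    mu = (
        params.trust_mean
        + params.novax_trust_shift * novax
        + params.t3_trust_shift * (treatment == "T3")
        + params.t1_trust_shift * (treatment == "T1")
    )
    alpha, beta = _beta_moment_match(mu, params.trust_sd)
    trust = np.clip(rng.beta(alpha, beta), 0.0, 1.0)
    n_others = np.array([get_treatment(t).n_others for t in treatment])
    g3_guess = np.rint(trust * n_others).astype(int)

    g1_frac = np.clip(rng.normal(params.g1_mean, params.g1_sd, size=n), 0.0, 1.0)
    g1_invest = np.rint(g1_frac * ENDOWMENT).astype(int)

    truth: dict[str, Any] = {
        "params": params,
        "trust": trust,
        "treatment": treatment.copy(),
        "no_vaxxer": novax.copy(),
    }

    G1 = g1_invest / ENDOWMENT
    G3 = g3_guess / n_others
    if params.behavior == "probit":
        x = np.column_stack(
            [G1, G3, (treatment == "T3").astype(float),
             (treatment == "T1").astype(float), novax.astype(float)]
        )
        targets = np.array(
            [params.contribution_ames[k] for k in ("G1", "G3", "T3", "T1", "novax")]
        )
        gamma0, gamma, scale = _calibrate_probit_index(x, targets, params.g2_rate)
        index = gamma0 + x @ gamma
        g2 = rng.random(n) < stats.norm.cdf(index)
        mean_density = stats.norm.pdf(index).mean()
        truth.update(
            probit_intercept=gamma0,
            probit_index_coefs=dict(
                zip(("G1", "G3", "T3", "T1", "novax"), gamma)
            ),
            planted_ames=dict(params.contribution_ames),
            mean_index_density=mean_density,
            mean_contribution_prob=float(stats.norm.cdf(index).mean()),
        )
    else:
        glow = rng.normal(params.glow_mean, params.glow_sd, size=n)
        g2 = np.empty(n, dtype=bool)
        selfish = np.empty(n, dtype=bool)
        for i in range(n):
            rho = crra_from_investment(int(g1_invest[i])).rho
            p = belief_from_guess(int(g3_guess[i]), treatment[i])
            g2[i] = _selfish_gain(rho, p, treatment[i], glow[i]) >= 0.0
            selfish[i] = _selfish_gain(rho, p, treatment[i], 0.0) >= 0.0
        labels = np.where(
            g2 == selfish, "type_i", np.where(g2, "type_ii", "type_iii")
        )
        truth.update(
            warm_glow=glow,
            selfish_action=selfish,
            type_label=labels,
        )

    vaccinated = np.where(
        novax, False, rng.random(n) >= params.other_unvaccinated_share
    )
    had_covid = np.where(novax, False, rng.random(n) < 0.10)
    wants_vaccine = np.where(novax, False, ~vaccinated)

    df = pd.DataFrame(
        {
            "respondent_id": [f"r{i:05d}" for i in range(n)],
            "treatment": treatment,
            "g1_invest": g1_invest,
            "g2_contribute": g2,
            "g3_guess": g3_guess,
            "vaccinated": vaccinated.astype(bool),
            "had_covid": had_covid.astype(bool),
            "wants_vaccine": wants_vaccine.astype(bool),
            "age": age,
            "region": region,
        }
    )
    df["no_vaxxer"] = ~(
        df["vaccinated"] | df["had_covid"] | df["wants_vaccine"]
    )
    df = df[
        ["respondent_id", "treatment", "g1_invest", "g2_contribute", "g3_guess",
         "vaccinated", "had_covid", "wants_vaccine", "no_vaxxer", "age", "region"]
    ]
    assert (df["no_vaxxer"].to_numpy() == novax).all()
    return df, truth


@dataclass
class RecoveryReport:
    """Replicate-level estimates plus a bias/SE/coverage summary."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    params: CohortParams
    n_replicates: int


def recovery_experiment(
    params: CohortParams,
    n_replicates: int,
    seed: int,
    include_eq2: bool = True,
    include_classification: bool = True,
) -> RecoveryReport:
    """Monte-Carlo check that the pipeline recovers the planted structure.

    Replicate ``r`` regenerates a cohort with ``seed + r``, runs the
    belief regression, optionally the probit contribution regression and
    the warm-glow classification, and records estimates, standard errors
    and 95% CI coverage of the planted trust shifts.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    rows = []
    z = stats.norm.ppf(0.975)
    planted_eq1 = {
        "No-vaxxer": params.novax_trust_shift,
        "Treatment=T3": params.t3_trust_shift,
        "Treatment=T1": params.t1_trust_shift,
        "G1": 0.0,
    }
    for r in range(n_replicates):
        cohort, truth = generate_cohort(replace(params, seed=seed + r))
        row: dict[str, Any] = {"replicate": r, "seed": seed + r}
        eq1 = fit_eq1(cohort, validate=False)
        for name, true_val in planted_eq1.items():
            est = eq1.coefficients[name]
            se = eq1.std_errors[name]
            row[f"eq1_{name}"] = est
            row[f"eq1_{name}_se"] = se
            row[f"eq1_{name}_covered"] = abs(est - true_val) <= z * se
        tstat = eq1.coefficients["No-vaxxer"] / eq1.std_errors["No-vaxxer"]
        row["eq1_novax_pvalue"] = 2.0 * stats.t.sf(abs(tstat), eq1.residual_df)
        if include_eq2:
            eq2 = fit_eq2(cohort, family="probit", validate=False)
            for name in ("G1", "G3", "No-vaxxer", "Treatment=T3", "Treatment=T1"):
                row[f"eq2_ame_{name}"] = eq2.marginal_effects[name]
        if include_classification:
            tidy, summary = classify_cohort(cohort, validate=False)
            for label in ("type_i", "type_ii", "type_iii"):
                row[f"share_{label}"] = (tidy["type_label"] == label).mean()
                if "type_label" in truth:
                    row[f"true_share_{label}"] = float(
                        np.mean(truth["type_label"] == label)
                    )
        rows.append(row)
    reps = pd.DataFrame(rows)

    summary_rows = {}
    for name, true_val in planted_eq1.items():
        est = reps[f"eq1_{name}"]
        summary_rows[f"eq1_{name}"] = {
            "planted": true_val,
            "mean_estimate": est.mean(),
            "bias": est.mean() - true_val,
            "empirical_se": est.std(ddof=1),
            "mc_se_of_mean": est.std(ddof=1) / np.sqrt(len(est)),
            "coverage_95": reps[f"eq1_{name}_covered"].mean(),
        }
    summary_rows["eq1_novax_rejection_rate_5pct"] = {
        "planted": np.nan,
        "mean_estimate": (reps["eq1_novax_pvalue"] < 0.05).mean(),
        "bias": np.nan,
        "empirical_se": np.nan,
        "mc_se_of_mean": np.sqrt(
            (reps["eq1_novax_pvalue"] < 0.05).mean()
            * (1 - (reps["eq1_novax_pvalue"] < 0.05).mean())
            / len(reps)
        ),
        "coverage_95": np.nan,
    }
    if include_eq2:
        ames = {
            "G1": params.contribution_ames["G1"],
            "G3": params.contribution_ames["G3"],
            "No-vaxxer": params.contribution_ames["novax"],
            "Treatment=T3": params.contribution_ames["T3"],
            "Treatment=T1": params.contribution_ames["T1"],
        }
        for name, true_val in ames.items():
            est = reps[f"eq2_ame_{name}"]
            summary_rows[f"eq2_ame_{name}"] = {
                "planted": true_val,
                "mean_estimate": est.mean(),
                "bias": est.mean() - true_val,
                "empirical_se": est.std(ddof=1),
                "mc_se_of_mean": est.std(ddof=1) / np.sqrt(len(est)),
                "coverage_95": np.nan,
            }
    if include_classification:
        for label in ("type_i", "type_ii", "type_iii"):
            est = reps[f"share_{label}"]
            planted = (
                reps[f"true_share_{label}"].mean()
                if f"true_share_{label}" in reps
                else np.nan
            )
            summary_rows[f"share_{label}"] = {
                "planted": planted,
                "mean_estimate": est.mean(),
                "bias": est.mean() - planted if np.isfinite(planted) else np.nan,
                "empirical_se": est.std(ddof=1),
                "mc_se_of_mean": est.std(ddof=1) / np.sqrt(len(est)),
                "coverage_95": np.nan,
            }
    return RecoveryReport(
        replicates=reps,
        summary=pd.DataFrame.from_dict(summary_rows, orient="index"),
        params=params,
        n_replicates=n_replicates,
    )
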