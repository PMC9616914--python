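"""Warm-glow threshold C and the rationality / other-regarding classification.

A fully rational, purely selfish player contributes in the threshold
public-good game only when pivotal, so for most beliefs defection is the
selfish optimum. The warm-glow threshold ``C`` of a respondent is the
minimal *monetary* value she must attach to the act of contributing for
contribution to maximize her expected CRRA utility, given her risk
preference (from Game 1) and her belief about others (from Game 3):

    E[u(payoff_contribute + C)] = E[u(payoff_defect)],

with payoffs in euros and the warm glow entering as money added to the
contributor's payoff in both the success and the failure state. ``C <= 0``
means a selfish rational player would contribute.

Respondents are partitioned into three types by comparing the observed
Game 2 action with the selfish optimum:

* type (i)   — action matches the selfish optimum (*homo economicus*);
* type (ii)  — contributed although C > 0 (positive other-regarding
  preferences worth at least C euros);
* type (iii) — defected although C <= 0 (negative other-regarding
  preferences: forgoes own expected payoff, lowering others' odds).

When ``C`` is negative its magnitude is the compensating money that must
accompany *defection* to restore indifference, which keeps the CRRA
argument non-negative in the treatments where a failed contribution pays
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin

from .beliefs import BeliefModel, belief_from_guess, outcome_probabilities
from .cohort import REQUIRED_COLUMNS, Respondent, validate_cohort
from .games import TOKEN_EUR, TreatmentSpec, get_treatment
from .preferences import crra_from_investment, crra_utility

__all__ = [
    "ClassificationResult",
    "RationalityClassifier",
    "expected_utility",
    "warm_glow_threshold",
    "risk_neutral_threshold",
    "classify_respondent",
    "classify_cohort",
    "summarize_types",
    "TYPE_LABELS",
]

TYPE_LABELS = ("type_i", "type_ii", "type_iii")

# bisection bracket (euros) and root tolerance for the indifference equation
_BRACKET_LO = 1e-12
_BRACKET_HI = 10.0
_XTOL = 1e-12
_MAXITER = 200


@dataclass(frozen=True)
class ClassificationResult:
    """Per-respondent warm-glow threshold and type assignment."""

    C: float
    selfish_action: bool  # True = contribute is the selfish optimum
    type_label: str
    rho: float
    censoring: str
    p: float
    prob_pivot: float


def _euro_payoffs(spec: TreatmentSpec) -> tuple[float, float, float, float]:
    """(contribute_success, contribute_fail, defect_success, defect_fail) in euros."""
    return (
        spec.pay_contribute_success * TOKEN_EUR,
        spec.pay_contribute_fail * TOKEN_EUR,
        spec.pay_defect_success * TOKEN_EUR,
        spec.pay_defect_fail * TOKEN_EUR,
    )


def expected_utility(
    contribute: bool,
    warm_glow: float,
    rho: float,
    beliefs: BeliefModel,
    spec: "str | TreatmentSpec",
) -> float:
    """Expected CRRA utility of one Game 2 action under binomial beliefs.

    The warm glow ``warm_glow`` (euros, non-negative) is added to the
    contributor's monetary payoff in both outcome states; it does not
    attach to defection.
    """
    spec = get_treatment(spec)
    cs, cf, ds, df = _euro_payoffs(spec)
    if contribute:
        if warm_glow < 0:
            raise ValueError("warm glow must be non-negative")
        ps = beliefs.prob_success_if_contribute
        return ps * crra_utility(cs + warm_glow, rho) + (1.0 - ps) * crra_utility(
            cf + warm_glow, rho
        )
    ps = beliefs.prob_success_if_defect
    return ps * crra_utility(ds, rho) + (1.0 - ps) * crra_utility(df, rho)


@lru_cache(maxsize=200_000)
def _threshold_cached(rho: float, p: float, spec_id: str) -> tuple[float, float, bool]:
    spec = get_treatment(spec_id)
    bel = outcome_probabilities(p, spec)
    cs, cf, ds, df = _euro_payoffs(spec)
    pc, pd_ = bel.prob_success_if_contribute, bel.prob_success_if_defect
    eu_defect = pd_ * crra_utility(ds, rho) + (1.0 - pd_) * crra_utility(df, rho)

    def gain_contribute(c: float) -> float:
        return (
            pc * crra_utility(cs + c, rho)
            + (1.0 - pc) * crra_utility(cf + c, rho)
            - eu_defect
        )

    g0 = gain_contribute(_BRACKET_LO)
    if g0 < 0.0:
        # contribution needs a strictly positive warm glow
        if gain_contribute(_BRACKET_HI) < 0.0:  # pragma: no cover - payoff gap < 10 EUR
            raise RuntimeError(
                f"no warm-glow root in ({_BRACKET_LO}, {_BRACKET_HI}) euros "
                f"for rho={rho}, p={p}, treatment={spec_id}"
            )
        c = brentq(
            gain_contribute, _BRACKET_LO, _BRACKET_HI, xtol=_XTOL, maxiter=_MAXITER
        )
        return float(c), bel.prob_pivot, False
    # selfish contribution is already (weakly) rational: C <= 0. Its magnitude
    # is the compensating money m that must accompany defection instead:
    # E[u(contribute + 0)] = E[u(defect + m)].
    eu_contribute0 = pc * crra_utility(cs, rho) + (1.0 - pc) * crra_utility(cf, rho)

    def gain_over_compensated_defection(m: float) -> float:
        return eu_contribute0 - (
            pd_ * crra_utility(ds + m, rho) + (1.0 - pd_) * crra_utility(df + m, rho)
        )

    if gain_over_compensated_defection(_BRACKET_LO) <= 0.0:
        return 0.0, bel.prob_pivot, True  # exact indifference at zero glow
    m = brentq(
        gain_over_compensated_defection,
        _BRACKET_LO,
        _BRACKET_HI,
        xtol=_XTOL,
        maxiter=_MAXITER,
    )
    return float(-m), bel.prob_pivot, True


def warm_glow_threshold(
    rho: float, beliefs: "BeliefModel | float", spec: "str | TreatmentSpec"
) -> float:
    """Solve the indifference equation for the warm-glow threshold C (euros).

    Root-finding brackets C in (0, 10] euros; the contribute-side expected
    utility is strictly increasing in the glow, so the root is unique.
    If contributing is already weakly optimal at zero glow, the negative
    branch is solved on the defection side (see module docstring).
    """
    spec = get_treatment(spec)
    p = beliefs.p if isinstance(beliefs, BeliefModel) else float(beliefs)
    C, _, _ = _threshold_cached(float(rho), p, spec.id)
    return C


def risk_neutral_threshold(p: float, spec: "str | TreatmentSpec") -> float:
    """Closed-form C for a risk-neutral player (linear utility), in euros.

    With token payoffs (cs, cf, ds, df) and success probabilities Pc, Pd
    the threshold is ``df + Pd (ds - df) - cf - Pc (cs - cf)``; in the
    risky treatments this reduces to ``1 - 3 P(X = T - 1)``.
    """
    spec = get_treatment(spec)
    bel = outcome_probabilities(p, spec)
    cs, cf, ds, df = _euro_payoffs(spec)
    return (
        df
        + bel.prob_success_if_defect * (ds - df)
        - cf
        - bel.prob_success_if_contribute * (cs - cf)
    )


def classify_respondent(r: "Respondent | pd.Series | dict") -> ClassificationResult:
    """Classify one respondent from her Game 1, 2 and 3 choices.

    Chains the CRRA inversion, the belief point-identification and the
    warm-glow threshold, then compares the observed Game 2 action with
    the selfish optimum. A tie (C = 0) counts contribution as selfish.
    """
    get = r.__getattribute__ if isinstance(r, Respondent) else r.__getitem__
    spec = get_treatment(get("treatment"))
    pref = crra_from_investment(get("g1_invest"))
    p = belief_from_guess(get("g3_guess"), spec)
    C, pivot, _ = _threshold_cached(pref.rho, p, spec.id)
    selfish_action = C <= 0.0
    contributed = bool(get("g2_contribute"))
    if contributed == selfish_action:
        label = "type_i"
    elif contributed:
        label = "type_ii"
    else:
        label = "type_iii"
    return ClassificationResult(
        C=C,
        selfish_action=selfish_action,
        type_label=label,
        rho=pref.rho,
        censoring=pref.censoring,
        p=p,
        prob_pivot=pivot,
    )


class RationalityClassifier(BaseEstimator, TransformerMixin):
    """Stateless transformer adding warm-glow classification columns.

    ``transform`` maps a cohort table (one row per respondent, with the
    survey schema columns) to the same table augmented with ``rho``,
    ``censoring``, ``p``, ``prob_pivot``, ``C``, ``selfish_action`` and
    ``type_label``. ``fit`` only validates the input schema; the
    classification has no free parameters to learn.

    Parameters
    ----------
    validate : bool, default True
        Run full cohort-schema validation before classifying.
    """

    def __init__(self, validate: bool = True):
        self.validate = validate

    def fit(self, X: pd.DataFrame, y=None) -> "RationalityClassifier":
        X = self._check(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _check(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("RationalityClassifier expects a cohort DataFrame")
        if X.empty:
            raise ValueError("cohort is empty")
        if self.validate:
            return validate_cohort(X)
        missing = [
            c
            for c in ("treatment", "g1_invest", "g2_contribute", "g3_guess")
            if c not in X.columns
        ]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        return X

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._check(X)
        rows = [classify_respondent(row) for _, row in X.iterrows()]
        out = X.copy()
        for field in ("rho", "censoring", "p", "prob_pivot", "C",
                      "selfish_action", "type_label"):
            out[field] = [getattr(c, field) for c in rows]
        return out

    def get_feature_names_out(self, input_features=None):
        extra = ["rho", "censoring", "p", "prob_pivot", "C",
                 "selfish_action", "type_label"]
        base = list(input_features) if input_features is not None else list(
            getattr(self, "feature_names_in_", [])
        )
        return np.asarray(base + extra, dtype=object)


def summarize_types(classified: pd.DataFrame) -> pd.DataFrame:
    """Type shares split by no-vaxxer status, in the survey's table layout.

    Rows are the three types plus a total row; columns give the percentage
    composition within vaxxers and no-vaxxers and the overall count and
    share.
    """
    n = len(classified)
    if "no_vaxxer" not in classified.columns:
        classified = classified.assign(no_vaxxer=False)
    rows = {}
    for label in TYPE_LABELS:
        sub = classified[classified["type_label"] == label]
        row = {}
        for novax, col in ((False, "vaxxer_pct"), (True, "no_vaxxer_pct")):
            group = classified[classified["no_vaxxer"].astype(bool) == novax]
            row[col] = 100.0 * (group["type_label"] == label).mean() if len(group) else np.nan
        row["count"] = len(sub)
        row["total_pct"] = 100.0 * len(sub) / n
        rows[label] = row
    rows["total"] = {
        "vaxxer_pct": 100.0 * (~classified["no_vaxxer"].astype(bool)).mean(),
        "no_vaxxer_pct": 100.0 * classified["no_vaxxer"].astype(bool).mean(),
        "count": n,
        "total_pct": 100.0,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_cohort(data: pd.DataFrame, validate: bool = True):
    """Classify every respondent in a cohort table.

    Returns ``(per_respondent, summary)``: a tidy per-respondent frame
    with columns respondent_id, rho, p, prob_pivot, C, selfish_action,
    type_label, and the type-share summary from :func:`summarize_types`.
    """
    if not isinstance(data, pd.DataFrame) or data.empty:
        raise ValueError("classify_cohort requires a non-empty cohort DataFrame")
    clf = RationalityClassifier(validate=validate)
    full = clf.fit(data).transform(data)
    keep = [c for c in ("respondent_id", "no_vaxxer") if c in full.columns]
    tidy = full[
        keep + ["rho", "censoring", "p", "prob_pivot", "C",
                "selfish_action", "type_label"]
    ].copy()
    return tidy, summarize_types(full)
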