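"""Regression and contingency analyses for the survey cohort.

Two regressions are fit on respondent-level data:

* the *belief* regression — OLS of the Game 3 guess fraction ``G3`` on the
  Game 1 invested fraction ``G1``, the no-vaxxer dummy, treatment dummies
  and controls (age, region); and
* the *contribution* regression — the binary Game 2 choice ``G2`` on
  ``G1``, ``G3``, the no-vaxxer dummy, treatment dummies and controls,
  either as a linear probability model (OLS) or as a probit whose results
  are reported as average marginal effects (AMEs).

The treatment reference category is T2 and the region reference is the
alphabetically first region present, so a full cohort with all 20 regions
yields 24 regressors beside the intercept without ``G3`` and 25 with it.

Group comparisons of discrete outcomes use the chi-square test of
independence and, for 2x2 tables, Barnard's exact unconditional test
(maximizing over the nuisance success probability), preferred over
Fisher's conditional test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import ITALIAN_REGIONS, validate_cohort
from .games import ENDOWMENT, get_treatment

__all__ = [
    "FitResult",
    "ContingencyResult",
    "BeliefRegression",
    "ContributionRegression",
    "build_design",
    "fit_eq1",
    "fit_eq2",
    "contingency_tests",
    "game1_decile_table",
    "game1_split_table",
]

_DUMMY_PREFIXES = ("No-vaxxer", "Treatment=", "region=")


@dataclass
class FitResult:
    """Coefficients and fit diagnostics of one cohort regression."""

    model_id: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    n_obs: int
    residual_df: int
    r_squared: float | None = None
    pseudo_r_squared: float | None = None
    marginal_effects: dict[str, float] | None = None
    results: object = field(default=None, repr=False)  # statsmodels results

    def to_frame(self) -> pd.DataFrame:
        """Tabular report (one row per regressor) for printing/CSV."""
        out = pd.DataFrame(
            {"coefficient": self.coefficients, "std_error": self.std_errors}
        )
        if self.marginal_effects is not None:
            out["avg_marginal_effect"] = pd.Series(self.marginal_effects)
        return out


@dataclass(frozen=True)
class ContingencyResult:
    """One contingency-table test: statistic and p-value."""

    statistic: float
    p_value: float
    test_name: str


def _fractions(data: pd.DataFrame) -> pd.DataFrame:
    d = data.copy()
    d["G1"] = d["g1_invest"] / ENDOWMENT
    n_others = d["treatment"].map(lambda t: get_treatment(t).n_others)
    d["G3"] = d["g3_guess"] / n_others
    d["G2"] = d["g2_contribute"].astype(int)
    return d


def build_design(data: pd.DataFrame, include_g3: bool) -> pd.DataFrame:
    """Construct the regression design matrix from a cohort table.

    Columns: intercept, ``G1`` (fraction of the 200-token endowment
    invested), optionally ``G3`` (guessed fraction of others
    contributing), the ``No-vaxxer`` dummy, treatment dummies for T3 and
    T1 (T2 is the reference), ``age``, and region dummies with the
    alphabetically first observed region as reference.
    """
    missing = [
        c
        for c in ("g1_invest", "g3_guess", "treatment", "no_vaxxer", "age", "region")
        if c not in data.columns
    ]
    if missing:
        raise ValueError(f"design requires missing columns: {missing}")
    unknown = set(data["region"]) - set(ITALIAN_REGIONS)
    if unknown:
        raise ValueError(f"unknown region levels: {sorted(unknown)}")
    d = _fractions(data)
    X = pd.DataFrame(index=d.index)
    X["Intercept"] = 1.0
    X["G1"] = d["G1"]
    if include_g3:
        X["G3"] = d["G3"]
    X["No-vaxxer"] = d["no_vaxxer"].astype(int)
    X["Treatment=T3"] = (d["treatment"] == "T3").astype(int)
    X["Treatment=T1"] = (d["treatment"] == "T1").astype(int)
    X["age"] = d["age"].astype(float)
    regions = sorted(set(d["region"]))
    for r in regions[1:]:  # first observed region is the reference level
        X[f"region={r}"] = (d["region"] == r).astype(int)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # identify offending columns by greedy elimination
        keep: list[str] = []
        culprits: list[str] = []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy(dtype=float)
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(col)
            else:
                culprits.append(col)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {culprits}"
        )


def _probit_ames(results, X: pd.DataFrame) -> dict[str, float]:
    """Average marginal effects: mean per-observation effect per regressor.

    Continuous regressors use the density-weighted slope; dummy regressors
    use the discrete change in predicted probability between 0 and 1.
    """
    beta = results.params
    xb = X.to_numpy(dtype=float) @ beta.to_numpy()
    mean_density = stats.norm.pdf(xb).mean()
    ames: dict[str, float] = {}
    for col in X.columns:
        if col == "Intercept":
            continue
        if col.startswith(_DUMMY_PREFIXES):
            x1 = X.copy()
            x0 = X.copy()
            x1[col] = 1
            x0[col] = 0
            p1 = stats.norm.cdf(x1.to_numpy(dtype=float) @ beta.to_numpy())
            p0 = stats.norm.cdf(x0.to_numpy(dtype=float) @ beta.to_numpy())
            ames[col] = float((p1 - p0).mean())
        else:
            ames[col] = float(mean_density * beta[col])
    return ames


class BeliefRegression(BaseEstimator):
    """OLS of the Game 3 belief fraction on risk taking, no-vaxxer status,
    treatment and controls.

    Fitted attributes: ``coef_`` and ``bse_`` (pandas Series indexed by
    regressor), ``n_obs_``, ``resid_df_``, ``rsquared_`` and the full
    statsmodels ``results_``.
    """

    def __init__(self, validate: bool = True):
        self.validate = validate

    def fit(self, X: pd.DataFrame, y=None) -> "BeliefRegression":
        data = validate_cohort(X) if self.validate else X
        design = build_design(data, include_g3=False)
        _check_rank(design)
        target = _fractions(data)["G3"]
        res = sm.OLS(target.to_numpy(dtype=float), design).fit()
        self.results_ = res
        self.coef_ = res.params
        self.bse_ = res.bse
        self.n_obs_ = int(res.nobs)
        self.resid_df_ = int(res.df_resid)
        rsq = float(res.rsquared)
        # a constant outcome has zero total variation; report R^2 = 0
        self.rsquared_ = rsq if np.isfinite(rsq) else 0.0
        return self

    def to_fit_result(self) -> FitResult:
        return FitResult(
            model_id="eq1_ols",
            coefficients=self.coef_.to_dict(),
            std_errors=self.bse_.to_dict(),
            n_obs=self.n_obs_,
            residual_df=self.resid_df_,
            r_squared=self.rsquared_,
            results=self.results_,
        )


class ContributionRegression(BaseEstimator):
    """Model of the binary Game 2 contribution on G1, G3, no-vaxxer status,
    treatment and controls.

    Parameters
    ----------
    family : {"ols", "probit"}
        Linear probability model, or probit reported as average marginal
        effects (``marginal_effects_``).
    validate : bool
        Run cohort-schema validation before fitting.
    """

    def __init__(self, family: str = "probit", validate: bool = True):
        self.family = family
        self.validate = validate

    def fit(self, X: pd.DataFrame, y=None) -> "ContributionRegression":
        if self.family not in ("ols", "probit"):
            raise ValueError("family must be 'ols' or 'probit'")
        data = validate_cohort(X) if self.validate else X
        design = build_design(data, include_g3=True)
        _check_rank(design)
        target = _fractions(data)["G2"].to_numpy(dtype=float)
        if target.min() == target.max():
            raise ValueError("Game 2 outcome is constant; contribution model is degenerate")
        self.marginal_effects_ = None
        if self.family == "ols":
            res = sm.OLS(target, design).fit()
            self.rsquared_ = float(res.rsquared)
            self.pseudo_rsquared_ = None
        else:
            res = sm.Probit(target, design).fit(disp=0, maxiter=200)
            self.rsquared_ = None
            self.pseudo_rsquared_ = float(res.prsquared)
            self.marginal_effects_ = _probit_ames(res, design)
        self.results_ = res
        self.coef_ = res.params
        self.bse_ = res.bse
        self.n_obs_ = int(res.nobs)
        self.resid_df_ = int(res.df_resid)
        return self

    def to_fit_result(self) -> FitResult:
        return FitResult(
            model_id=f"eq2_{self.family}",
            coefficients=self.coef_.to_dict(),
            std_errors=self.bse_.to_dict(),
            n_obs=self.n_obs_,
            residual_df=self.resid_df_,
            r_squared=self.rsquared_,
            pseudo_r_squared=self.pseudo_rsquared_,
            marginal_effects=self.marginal_effects_,
            results=self.results_,
        )


def fit_eq1(data: pd.DataFrame, validate: bool = True) -> FitResult:
    """Belief regression (OLS of G3); see :class:`BeliefRegression`."""
    return BeliefRegression(validate=validate).fit(data).to_fit_result()


def fit_eq2(data: pd.DataFrame, family: str = "probit", validate: bool = True) -> FitResult:
    """Contribution regression (LPM or probit); see
    :class:`ContributionRegression`."""
    return ContributionRegression(family=family, validate=validate).fit(data).to_fit_result()


def contingency_tests(
    table, tests: tuple[str, ...] = ("chi2", "barnard"), barnard_grid: int = 200
) -> dict[str, ContingencyResult]:
    """Chi-square and (for 2x2 tables) Barnard exact tests of independence.

    The chi-square test is run without continuity correction. Barnard's
    exact unconditional test maximizes the p-value over a grid of
    ``barnard_grid`` nuisance success probabilities and uses the pooled
    (score) statistic; it treats the two *columns* as independent
    binomial samples of fixed size.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("contingency table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    out: dict[str, ContingencyResult] = {}
    for name in tests:
        if name == "chi2":
            res = stats.chi2_contingency(table, correction=False)
            out[name] = ContingencyResult(float(res.statistic), float(res.pvalue), "chi2")
        elif name == "barnard":
            if table.shape != (2, 2):
                raise ValueError("Barnard's test is defined for 2x2 tables only")
            res = stats.barnard_exact(table, pooled=True, n=barnard_grid)
            out[name] = ContingencyResult(
                float(res.statistic), float(res.pvalue), "barnard"
            )
        else:
            raise ValueError(f"unknown test {name!r}")
    return out


def game1_decile_table(data: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Counts of binned Game 1 investments by no-vaxxer status.

    Investments are binned into ``n_bins`` equal-width bands of the
    endowment (deciles by default); empty bins are dropped so the
    chi-square test is well defined.
    """
    edges = np.linspace(0, ENDOWMENT, n_bins + 1)
    bins = pd.cut(data["g1_invest"], edges, include_lowest=True)
    tab = pd.crosstab(data["no_vaxxer"].astype(bool), bins, dropna=True)
    return tab.loc[:, tab.sum(axis=0) > 0]


def game1_split_table(data: pd.DataFrame, cut: int = 100) -> pd.DataFrame:
    """2x2 counts of investing above vs at-or-below ``cut`` tokens.

    Columns are the two groups being compared (vaxxers, no-vaxxers), the
    orientation in which Barnard's unconditional test treats the group
    sizes as the fixed binomial sample sizes.
    """
    above = data["g1_invest"] > cut
    return pd.crosstab(above, data["no_vaxxer"].astype(bool))
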