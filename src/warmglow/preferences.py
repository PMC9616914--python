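"""CRRA risk preferences inferred from the Game 1 investment choice.

The investment task identifies a constant-relative-risk-aversion (CRRA)
coefficient under narrow bracketing: utility is defined over the game's own
monetary payoff with zero background wealth. For an interior investment
``q`` the first-order condition of

    max_q  0.5 u(200 + 1.5 q) + 0.5 u(200 - q),   u(x) = x^(1-rho)/(1-rho)

pins down the unique ``rho`` that makes ``q`` optimal:

    rho = ln(1.5) / ln((200 + 1.5 q) / (200 - q)).

Corner choices are censored: q=200 is consistent with any rho <= 0 and is
floored at the risk-neutral value 0; q=0 is consistent with arbitrarily
large aversion and is capped at ``RHO_CAP``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .games import ENDOWMENT, RETURN_MULTIPLIER

__all__ = [
    "RHO_CAP",
    "RiskPreference",
    "crra_utility",
    "crra_from_investment",
    "optimal_investment",
]

#: Upper cap on the inferred CRRA coefficient at the q=0 corner. Any cap
#: above ~5 is behaviorally indistinguishable in this game.
RHO_CAP = 20.0

# net gain multiplier on invested tokens in the success state (2.5 - 1)
_GAIN = RETURN_MULTIPLIER - 1.0


@dataclass(frozen=True)
class RiskPreference:
    """CRRA coefficient inferred from Game 1, with corner-censoring flag.

    ``censoring`` is ``"none"`` for interior investments,
    ``"at_risk_neutral_floor"`` when q=200 (rho floored at 0) and
    ``"at_upper_cap"`` when q=0 (rho capped at ``RHO_CAP``).
    """

    rho: float
    censoring: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= RHO_CAP:
            raise ValueError(f"rho={self.rho} outside [0, {RHO_CAP}]")
        if self.censoring not in ("none", "at_risk_neutral_floor", "at_upper_cap"):
            raise ValueError(f"unknown censoring flag {self.censoring!r}")


def crra_utility(x: float, rho: float) -> float:
    """CRRA utility u(x) = x^(1-rho)/(1-rho), with u(x) = ln(x) at rho=1.

    Defined for non-negative wealth only; at x=0 with rho >= 1 the utility
    diverges and ``-inf`` is returned by convention.
    """
    if x < 0:
        raise ValueError(f"CRRA utility undefined for negative wealth x={x}")
    if rho == 1.0:
        return math.log(x) if x > 0 else -math.inf
    if x == 0.0 and rho > 1.0:
        return -math.inf
    return x ** (1.0 - rho) / (1.0 - rho)


def _validate_q(q: int) -> int:
    if isinstance(q, float) and not float(q).is_integer():
        raise ValueError(f"investment q={q} must be an integer token count")
    q = int(q)
    if not 0 <= q <= ENDOWMENT:
        raise ValueError(f"investment q={q} outside [0, {ENDOWMENT}]")
    return q


def crra_from_investment(q: int) -> RiskPreference:
    """Invert the Game 1 first-order condition for the CRRA coefficient.

    Parameters
    ----------
    q : int
        Tokens invested, in [0, 200].

    Returns
    -------
    RiskPreference
        The unique rho making ``q`` optimal, censored at the corners.
    """
    q = _validate_q(q)
    if q == ENDOWMENT:
        return RiskPreference(0.0, "at_risk_neutral_floor")
    if q == 0:
        return RiskPreference(RHO_CAP, "at_upper_cap")
    rho = math.log(_GAIN) / math.log(
        (ENDOWMENT + _GAIN * q) / (ENDOWMENT - q)
    )
    return RiskPreference(min(max(rho, 0.0), RHO_CAP))


def optimal_investment(rho: float) -> int:
    """Integer investment maximizing expected CRRA utility of Game 1.

    Brute-force argmax over q in {0, ..., 200}; ties break toward the
    smaller investment.
    """
    if not 0.0 <= rho <= RHO_CAP:
        raise ValueError(f"rho={rho} outside [0, {RHO_CAP}]")
    q = np.arange(ENDOWMENT + 1, dtype=float)
    hi = ENDOWMENT + _GAIN * q
    lo = ENDOWMENT - q
    with np.errstate(divide="ignore", invalid="ignore"):
        if rho == 1.0:
            eu = 0.5 * np.log(hi) + 0.5 * np.where(lo > 0, np.log(lo), -np.inf)
        else:
            pw = lambda x: np.where(  # noqa: E731
                (x > 0) | (rho < 1), x ** (1.0 - rho) / (1.0 - rho), -np.inf
            )
            eu = 0.5 * pw(hi) + 0.5 * pw(lo)
    return int(np.argmax(eu))  # argmax returns the first (smallest q) maximizer
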