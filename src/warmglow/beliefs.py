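"""Beliefs about others' contributions, from the Game 3 guess.

A guess of ``t`` among the ``N - 1`` other group members point-identifies
an i.i.d. contribution probability ``p = t / (N - 1)``. Under that belief
the number of other contributors is ``X ~ Binomial(N - 1, p)``, and the
three outcome probabilities that drive the rationality classification are

* ``prob_pivot``                — P(X = T - 1): the respondent is pivotal,
* ``prob_success_if_contribute``— P(X >= T - 1),
* ``prob_success_if_defect``    — P(X >= T).

Exact binomial tails are used throughout (no normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

from .games import TreatmentSpec, get_treatment

__all__ = ["BeliefModel", "belief_from_guess", "belief_interval_from_guess",
           "outcome_probabilities"]


@dataclass(frozen=True)
class BeliefModel:
    """Binomial outcome probabilities implied by contribution belief ``p``."""

    p: float
    n_others: int
    prob_pivot: float
    prob_success_if_contribute: float
    prob_success_if_defect: float


def _validate_guess(t: int, spec: TreatmentSpec) -> int:
    if isinstance(t, float) and not float(t).is_integer():
        raise ValueError(
            f"guess t={t} must be an integer count of other contributors"
        )
    t = int(t)
    if not 0 <= t <= spec.n_others:
        raise ValueError(f"guess t={t} outside [0, {spec.n_others}]")
    return t


def belief_from_guess(t: int, spec: "str | TreatmentSpec") -> float:
    """Point-identified i.i.d. contribution probability p = t / (N - 1)."""
    spec = get_treatment(spec)
    t = _validate_guess(t, spec)
    return t / spec.n_others


def belief_interval_from_guess(
    t: int, spec: "str | TreatmentSpec"
) -> tuple[float, float]:
    """Half-unit belief interval [t - 1/2, t + 1/2] / (N - 1), clipped to [0, 1].

    The integer guess only brackets the underlying belief; this interval is
    exposed for sensitivity analysis around the point estimate.
    """
    spec = get_treatment(spec)
    t = _validate_guess(t, spec)
    lo = max(t - 0.5, 0.0) / spec.n_others
    hi = min(t + 0.5, float(spec.n_others)) / spec.n_others
    return lo, hi


def outcome_probabilities(p: float, spec: "str | TreatmentSpec") -> BeliefModel:
    """Exact binomial outcome probabilities for X ~ Binomial(N - 1, p).

    Returns the pivot probability P(X = T - 1) and the success
    probabilities conditional on contributing, P(X >= T - 1), and on
    defecting, P(X >= T).
    """
    spec = get_treatment(spec)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"belief p={p} outside [0, 1]")
    n, k = spec.n_others, spec.threshold - 1
    pivot = float(binom.pmf(k, n, p))
    succ_contribute = float(binom.sf(k - 1, n, p))  # P(X >= T-1)
    succ_defect = float(binom.sf(k, n, p))          # P(X >= T)
    return BeliefModel(
        p=p,
        n_others=n,
        prob_pivot=pivot,
        prob_success_if_contribute=succ_contribute,
        prob_success_if_defect=succ_defect,
    )
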