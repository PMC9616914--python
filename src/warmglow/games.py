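"""Rules and payoff functions for the three incentivized survey games.

Game 1 is a risk-elicitation investment task: each respondent holds 200
tokens and invests ``q`` of them in a project that returns ``2.5 q`` with
probability one half and nothing otherwise; tokens not invested are kept.

Game 2 is a one-shot binary threshold public-good game. A group of ``N``
players each decide whether to contribute; the good is produced iff at
least ``T < N`` players contribute. Payoffs (in tokens) follow the survey's
payoff table; in the "safe" treatment T3 contributors are partially
compensated when the threshold is missed.

Game 3 is an incentivized belief-elicitation task: the respondent guesses
how many of the ``N - 1`` *other* group members contributed in Game 2 and
is paid on banded guess accuracy.

One token is worth one euro cent throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = [
    "TOKEN_EUR",
    "TreatmentSpec",
    "TREATMENTS",
    "get_treatment",
    "game1_payoff",
    "game2_payoff",
    "game3_score",
]

#: Conversion rate: one token = one euro cent.
TOKEN_EUR = 0.01

#: Game 1 endowment in tokens.
ENDOWMENT = 200

#: Game 1 gross return multiplier on the risky project.
RETURN_MULTIPLIER = 2.5


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment arm of the public-good and belief games.

    Parameters
    ----------
    id : str
        Treatment label, one of ``"T1"``, ``"T2"``, ``"T3"``.
    group_size : int
        Number of players ``N`` in the group.
    threshold : int
        Minimum number of contributors ``T`` required to produce the good;
        must satisfy ``T < N``.
    pay_contribute_fail, pay_contribute_success : int
        Tokens paid to a contributor when the threshold is missed / met.
    pay_defect_fail, pay_defect_success : int
        Tokens paid to a non-contributor when the threshold is missed / met.
    guess_band_150, guess_band_100 : int
        Largest absolute guess error (in players) still scoring 150 and
        100 tokens respectively in Game 3; an exact guess scores 300 and
        anything beyond ``guess_band_100`` scores 50.
    """

    id: str
    group_size: int
    threshold: int
    pay_contribute_fail: int
    pay_contribute_success: int
    pay_defect_fail: int
    pay_defect_success: int
    guess_band_150: int
    guess_band_100: int

    def __post_init__(self) -> None:
        if not self.threshold < self.group_size:
            raise ValueError(
                f"threshold T={self.threshold} must be below group size "
                f"N={self.group_size}"
            )
        if not 1 <= self.guess_band_150 <= self.guess_band_100:
            raise ValueError("guess bands must be nested: 1 <= band150 <= band100")

    @property
    def n_others(self) -> int:
        """Number of other group members, ``N - 1``."""
        return self.group_size - 1

    def to_config(self) -> dict:
        """Plain key-value serialization of the treatment for reports."""
        return asdict(self)


#: Registry of the three treatment arms used in the survey.
#: T1 "small and risky": N=5, T=3, contributors lose their stake on failure.
#: T2 "large and risky": N=50, T=25, same failure rule.
#: T3 "large and safe": N=50, T=25, contributors get 200 tokens back on failure.
TREATMENTS: dict[str, TreatmentSpec] = {
    "T1": TreatmentSpec("T1", 5, 3, 0, 300, 100, 400, 1, 2),
    "T2": TreatmentSpec("T2", 50, 25, 0, 300, 100, 400, 2, 10),
    "T3": TreatmentSpec("T3", 50, 25, 200, 300, 100, 400, 2, 10),
}


def get_treatment(treatment: "str | TreatmentSpec") -> TreatmentSpec:
    """Resolve a treatment id string (or pass a spec through)."""
    if isinstance(treatment, TreatmentSpec):
        return treatment
    try:
        return TREATMENTS[treatment]
    except KeyError:
        raise KeyError(
            f"unknown treatment {treatment!r}; expected one of {sorted(TREATMENTS)}"
        ) from None


def game1_payoff(q: int, success: bool) -> float:
    """Token payoff of investing ``q`` of the 200-token endowment.

    The project returns ``2.5 q`` tokens with probability one half
    (``success=True``) and nothing otherwise; unspent tokens are kept.
    """
    if not (0 <= q <= ENDOWMENT):
        raise ValueError(f"investment q={q} outside [0, {ENDOWMENT}]")
    kept = ENDOWMENT - q
    return kept + RETURN_MULTIPLIER * q if success else float(kept)


def game2_payoff(
    contributed: bool, total_contributors: int, spec: "str | TreatmentSpec"
) -> int:
    """Token payoff in the threshold public-good game.

    ``total_contributors`` counts all contributors in the group, including
    the respondent when she contributed. The good is produced iff the count
    meets the treatment threshold.
    """
    spec = get_treatment(spec)
    if not (0 <= total_contributors <= spec.group_size):
        raise ValueError(
            f"total_contributors={total_contributors} outside "
            f"[0, {spec.group_size}]"
        )
    if contributed and total_contributors == 0:
        raise ValueError("contributed=True requires at least one contributor")
    success = total_contributors >= spec.threshold
    if contributed:
        return spec.pay_contribute_success if success else spec.pay_contribute_fail
    return spec.pay_defect_success if success else spec.pay_defect_fail


def game3_score(guess: int, actual: int, spec: "str | TreatmentSpec") -> int:
    """Token payoff for the belief-elicitation guess.

    Scoring bands are nested and inclusive: an exact guess pays 300 tokens,
    an absolute error up to ``guess_band_150`` pays 150, up to
    ``guess_band_100`` pays 100, and larger errors pay 50.
    """
    spec = get_treatment(spec)
    for name, value in (("guess", guess), ("actual", actual)):
        if not (0 <= value <= spec.n_others):
            raise ValueError(f"{name}={value} outside [0, {spec.n_others}]")
    err = abs(guess - actual)
    if err == 0:
        return 300
    if err <= spec.guess_band_150:
        return 150
    if err <= spec.guess_band_100:
        return 100
    return 50
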