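"""Respondent schema shared by the I/O, classification and simulation layers."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .games import ENDOWMENT, get_treatment

__all__ = ["Respondent", "ITALIAN_REGIONS", "REQUIRED_COLUMNS", "validate_cohort"]

#: The 20 Italian regions used as the categorical residence control.
ITALIAN_REGIONS = (
    "Abruzzo", "Basilicata", "Calabria", "Campania", "Emilia-Romagna",
    "Friuli-Venezia Giulia", "Lazio", "Liguria", "Lombardia", "Marche",
    "Molise", "Piemonte", "Puglia", "Sardegna", "Sicilia", "Toscana",
    "Trentino-Alto Adige", "Umbria", "Valle d'Aosta", "Veneto",
)

REQUIRED_COLUMNS = (
    "respondent_id", "treatment", "g1_invest", "g2_contribute", "g3_guess",
    "vaccinated", "had_covid", "wants_vaccine", "no_vaxxer", "age", "region",
)


@dataclass(frozen=True)
class Respondent:
    """One survey row: game choices, treatment arm, vaccination fields."""

    respondent_id: str
    treatment: str
    g1_invest: int
    g2_contribute: bool
    g3_guess: int
    vaccinated: bool
    had_covid: bool
    wants_vaccine: bool
    age: float
    region: str

    @property
    def no_vaxxer(self) -> bool:
        """Unvaccinated, no prior infection, and unwilling to vaccinate."""
        return not (self.vaccinated or self.had_covid or self.wants_vaccine)


def validate_cohort(df: pd.DataFrame, on_invalid: str = "raise") -> pd.DataFrame:
    """Validate a cohort table against the survey schema.

    Checks column presence, game-choice ranges per treatment, region
    levels, and consistency of the derived ``no_vaxxer`` flag with the
    three vaccination fields. Invalid rows either abort with an error
    naming the offending rows (``on_invalid="raise"``) or are dropped
    (``on_invalid="drop"``).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    df = df.copy()
    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask & ~bad]:
            reasons[idx] = reason
        bad[mask] = True

    flag(~df["treatment"].isin(("T1", "T2", "T3")), "unknown treatment")
    flag(~df["region"].isin(ITALIAN_REGIONS), "unknown region")
    flag(~df["g1_invest"].between(0, ENDOWMENT), "g1_invest outside [0, 200]")
    n_others = df["treatment"].map(
        lambda t: get_treatment(t).n_others if t in ("T1", "T2", "T3") else -1
    )
    flag(
        (df["g3_guess"] < 0) | (df["g3_guess"] > n_others),
        "g3_guess outside [0, N-1] for treatment",
    )
    derived = ~(
        df["vaccinated"].astype(bool)
        | df["had_covid"].astype(bool)
        | df["wants_vaccine"].astype(bool)
    )
    flag(
        derived != df["no_vaxxer"].astype(bool),
        "no_vaxxer inconsistent with vaccination fields",
    )

    if bad.any():
        detail = "; ".join(
            f"row {idx}: {reason}" for idx, reason in sorted(reasons.items())[:10]
        )
        if on_invalid == "raise":
            raise ValueError(f"{int(bad.sum())} invalid cohort rows ({detail})")
        df = df[~bad]
    if df.empty:
        raise ValueError("cohort table has no valid rows")
    return df
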