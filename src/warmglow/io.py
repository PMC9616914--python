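"""CSV reading/writing for cohort tables and flat key-value configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .cohort import REQUIRED_COLUMNS, validate_cohort
from .synthetic_data import CohortParams

__all__ = ["read_cohort", "write_cohort", "read_params", "write_params"]

_BOOL_COLUMNS = ("g2_contribute", "vaccinated", "had_covid", "wants_vaccine", "no_vaxxer")
_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def read_cohort(
    path: "str | Path", delimiter: str = ",", on_invalid: str = "raise"
) -> pd.DataFrame:
    """Read and validate a respondent-level cohort CSV.

    Boolean columns accept true/false, yes/no, 1/0 (case-insensitive).
    Rows failing validation abort with row numbers (``on_invalid="raise"``)
    or are dropped (``"drop"``).
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype={"respondent_id": str})
    if df.empty:
        raise ValueError(f"cohort file {path} has no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map(_parse_bool).astype(bool)
    for col in ("g1_invest", "g3_guess"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    return validate_cohort(df, on_invalid=on_invalid)


def write_cohort(df: pd.DataFrame, path: "str | Path") -> None:
    """Write a cohort table as RFC-4180 CSV (booleans as True/False)."""
    df.to_csv(path, index=False)


def read_params(path: "str | Path") -> CohortParams:
    """Read generator parameters from a flat ``key = value`` text file.

    Unknown keys are rejected. The nested contribution marginal effects
    use dotted keys (``contribution_ames.G3 = 0.69``).
    """
    fields = {f.name: f for f in dataclasses.fields(CohortParams)}
    kwargs: dict = {}
    ames = dict(CohortParams().contribution_ames)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("contribution_ames."):
            sub = key.split(".", 1)[1]
            if sub not in ames:
                raise ValueError(f"{path}:{lineno}: unknown marginal effect {sub!r}")
            ames[sub] = float(value)
            continue
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key == "behavior":
            kwargs[key] = value
        elif key in ("n", "n_regions", "seed"):
            kwargs[key] = int(value)
        elif key == "age_range":
            lo, hi = value.split(",")
            kwargs[key] = (float(lo), float(hi))
        else:
            kwargs[key] = float(value)
    kwargs["contribution_ames"] = ames
    return CohortParams(**kwargs)


def write_params(params: CohortParams, path: "str | Path") -> None:
    """Write generator parameters as a flat key-value file."""
    lines = []
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if f.name == "contribution_ames":
            for k, v in value.items():
                lines.append(f"contribution_ames.{k} = {v}")
        elif f.name == "age_range":
            lines.append(f"age_range = {value[0]}, {value[1]}")
        else:
            lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
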