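import pandas as pd
import pytest

from warmglow import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 300-respondent synthetic cohort with the default planted structure."""
    cohort, _ = generate_cohort(CohortParams(n=300, seed=7))
    return cohort


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """A full-size cohort (n=1482) mirroring the survey's scale."""
    cohort, _ = generate_cohort(CohortParams(seed=42))
    return cohort


def make_respondent_row(
    treatment="T2",
    g1_invest=100,
    g2_contribute=True,
    g3_guess=20,
    no_vaxxer=False,
    age=40,
    region="Toscana",
    respondent_id="r0",
):
    """One schema-consistent cohort row as a dict."""
    return {
        "respondent_id": respondent_id,
        "treatment": treatment,
        "g1_invest": g1_invest,
        "g2_contribute": g2_contribute,
        "g3_guess": g3_guess,
        "vaccinated": not no_vaxxer,
        "had_covid": False,
        "wants_vaccine": False,
        "no_vaxxer": no_vaxxer,
        "age": age,
        "region": region,
    }
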