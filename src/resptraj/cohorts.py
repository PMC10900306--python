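"""New-diagnosis cohort construction for asthma and COPD.

Two mutually exclusive cohorts: adults newly diagnosed with asthma (no prior
COPD) and adults newly diagnosed with COPD (no prior asthma).  A patient
enters on the date of first diagnosis (the index date) and must have a first
diagnosis inside the calendar window (2010–2019 by default), at least 1 year
of observation before index, at least 3 years of follow-up after index, and
meet the disease-specific minimum age (18 for asthma, 40 for COPD).
"""

from __future__ import annotations

import pandas as pd

from .config import RunConfig, year_of_day
from .io import TableBundle

#: Exclusion reasons in the fixed precedence/reporting order.
EXCLUSION_REASONS = (
    "index_outside_window",
    "below_min_age",
    "short_prior_observation",
    "short_followup",
    "prior_other_disease",
)

COHORT_COLUMNS = ["person_id", "disease", "index_day", "followup_end_day", "age_at_index"]

_OTHER = {"asthma": "copd", "copd": "asthma"}


def find_first_diagnosis(conditions: pd.DataFrame, disease: str) -> pd.Series:
    """Earliest diagnosis day per person for ``disease`` over all history.

    Persons without a record of the disease are simply absent from the
    returned Series (index: person_id, values: day).
    """
    hits = conditions[conditions["concept"] == disease]
    return hits.groupby("person_id")["day"].min()


def build_cohort(
    bundle: TableBundle, disease: str, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all eligibility rules; return (cohort, attrition tally).

    Each excluded person is tallied under the first failing reason in the
    fixed precedence order: calendar window → age → prior observation →
    follow-up → prior history of the other disease.  "Prior history" means a
    diagnosis of the other disease on or before the index day; later
    cross-diagnoses do not exclude.
    """
    if disease not in _OTHER:
        raise ValueError(f"unknown disease {disease!r}")
    first = find_first_diagnosis(bundle.condition_occurrence, disease)
    first_other = find_first_diagnosis(bundle.condition_occurrence, _OTHER[disease])
    obs = bundle.observation_period.set_index("person_id")
    birth = bundle.person.set_index("person_id")["birth_year"]
    lo, hi = config.index_window
    min_age = config.min_age(disease)

    members = []
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    for pid, index_day in first.sort_index().items():
        index_day = int(index_day)
        age = year_of_day(index_day) - int(birth.loc[pid])
        obs_start = int(obs.at[pid, "start_day"])
        obs_end = int(obs.at[pid, "end_day"])
        if not (lo <= index_day <= hi):
            tally["index_outside_window"] += 1
        elif age < min_age:
            tally["below_min_age"] += 1
        elif index_day - obs_start < config.prior_observation_days:
            tally["short_prior_observation"] += 1
        elif obs_end - index_day < config.followup_days:
            tally["short_followup"] += 1
        elif pid in first_other.index and int(first_other.loc[pid]) <= index_day:
            tally["prior_other_disease"] += 1
        else:
            members.append((pid, disease, index_day, obs_end, age))

    cohort = pd.DataFrame(members, columns=COHORT_COLUMNS)
    attrition = pd.DataFrame(
        {"reason": list(EXCLUSION_REASONS), "excluded": [tally[r] for r in EXCLUSION_REASONS]}
    )
    return cohort, attrition


def assert_disjoint(asthma: pd.DataFrame, copd: pd.DataFrame) -> None:
    """Mutual exclusivity check run on every pipeline run."""
    shared = set(asthma["person_id"]) & set(copd["person_id"])
    if shared:
        raise AssertionError(f"cohorts are not disjoint: {sorted(shared)[:5]}")


def census(cohort: pd.DataFrame, person: pd.DataFrame | None = None) -> dict:
    """Cohort headline summary: n, % male, mean age (1-decimal rounding).

    % male needs the person table for sex; persons with unknown sex are
    excluded from the percentage denominator.
    """
    n = len(cohort)
    if n == 0:
        return {"n": 0, "pct_male": None, "mean_age": None}
    out = {"n": n, "mean_age": round(float(cohort["age_at_index"].mean()), 1)}
    if person is not None:
        sex = person.set_index("person_id")["sex"].reindex(cohort["person_id"])
        known = sex[sex.isin(["male", "female"])]
        out["pct_male"] = round(100.0 * (known == "male").sum() / len(known), 1) if len(known) else None
    else:
        out["pct_male"] = None
    return out
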