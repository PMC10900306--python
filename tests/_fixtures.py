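"""Hand-built table fixtures with hand-computed expected results."""

from __future__ import annotations

import pandas as pd

from resptraj import TableBundle, validate_bundle
from resptraj.config import date_from_day


def _bundle_from_days(person, obs, cond, drug) -> TableBundle:
    def dated(frame, cols):
        frame = frame.copy()
        for col, newcol in cols:
            frame[newcol] = frame[col].map(lambda d: date_from_day(d).isoformat())
            frame = frame.drop(columns=[col])
        return frame

    return validate_bundle(
        {
            "person": person,
            "observation_period": dated(obs, [("start_day", "start_date"), ("end_day", "end_date")]),
            "condition_occurrence": dated(cond, [("day", "date")]),
            "drug_exposure": dated(drug, [("start_day", "start_date"), ("end_day", "end_date")]),
        }
    )


def twelve_person_bundle() -> TableBundle:
    """Twelve hand-built persons covering every cohort exclusion reason.

    Day indices count from 2009-01-01; the study window is days [365, 4016]
    (2010-01-01 .. 2019-12-31).  Hand-derived expectations (defaults: 365 d
    prior observation, 1095 d follow-up, ages 18/40):

    - A1 obs[0,2000], asthma@500, born 1980 (age 30)          -> asthma cohort
    - A2 obs[100,3000], asthma@600, born 1950, male            -> asthma cohort
    - A3 obs[0,2000], asthma@100 (before window)               -> index_outside_window
    - A4 obs[3000,5500], asthma@4100 (after window)            -> index_outside_window
    - A5 obs[0,2000], asthma@500, born 2000 (age 10)           -> below_min_age
    - A6 obs[300,2000], asthma@500 (200 d prior obs)           -> short_prior_observation
    - A7 obs[0,1400], asthma@500 (900 d follow-up)             -> short_followup
    - A8 obs[0,2000], copd@400 then asthma@500, born 1960      -> prior_other_disease
                                                  (but enters the COPD cohort)
    - A9 obs[0,2000], asthma@500 then copd@800, born 1960      -> asthma cohort
                                     (post-index cross-diagnosis never excludes)
    - C1 obs[0,2000], copd@600, born 1950                      -> copd cohort
    - C2 obs[0,2000], copd@600, born 1985 (age 25)             -> copd below_min_age
    - N1 obs[0,2000], no diagnoses                             -> in neither map
    """
    person = pd.DataFrame(
        [
            ("A1", 1980, "female"),
            ("A2", 1950, "male"),
            ("A3", 1980, "female"),
            ("A4", 1960, "female"),
            ("A5", 2000, "female"),
            ("A6", 1980, "female"),
            ("A7", 1980, "female"),
            ("A8", 1960, "male"),
            ("A9", 1960, "female"),
            ("C1", 1950, "female"),
            ("C2", 1985, "male"),
            ("N1", 1980, "female"),
        ],
        columns=["person_id", "birth_year", "sex"],
    )
    obs = pd.DataFrame(
        [
            ("A1", 0, 2000),
            ("A2", 100, 3000),
            ("A3", 0, 2000),
            ("A4", 3000, 5500),
            ("A5", 0, 2000),
            ("A6", 300, 2000),
            ("A7", 0, 1400),
            ("A8", 0, 2000),
            ("A9", 0, 2000),
            ("C1", 0, 2000),
            ("C2", 0, 2000),
            ("N1", 0, 2000),
        ],
        columns=["person_id", "start_day", "end_day"],
    )
    cond = pd.DataFrame(
        [
            ("A1", "asthma", 500),
            ("A2", "asthma", 600),
            ("A3", "asthma", 100),
            ("A4", "asthma", 4100),
            ("A5", "asthma", 500),
            ("A6", "asthma", 500),
            ("A7", "asthma", 500),
            ("A8", "copd", 400),
            ("A8", "asthma", 500),
            ("A9", "asthma", 500),
            ("A9", "copd", 800),
            ("C1", "copd", 600),
            ("C2", "copd", 600),
        ],
        columns=["person_id", "concept", "day"],
    )
    drug = pd.DataFrame([], columns=["person_id", "drug_class", "start_day", "end_day"])
    return _bundle_from_days(person, obs, cond, drug)


EXPECTED_ASTHMA_COHORT = {"A1", "A2", "A9"}
EXPECTED_COPD_COHORT = {"A8", "C1"}
EXPECTED_ASTHMA_ATTRITION = {
    "index_outside_window": 2,
    "below_min_age": 1,
    "short_prior_observation": 1,
    "short_followup": 1,
    "prior_other_disease": 1,
}
EXPECTED_COPD_ATTRITION = {
    "index_outside_window": 0,
    "below_min_age": 1,
    "short_prior_observation": 0,
    "short_followup": 0,
    "prior_other_disease": 1,
}
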