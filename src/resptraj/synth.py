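"""Synthetic OMOP-subset data with planted ground truth.

The generator emulates the data structures the trajectory analysis assumes:
per-person observation periods, diagnosis records, and drug exposures in one
of two styles — *prescription* (one long contiguous record per treatment
event, as in EHR databases) or *dispensing* (~30-day fills separated by
stochastic refill gaps, as in claims databases).  Every eligible treated
person carries a planted treatment trajectory drawn from a configurable
distribution, and the construction guarantees the pipeline reconstructs it:
consecutive events are separated by gaps strictly greater than the era-merge
gap, loose combinations are planted as co-extensive intervals (the
full-duration overlap rule), and intra-event refill gaps never exceed the
era-merge gap.  Configurable fractions of persons violate exactly one
eligibility rule each, so cohort filters can be checked against ground truth
exactly.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .config import (
    RunConfig,
    STEROID,
    STEROID_BURST,
    STEROID_MAINTENANCE,
    VOCABULARY,
    canonical_label,
    year_of_day,
)
from .io import TableBundle, validate_bundle
from .steps import load_ladder, classify_transition

INELIGIBLE_REASONS = ("too_young", "short_prior_obs", "short_followup", "prior_other_disease")

#: Class tokens accepted in planted sequences: the input vocabulary minus the
#: raw steroid class, plus the two resolved steroid labels.
PLANTABLE = frozenset((VOCABULARY - {STEROID}) | {STEROID_BURST, STEROID_MAINTENANCE})


class Dist(BaseModel):
    """Mean/sd of a (truncated) normal duration or gap, in days."""

    mean: float
    sd: float = 0.0

    @field_validator("sd")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("sd must be non-negative")
        return v


class PlannedTrajectory(BaseModel):
    """One planted sequence of class sets with its sampling probability."""

    sequence: list[list[str]]
    probability: float

    @field_validator("sequence")
    @classmethod
    def _valid_sets(cls, seq: list[list[str]]) -> list[list[str]]:
        if not seq:
            raise ValueError("empty planted sequence")
        for classes in seq:
            if not classes:
                raise ValueError("empty class set in planted sequence")
            unknown = set(classes) - PLANTABLE
            if unknown:
                raise ValueError(f"unknown classes in planted sequence: {sorted(unknown)}")
            if len(classes) > 1 and {STEROID_BURST, STEROID_MAINTENANCE} & set(classes):
                raise ValueError(
                    "steroid burst/maintenance tokens must be singleton events "
                    "(their duration is constrained by the 30-day rule)"
                )
        for a, b in zip(seq, seq[1:]):
            if set(a) == set(b):
                raise ValueError("consecutive planted events must have different class sets")
        return seq

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(canonical_label(frozenset(s)) for s in self.sequence)


class ScenarioConfig(BaseModel):
    """Everything the generator needs to emit one synthetic database."""

    n_persons: int = 1000
    disease: str = "asthma"
    untreated_fraction: float = 0.0
    trajectory_distribution: list[PlannedTrajectory] = Field(
        default_factory=lambda: [
            PlannedTrajectory(sequence=[["SABA"]], probability=0.4),
            PlannedTrajectory(sequence=[["SABA"], ["ICS"]], probability=0.3),
            PlannedTrajectory(sequence=[["SABA"], ["LABA-ICS"]], probability=0.3),
        ]
    )
    exposure_style: str = "prescription"
    dispensing_fill_days: int = 30
    dispensing_gap_distribution: Dist = Dist(mean=10.0, sd=5.0)
    event_duration_distribution: Dist = Dist(mean=120.0, sd=30.0)
    inter_event_gap_distribution: Dist = Dist(mean=90.0, sd=30.0)
    ineligible_fractions: dict[str, float] = Field(default_factory=dict)
    comorbidity_prevalences: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("disease")
    @classmethod
    def _disease(cls, v: str) -> str:
        if v not in ("asthma", "copd"):
            raise ValueError("disease must be 'asthma' or 'copd'")
        return v

    @field_validator("exposure_style")
    @classmethod
    def _style(cls, v: str) -> str:
        if v not in ("prescription", "dispensing"):
            raise ValueError("exposure_style must be 'prescription' or 'dispensing'")
        return v

    @field_validator("untreated_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("untreated_fraction must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _probabilities(self) -> "ScenarioConfig":
        total = sum(t.probability for t in self.trajectory_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"trajectory probabilities sum to {total}, not 1")
        for reason, frac in self.ineligible_fractions.items():
            if reason not in INELIGIBLE_REASONS:
                raise ValueError(f"unknown ineligible reason {reason!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("ineligible fractions must lie in [0, 1]")
        if sum(self.ineligible_fractions.values()) > 1.0:
            raise ValueError("ineligible fractions must sum to at most 1")
        for concept, p in self.comorbidity_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {concept!r} outside [0, 1]")
        return self

    @classmethod
    def from_file(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _check_feasible(scenario: ScenarioConfig, config: RunConfig) -> None:
    """Reject scenarios whose planted structure the pipeline cannot recover."""
    if scenario.event_duration_distribution.mean < config.min_era_days:
        raise ValueError(
            f"mean event duration {scenario.event_duration_distribution.mean} "
            f"is below the minimum era duration {config.min_era_days}"
        )
    if scenario.inter_event_gap_distribution.mean <= config.era_gap_days:
        raise ValueError(
            "mean inter-event gap must exceed era_gap_days so planted switches "
            "cannot merge into one era"
        )
    if scenario.exposure_style == "dispensing" and scenario.dispensing_fill_days < 1:
        raise ValueError("dispensing_fill_days must be positive")


def _trunc_normal(rng: np.random.Generator, dist: Dist, lo: float, hi: float | None = None) -> int:
    """One integer draw from N(mean, sd) clipped to [lo, hi]."""
    x = rng.normal(dist.mean, dist.sd) if dist.sd > 0 else dist.mean
    if hi is not None:
        x = min(x, hi)
    return int(round(max(x, lo)))


def _event_duration(rng: np.random.Generator, scenario: ScenarioConfig, config: RunConfig, classes: Sequence[str]) -> int:
    classes = set(classes)
    if STEROID_BURST in classes:
        # burst = systemic glucocorticoid era of 5..29 days
        return int(rng.integers(config.min_era_days, config.steroid_maintenance_days))
    lo = float(config.min_era_days)
    if STEROID_MAINTENANCE in classes:
        lo = max(lo, float(config.steroid_maintenance_days))
    return _trunc_normal(rng, scenario.event_duration_distribution, lo)


def _expand_exposures(
    rng: np.random.Generator,
    scenario: ScenarioConfig,
    config: RunConfig,
    drug_class: str,
    start: int,
    end: int,
) -> list[tuple[str, int, int]]:
    """Turn one planted class interval into exposure records.

    Prescription style emits a single contiguous record; dispensing style
    emits ~fill_days records with refill gaps clipped to [0, era_gap_days] so
    the era builder provably re-merges them.
    """
    source_class = STEROID if drug_class in (STEROID_BURST, STEROID_MAINTENANCE) else drug_class
    if scenario.exposure_style == "prescription":
        return [(source_class, start, end)]
    records = []
    pos = start
    while pos <= end:
        fill_end = min(pos + scenario.dispensing_fill_days - 1, end)
        records.append((source_class, pos, fill_end))
        gap = _trunc_normal(rng, scenario.dispensing_gap_distribution, 0, float(config.era_gap_days))
        pos = fill_end + 1 + gap
    return records


def generate(
    scenario: ScenarioConfig, config: RunConfig | None = None
) -> tuple[TableBundle, pd.DataFrame]:
    """Generate the four tables plus per-person ground truth.

    Ground-truth columns: ``person_id, eligible, reason, treated,
    trajectory`` (planted labels joined by ``|``), ``first_transition`` (the
    broad category the planted first transition implies under the default
    ladder), and ``n_events`` (planted event count).  Identical seed and
    scenario give identical tables.
    """
    config = config or RunConfig()
    _check_feasible(scenario, config)
    rng = np.random.default_rng(scenario.seed)
    ladder = load_ladder(scenario.disease, config)
    other_disease = "copd" if scenario.disease == "asthma" else "asthma"
    lo, hi = config.index_window
    min_age = config.min_age(scenario.disease)

    reasons = list(scenario.ineligible_fractions.items())
    traj_probs = [t.probability for t in scenario.trajectory_distribution]

    persons, obs_rows, cond_rows, drug_rows, truth_rows = [], [], [], [], []
    for i in range(scenario.n_persons):
        pid = f"P{i:06d}"
        u = rng.random()
        reason = "eligible"
        acc = 0.0
        for r, frac in reasons:
            acc += frac
            if u < acc:
                reason = r
                break

        index_day = int(rng.integers(lo, hi + 1))
        index_year = year_of_day(index_day)
        age = int(rng.integers(min_age, min_age + 41))
        obs_start = index_day - config.prior_observation_days - int(rng.integers(0, 1500))
        obs_end = index_day + config.followup_days + int(rng.integers(0, 800))

        if reason == "too_young":
            age = max(1, min_age - int(rng.integers(1, 10)))
        elif reason == "short_prior_obs":
            obs_start = index_day - int(rng.integers(0, config.prior_observation_days))
        elif reason == "short_followup":
            obs_end = index_day + int(rng.integers(0, config.followup_days))
        elif reason == "prior_other_disease":
            prior_day = index_day - int(rng.integers(1, config.prior_observation_days))
            cond_rows.append((pid, other_disease, prior_day))

        eligible = reason == "eligible"
        cond_rows.append((pid, scenario.disease, index_day))

        treated = False
        labels: tuple[str, ...] = ()
        n_events = 0
        if eligible and rng.random() >= scenario.untreated_fraction:
            treated = True
            plan = scenario.trajectory_distribution[rng.choice(len(traj_probs), p=traj_probs)]
            labels = plan.labels
            n_events = len(plan.sequence)
            pos = index_day + int(rng.integers(0, 120))
            for classes in plan.sequence:
                dur = _event_duration(rng, scenario, config, classes)
                ev_start, ev_end = pos, pos + dur - 1
                for cls in classes:
                    drug_rows.extend(
                        (pid, c, s, e)
                        for c, s, e in _expand_exposures(rng, scenario, config, cls, ev_start, ev_end)
                    )
                gap = _trunc_normal(
                    rng, scenario.inter_event_gap_distribution, float(config.era_gap_days + 1)
                )
                pos = ev_end + 1 + gap
            obs_end = max(obs_end, pos)

        # Comorbidities, sampled independently per condition; kept inside the
        # observation period and, for recent-only concepts, the prior year.
        for concept, p in sorted(scenario.comorbidity_prevalences.items()):
            if rng.random() < p:
                room = index_day - obs_start
                if room < 1:
                    continue
                lookback = min(365, room) if concept == "lower_respiratory_tract_infection" else room
                cond_rows.append((pid, concept, index_day - int(rng.integers(1, lookback + 1))))

        first_transition = ""
        if treated:
            second = labels[1] if len(labels) > 1 else None
            first_transition = classify_transition(labels[0], second, ladder)

        persons.append((pid, index_year - age, "male" if rng.random() < 0.5 else "female"))
        obs_rows.append((pid, obs_start, obs_end))
        truth_rows.append(
            {
                "person_id": pid,
                "eligible": eligible,
                "reason": reason,
                "treated": treated,
                "trajectory": "|".join(labels),
                "first_transition": first_transition,
                "n_events": n_events,
            }
        )

    bundle = TableBundle(
        person=pd.DataFrame(persons, columns=["person_id", "birth_year", "sex"]),
        observation_period=pd.DataFrame(obs_rows, columns=["person_id", "start_day", "end_day"]),
        condition_occurrence=pd.DataFrame(cond_rows, columns=["person_id", "concept", "day"]),
        drug_exposure=pd.DataFrame(drug_rows, columns=["person_id", "drug_class", "start_day", "end_day"]),
    )
    _revalidate(bundle)
    truth = pd.DataFrame(truth_rows)
    return bundle, truth


def _revalidate(bundle: TableBundle) -> None:
    """Generated tables must pass the same validation as read tables."""
    from .config import date_from_day

    raw = {}
    for name in ("person", "observation_period", "condition_occurrence", "drug_exposure"):
        frame = getattr(bundle, name).copy()
        for col, newcol in (("start_day", "start_date"), ("end_day", "end_date"), ("day", "date")):
            if col in frame.columns:
                frame[newcol] = frame[col].map(lambda d: date_from_day(d).isoformat())
                frame = frame.drop(columns=[col])
        raw[name] = frame
    validated = validate_bundle(raw)
    for name in ("person", "observation_period", "condition_occurrence", "drug_exposure"):
        setattr(bundle, name, getattr(validated, name))


def make_toy_patient(spec: dict[str, Any]) -> TableBundle:
    """Deterministic single-person bundle for worked examples and tests.

    ``spec`` keys: ``person_id`` (default "T0"), ``birth_year`` (default
    1980), ``sex`` (default female), ``observation`` = (start_day, end_day),
    ``conditions`` = [(concept, day), ...], ``exposures`` =
    [(drug_class, start_day, end_day), ...].
    """
    pid = str(spec.get("person_id", "T0"))
    obs = spec.get("observation", (0, 3000))
    bundle = TableBundle(
        person=pd.DataFrame(
            [(pid, int(spec.get("birth_year", 1980)), spec.get("sex", "female"))],
            columns=["person_id", "birth_year", "sex"],
        ),
        observation_period=pd.DataFrame(
            [(pid, int(obs[0]), int(obs[1]))], columns=["person_id", "start_day", "end_day"]
        ),
        condition_occurrence=pd.DataFrame(
            [(pid, c, int(d)) for c, d in spec.get("conditions", [])],
            columns=["person_id", "concept", "day"],
        ),
        drug_exposure=pd.DataFrame(
            [(pid, c, int(s), int(e)) for c, s, e in spec.get("exposures", [])],
            columns=["person_id", "drug_class", "start_day", "end_day"],
        ),
    )
    _revalidate(bundle)
    return bundle
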