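"""Shared conventions: drug-class vocabulary, day-index time model, run configuration.

Time is modelled as integer day indices relative to a fixed epoch
(2009-01-01, one year before the default study window opens, so small
non-negative toy indices carry enough prior observation time and fall inside
the window).  All intervals are closed ``[start, end]`` and a duration is
``end - start + 1`` days, so threshold rules such as "<30 days" are exact
integer comparisons.  "1 year" is 365 days and "3 years" is 1095 days; age is
computed as index calendar year minus birth year.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("resptraj")

# ---------------------------------------------------------------------------
# Time conventions
# ---------------------------------------------------------------------------

EPOCH = _dt.date(2009, 1, 1)


def day_from_date(date: str | _dt.date) -> int:
    """ISO-8601 date -> integer day index (days since the package epoch)."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return (date - EPOCH).days


def date_from_day(day: int) -> _dt.date:
    return EPOCH + _dt.timedelta(days=int(day))


def year_of_day(day: int) -> int:
    """Calendar year of a day index (used for age at index)."""
    return date_from_day(day).year


# ---------------------------------------------------------------------------
# Drug-class vocabulary
# ---------------------------------------------------------------------------

#: Single respiratory drug classes as recorded in drug_exposure.
SINGLE_CLASSES = (
    "ICS",
    "SABA",
    "LABA",
    "SAMA",
    "LAMA",
    "LTRA",
    "xanthines",
    "systemic_glucocorticoid",
    "PDE4",
    "biologics",
)

#: Fixed-combination inhaler products; atomic labels distinct from loose
#: combinations detected by interval overlap.
FIXED_COMBINATIONS = (
    "SABA-SAMA",
    "LABA-LAMA",
    "LABA-ICS",
    "LABA-LAMA-ICS",
)

#: The input vocabulary accepted in the drug_exposure table.
VOCABULARY = frozenset(SINGLE_CLASSES + FIXED_COMBINATIONS)

STEROID = "systemic_glucocorticoid"
STEROID_BURST = "steroid_burst"
STEROID_MAINTENANCE = "steroid_maintenance"

#: Era-level labels: the vocabulary with systemic glucocorticoid resolved into
#: burst vs maintenance.
ERA_CLASSES = frozenset(
    (VOCABULARY - {STEROID}) | {STEROID_BURST, STEROID_MAINTENANCE}
)

DISEASES = ("asthma", "copd")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """All numeric parameters of the analysis, with study defaults.

    Defaults encode the published analysis rules: drug eras merge exposure
    records of one class separated by at most 30 uncovered days, eras shorter
    than 5 days are dropped, concurrent classes overlapping at least 30 days
    (or the full duration of one era) form combination therapy, systemic
    glucocorticoid eras of <30 days are steroid bursts, and trajectories
    occurring in <0.5% of the population are pooled.
    """

    era_gap_days: int = 30
    min_era_days: int = 5
    combination_overlap_days: int = 30
    steroid_maintenance_days: int = 30
    min_trajectory_fraction: float = 0.005
    prior_observation_days: int = 365
    followup_days: int = 1095
    asthma_min_age: int = 18
    copd_min_age: int = 40
    index_window: tuple[int, int] = (
        day_from_date("2010-01-01"),
        day_from_date("2019-12-31"),
    )
    max_trajectory_depth: int = 5
    seed: int = 0

    # Behaviour switches for rules the source rules leave open.
    truncate_at_index: bool = True
    drop_short_remnants: bool = True
    full_duration_uses_remnant: bool = True
    population_includes_untreated: bool = True
    other_wedge: bool = True

    # Optional overrides for packaged data files (None -> packaged default).
    ladders: dict[str, Any] | None = None
    strict_transitions: dict[str, Any] | None = None
    charlson_weights: dict[str, int] | None = None

    @field_validator(
        "era_gap_days",
        "min_era_days",
        "combination_overlap_days",
        "steroid_maintenance_days",
        "prior_observation_days",
        "followup_days",
        "max_trajectory_depth",
    )
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("durations and depths must be positive")
        return v

    @field_validator("min_trajectory_fraction")
    @classmethod
    def _fraction_open_interval(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("min_trajectory_fraction must lie in (0, 1)")
        return v

    @model_validator(mode="after")
    def _window_ordered(self) -> "RunConfig":
        lo, hi = self.index_window
        if lo > hi:
            raise ValueError("index_window start must not exceed its end")
        return self

    def min_age(self, disease: str) -> int:
        if disease == "asthma":
            return self.asthma_min_age
        if disease == "copd":
            return self.copd_min_age
        raise ValueError(f"unknown disease {disease!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a configuration from a YAML or JSON file.

        The file may give the index window as ISO dates; they are converted
        to day indices.
        """
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        raw = dict(raw or {})
        if "index_window" in raw:
            raw["index_window"] = tuple(
                day_from_date(v) if isinstance(v, (str, _dt.date)) else int(v)
                for v in raw["index_window"]
            )
        return cls(**raw)


def canonical_label(classes: frozenset[str] | set[str]) -> str:
    """Canonical rendering of a class set: alphabetical join with '+'.

    Fixed-combination products are atomic tokens, so a loose combination of a
    LABA-ICS inhaler with LTRA renders as ``LABA-ICS+LTRA``.
    """
    if not classes:
        raise ValueError("empty class set has no label")
    return "+".join(sorted(classes))


def label_classes(label: str) -> frozenset[str]:
    """Inverse of :func:`canonical_label`."""
    return frozenset(label.split("+"))
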