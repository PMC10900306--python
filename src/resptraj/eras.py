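"""Drug-era construction: collapse raw exposures into continuous eras.

A drug era is a continuous sequence of exposure records of one drug class
with at most ``era_gap_days`` uncovered days between consecutive records
(gap = next start − previous end − 1; merge when gap ≤ 30 by default).  Eras
shorter than ``min_era_days`` (default 5) are dropped *after* gap-merging, so
short fills that chain into a long era survive.  Systemic glucocorticoid eras
are then split by duration into steroid bursts (<30 days, an exacerbation
marker) and maintenance therapy (≥30 days).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .config import RunConfig, STEROID, STEROID_BURST, STEROID_MAINTENANCE

ERA_COLUMNS = ["person_id", "drug_class", "start_day", "end_day", "duration_days"]


def merge_intervals(
    intervals: Iterable[tuple[int, int]], gap_days: int, min_days: int
) -> list[tuple[int, int]]:
    """Merge closed integer intervals with tolerated gap, then apply a
    minimum-duration filter.

    The unit operation behind era construction, exposed for reuse and
    testing.  Intervals may overlap or arrive unsorted.
    """
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s - merged[-1][1] - 1 <= gap_days:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s + 1 >= min_days]


def build_eras(
    exposures: pd.DataFrame,
    config: RunConfig,
    index_by_person: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Collapse validated drug exposures into per-person, per-class eras.

    When ``index_by_person`` is given, treatment is captured from the index
    date onward: exposures ending before the person's index day are dropped
    and, if ``config.truncate_at_index``, exposures straddling the index are
    truncated at it (post-index portion kept).  Persons absent from the map
    are dropped entirely.

    Returns a frame with columns ``person_id, drug_class, start_day, end_day,
    duration_days`` sorted by (person, class, start).
    """
    exp = exposures.copy()
    if index_by_person is not None:
        idx = exp["person_id"].map(index_by_person)
        exp = exp[idx.notna()].copy()
        idx = idx[idx.notna()].astype(int)
        exp = exp[exp["end_day"] >= idx]
        if config.truncate_at_index:
            idx = idx.loc[exp.index]
            exp["start_day"] = exp["start_day"].clip(lower=idx)
        else:
            exp = exp[exp["start_day"] >= idx.loc[exp.index]]

    rows: list[tuple[str, str, int, int]] = []
    if len(exp):
        for (pid, cls), grp in exp.groupby(["person_id", "drug_class"], sort=True):
            ivs = list(zip(grp["start_day"].astype(int), grp["end_day"].astype(int)))
            for s, e in merge_intervals(ivs, config.era_gap_days, config.min_era_days):
                rows.append((pid, cls, s, e))
    out = pd.DataFrame(rows, columns=ERA_COLUMNS[:4])
    out["duration_days"] = out["end_day"] - out["start_day"] + 1 if len(out) else pd.Series([], dtype="int64")
    return out.sort_values(["person_id", "drug_class", "start_day"]).reset_index(drop=True)


def classify_steroids(eras: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Relabel systemic glucocorticoid eras as burst vs maintenance.

    An era of duration < ``steroid_maintenance_days`` (default 30) becomes
    ``steroid_burst``; otherwise ``steroid_maintenance``.  Classification uses
    the merged era's duration — the era, not the raw record, is the analysis
    unit.  Other classes pass through unchanged.
    """
    out = eras.copy()
    if not len(out):
        return out
    is_steroid = out["drug_class"] == STEROID
    short = out["duration_days"] < config.steroid_maintenance_days
    out.loc[is_steroid & short, "drug_class"] = STEROID_BURST
    out.loc[is_steroid & ~short, "drug_class"] = STEROID_MAINTENANCE
    return out
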