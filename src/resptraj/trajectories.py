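"""Resolve cross-class era overlaps into ordered treatment events and
per-patient treatment trajectories.

Two rules drive the resolution of a pair of overlapping eras:

- *combination therapy*: the overlap lasts at least
  ``combination_overlap_days`` (default 30) OR spans the full duration of one
  of the two eras → a combination event carrying the union of the classes is
  emitted over the overlap, and the non-overlapping remnants survive as
  events;
- *switching*: the overlap is shorter than that → the earlier era is
  truncated at the day before the later one starts (the later class wins the
  overlap window).

Pairs are resolved iteratively, earliest-starting overlap first, until no two
events overlap; combinations of three or more classes arise naturally because
a combination event is itself re-eligible to overlap others.  Remnants
shorter than ``min_era_days`` are then dropped and consecutive events with
identical class sets merged.  The ordered sequence of distinct event labels
is the patient's treatment trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .config import RunConfig, canonical_label

_MAX_ITERATIONS = 100_000


@dataclass(frozen=True)
class Event:
    """A treatment event: one or more classes held over a closed interval."""

    classes: frozenset[str]
    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return canonical_label(self.classes)


def _overlap(a: Event, b: Event) -> tuple[int, int] | None:
    s, e = max(a.start, b.start), min(a.end, b.end)
    return (s, e) if s <= e else None


def _pair_key(a: Event, b: Event) -> tuple:
    """Deterministic processing order: earliest overlap start, then longer
    era first, then alphabetical label."""
    ov = _overlap(a, b)
    assert ov is not None
    longest = max(a.duration, b.duration)
    labels = tuple(sorted((a.label, b.label)))
    return (ov[0], -longest, -(a.duration + b.duration - longest), labels)


def resolve_events(eras: pd.DataFrame, config: RunConfig) -> list[Event]:
    """Resolve one person's drug eras into non-overlapping treatment events.

    ``eras`` holds rows for a single person (columns ``drug_class``,
    ``start_day``, ``end_day``).  Returns events sorted by start day, with
    consecutive identical class sets merged and (by default) remnants shorter
    than ``min_era_days`` dropped.  The result is independent of input row
    order.
    """
    events = [
        Event(frozenset({r.drug_class}), int(r.start_day), int(r.end_day))
        for r in eras.itertuples()
    ]

    for _ in range(_MAX_ITERATIONS):
        pairs = [
            (events[i], events[j])
            for i in range(len(events))
            for j in range(i + 1, len(events))
            if _overlap(events[i], events[j]) is not None
        ]
        if not pairs:
            break
        a, b = min(pairs, key=lambda p: _pair_key(*p))
        # Orient the pair: A starts first; equal starts → longer first, then
        # alphabetical (equal starts always resolve as combination anyway).
        if (a.start, -a.duration, a.label) > (b.start, -b.duration, b.label):
            a, b = b, a
        ov_s, ov_e = _overlap(a, b)
        ov = ov_e - ov_s + 1
        events.remove(a)
        events.remove(b)
        if (
            ov >= config.combination_overlap_days
            or ov == a.duration
            or ov == b.duration
        ):
            events.append(Event(a.classes | b.classes, ov_s, ov_e))
            for ev in (a, b):
                if ev.start < ov_s:
                    events.append(replace(ev, end=ov_s - 1))
                if ev.end > ov_e:
                    events.append(replace(ev, start=ov_e + 1))
        else:
            # Switch: overlap < threshold and A strictly precedes B.
            events.append(replace(a, end=b.start - 1))
            events.append(b)
    else:  # pragma: no cover - guarded; resolution provably terminates
        raise RuntimeError("event resolution did not terminate")

    if config.drop_short_remnants:
        events = [ev for ev in events if ev.duration >= config.min_era_days]
    events.sort(key=lambda ev: (ev.start, ev.end, ev.label))

    # Merge contiguous events with identical class sets (adjacent remnants
    # produced by resolution).  Non-contiguous repeats stay separate events —
    # they collapse to one trajectory label downstream, but their day
    # coverage is kept honest.
    merged: list[Event] = []
    for ev in events:
        if merged and merged[-1].classes == ev.classes and merged[-1].end + 1 >= ev.start:
            merged[-1] = replace(merged[-1], end=max(merged[-1].end, ev.end))
        else:
            merged.append(ev)
    return merged


def build_trajectory(events: list[Event], config: RunConfig) -> tuple[list[str], bool]:
    """Ordered distinct event labels, capped at ``max_trajectory_depth``.

    Returns ``(labels, treated)``; an untreated patient has no events and an
    empty label list.
    """
    labels: list[str] = []
    for ev in events:
        lab = ev.label
        if not labels or labels[-1] != lab:
            labels.append(lab)
    labels = labels[: config.max_trajectory_depth]
    return labels, bool(labels)


def trajectories_for_cohort(
    eras: pd.DataFrame, cohort: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-person event and trajectory tables for every cohort member.

    Members with no surviving eras get an untreated trajectory row.  Returns
    ``(events_df, trajectories_df)``; the trajectory frame has one row per
    member with columns ``person_id, treated, label_1..label_<depth>`` and a
    convenience ``labels`` tuple column.
    """
    by_person = dict(tuple(eras.groupby("person_id"))) if len(eras) else {}
    empty = eras.iloc[0:0]
    ev_rows, tr_rows = [], []
    depth = config.max_trajectory_depth
    for pid in cohort["person_id"]:
        events = resolve_events(by_person.get(pid, empty), config)
        labels, treated = build_trajectory(events, config)
        for ordinal, ev in enumerate(events, start=1):
            ev_rows.append((pid, ordinal, ev.label, ev.start, ev.end))
        row = {"person_id": pid, "treated": treated, "labels": tuple(labels)}
        for k in range(depth):
            row[f"label_{k + 1}"] = labels[k] if k < len(labels) else ""
        tr_rows.append(row)
    events_df = pd.DataFrame(
        ev_rows, columns=["person_id", "ordinal", "label", "start_day", "end_day"]
    )
    traj_cols = ["person_id", "treated", "labels"] + [f"label_{k + 1}" for k in range(depth)]
    trajectories_df = pd.DataFrame(tr_rows, columns=traj_cols)
    trajectories_df["treated"] = trajectories_df["treated"].astype(bool)
    return events_df, trajectories_df


def percent_treated(trajectories: pd.DataFrame) -> float | None:
    """Percentage of cohort members with any respiratory treatment during
    follow-up, rounded to 1 decimal; ``None`` for an empty cohort."""
    n = len(trajectories)
    if n == 0:
        return None
    return round(100.0 * trajectories["treated"].sum() / n, 1)
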