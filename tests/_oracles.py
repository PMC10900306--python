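"""Brute-force oracles, independent of the implementation under test.

Each oracle works at day granularity: mark exposed days in a set, then read
structure off the bitmap.  Slow but obviously correct on small inputs.
"""

from __future__ import annotations

import pandas as pd


def era_oracle(
    intervals: list[tuple[int, int]], gap_days: int, min_days: int
) -> list[tuple[int, int]]:
    """Day-set era construction: mark exposed days, close gaps of at most
    ``gap_days`` uncovered days, keep runs of at least ``min_days``."""
    days: set[int] = set()
    for s, e in intervals:
        days.update(range(s, e + 1))
    if not days:
        return []
    # close gaps: a day is covered if some exposed day lies within gap_days
    # of it on both sides
    lo, hi = min(days), max(days)
    closed = set(days)
    run_start = None
    prev = None
    for d in sorted(days):
        if prev is not None and 1 <= d - prev - 1 <= gap_days:
            closed.update(range(prev + 1, d))
        prev = d
    # extract maximal runs
    runs: list[tuple[int, int]] = []
    d = lo
    cur: int | None = None
    for d in range(lo, hi + 2):
        if d in closed and cur is None:
            cur = d
        elif d not in closed and cur is not None:
            runs.append((cur, d - 1))
            cur = None
    return [(s, e) for s, e in runs if e - s + 1 >= min_days]


def day_class_sets(eras: pd.DataFrame) -> dict[int, frozenset[str]]:
    """Map each day to the set of era classes active on it."""
    out: dict[int, set[str]] = {}
    for r in eras.itertuples():
        for d in range(int(r.start_day), int(r.end_day) + 1):
            out.setdefault(d, set()).add(r.drug_class)
    return {d: frozenset(s) for d, s in out.items()}


def event_day_sets(events) -> dict[int, frozenset[str]]:
    """Map each day to the class set implied by resolved events."""
    out: dict[int, frozenset[str]] = {}
    for ev in events:
        for d in range(ev.start, ev.end + 1):
            assert d not in out, "resolved events overlap"
            out[d] = ev.classes
    return out


def prefix_counts(trajectories: list[tuple[str, ...]]) -> dict[tuple[str, ...], int]:
    """Brute-force count of patients whose trajectory starts with each
    nonempty prefix."""
    out: dict[tuple[str, ...], int] = {}
    for t in trajectories:
        for k in range(1, len(t) + 1):
            out[t[:k]] = out.get(t[:k], 0) + 1
    return out
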