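"""Aggregation and presentation: trajectory counts, sunburst data and plots,
baseline-characteristics tables, first-line treatment distribution.

Trajectories occurring in fewer than ``min_trajectory_fraction`` (default
0.5%) of the population are pooled into an "other" bucket before plotting;
the sunburst is a radial prefix tree where ring *k* shows the *k*-th
treatment of the retained trajectories.
"""

from __future__ import annotations

import html as _html
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .steps import StepLadder, transition_table, guideline_conformance  # noqa: F401 (re-export convenience)


# ---------------------------------------------------------------------------
# Trajectory counting and the 0.5% retention rule
# ---------------------------------------------------------------------------

def count_trajectories(
    trajectories: pd.DataFrame, config: RunConfig
) -> tuple[dict[tuple[str, ...], int], int, int]:
    """Count patients per trajectory and apply the retention threshold.

    Returns ``(retained, other_count, untreated_count)`` where ``retained``
    maps a label tuple to its patient count.  A trajectory is retained when
    its count is at least ``min_trajectory_fraction`` of the population
    (cohort size including untreated by default; treated-only when
    ``config.population_includes_untreated`` is off).  Conservation holds on
    every call: retained + other + untreated = cohort size.
    """
    untreated = int((~trajectories["treated"]).sum())
    counts: dict[tuple[str, ...], int] = {}
    for labels in trajectories.loc[trajectories["treated"], "labels"]:
        counts[labels] = counts.get(labels, 0) + 1
    population = len(trajectories) if config.population_includes_untreated else len(trajectories) - untreated
    threshold = config.min_trajectory_fraction * population
    retained = {t: c for t, c in counts.items() if c >= threshold}
    other = sum(c for t, c in counts.items() if t not in retained)
    assert sum(retained.values()) + other + untreated == len(trajectories)
    return retained, other, untreated


# ---------------------------------------------------------------------------
# Sunburst prefix tree
# ---------------------------------------------------------------------------

@dataclass
class SunburstNode:
    """One wedge: a trajectory prefix, its patient count, and its children."""

    label: str
    depth: int
    patient_count: int
    children: list["SunburstNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "depth": self.depth,
            "patient_count": self.patient_count,
            "children": [c.to_dict() for c in self.children],
        }


def to_sunburst(
    counts: dict[tuple[str, ...], int], other_count: int = 0, config: RunConfig | None = None
) -> list[SunburstNode]:
    """Build the radial prefix tree: node count = patients whose trajectory
    passes through that prefix.

    Returns the depth-1 layer (roots).  When ``other_count`` > 0 and the
    config keeps the explicit wedge (default), a single depth-1 ``other``
    wedge carries the pooled rare trajectories.
    """
    roots: dict[str, SunburstNode] = {}
    store: dict[tuple[str, ...], SunburstNode] = {}
    for labels, n in sorted(counts.items()):
        for k in range(1, len(labels) + 1):
            prefix = labels[:k]
            if prefix not in store:
                store[prefix] = SunburstNode(label=labels[k - 1], depth=k, patient_count=0)
                if k == 1:
                    roots[prefix[0]] = store[prefix]
                else:
                    store[prefix[:-1]].children.append(store[prefix])
            store[prefix].patient_count += n
    out = [roots[k] for k in sorted(roots)]
    if other_count > 0 and (config is None or config.other_wedge):
        out.append(SunburstNode(label="other", depth=1, patient_count=other_count))
    return out


# ---------------------------------------------------------------------------
# Sunburst rendering (self-contained SVG-in-HTML)
# ---------------------------------------------------------------------------

_PALETTE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f", "#edc948",
    "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac", "#86bcb6", "#d37295",
    "#fabfd2", "#b6992d", "#499894", "#79706e", "#d4a6c8", "#9d7660",
]


def _collect_classes(nodes: list[SunburstNode]) -> list[str]:
    seen: set[str] = set()
    stack = list(nodes)
    while stack:
        nd = stack.pop()
        seen.update(nd.label.split("+"))
        stack.extend(nd.children)
    return sorted(seen)


def _arc_path(cx: float, cy: float, r0: float, r1: float, a0: float, a1: float) -> str:
    """SVG path for an annular sector; angles in radians, clockwise from 12."""
    if a1 - a0 >= 2 * math.pi - 1e-9:
        a1 = a0 + 2 * math.pi - 1e-6
    large = 1 if (a1 - a0) > math.pi else 0

    def pt(r: float, a: float) -> tuple[float, float]:
        return (cx + r * math.sin(a), cy - r * math.cos(a))

    x0, y0 = pt(r1, a0)
    x1, y1 = pt(r1, a1)
    x2, y2 = pt(r0, a1)
    x3, y3 = pt(r0, a0)
    return (
        f"M{x0:.2f},{y0:.2f} A{r1:.2f},{r1:.2f} 0 {large} 1 {x1:.2f},{y1:.2f} "
        f"L{x2:.2f},{y2:.2f} A{r0:.2f},{r0:.2f} 0 {large} 0 {x3:.2f},{y3:.2f} Z"
    )


def render_sunburst(
    tree: list[SunburstNode],
    out_path: str | Path,
    n: int | None = None,
    pct_treated: float | None = None,
    title: str = "Treatment trajectories",
) -> Path:
    """Render the prefix tree as a self-contained HTML file.

    The file embeds the node tree as a JSON payload plus a static SVG
    sunburst with hover titles.  Colour assignment per drug class is stable
    across runs (alphabetical palette assignment); a wedge whose label is a
    loose combination is radially striped with the colour of each member
    class.  Annotated with cohort size N and % treated when given.
    """
    out_path = Path(out_path)
    try:
        out_path.parent.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create {out_path.parent}: {exc}") from None

    classes = _collect_classes(tree)
    colour = {cls: _PALETTE[i % len(_PALETTE)] for i, cls in enumerate(classes)}
    max_depth = 0

    def depth_of(nodes: list[SunburstNode]) -> int:
        return max((max(depth_of(nd.children), nd.depth) for nd in nodes), default=0)

    max_depth = depth_of(tree)
    total = sum(nd.patient_count for nd in tree)
    size, cx, cy = 640.0, 320.0, 320.0
    ring = 280.0 / max(max_depth, 1)

    shapes: list[str] = []

    def emit(nodes: list[SunburstNode], a0: float, a1: float, denom: int) -> None:
        angle = a0
        for nd in nodes:
            frac = nd.patient_count / denom if denom else 0.0
            b0, b1 = angle, angle + frac * (a1 - a0)
            r0 = 40.0 + (nd.depth - 1) * ring
            members = sorted(set(nd.label.split("+")))
            band = ring / len(members)
            tip = _html.escape(f"{nd.label}: {nd.patient_count} patients")
            for i, cls in enumerate(members):
                path = _arc_path(cx, cy, r0 + i * band, r0 + (i + 1) * band, b0, b1)
                shapes.append(
                    f'<path d="{path}" fill="{colour.get(cls, "#cccccc")}" '
                    f'stroke="white" stroke-width="1"><title>{tip}</title></path>'
                )
            child_total = sum(c.patient_count for c in nd.children)
            if child_total:
                emit(nd.children, b0, b0 + (b1 - b0) * child_total / nd.patient_count, nd.patient_count)
            angle = b1

    if total:
        emit(tree, 0.0, 2 * math.pi, total)

    caption = title
    if n is not None:
        caption += f" — N={n}"
    if pct_treated is not None:
        caption += f", {pct_treated}% treated"
    legend = "".join(
        f'<span style="margin-right:1em;white-space:nowrap">'
        f'<span style="display:inline-block;width:0.8em;height:0.8em;background:{colour[c]}"></span>'
        f" {_html.escape(c)}</span>"
        for c in classes
    )
    payload = json.dumps([nd.to_dict() for nd in tree], sort_keys=True, indent=1)
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{_html.escape(caption)}</title></head>
<body style="font-family:sans-serif">
<h2>{_html.escape(caption)}</h2>
<svg width="{size:.0f}" height="{size:.0f}" viewBox="0 0 {size:.0f} {size:.0f}">
{chr(10).join(shapes)}
</svg>
<div>{legend}</div>
<script type="application/json" id="sunburst-data">
{payload}
</script>
</body></html>
"""
    out_path.write_text(doc)
    return out_path


# ---------------------------------------------------------------------------
# Baseline characteristics
# ---------------------------------------------------------------------------

#: Comorbidities whose lookback is restricted to the year before index.
RECENT_ONLY = frozenset({"lower_respiratory_tract_infection"})


def baseline_table(
    cohort: pd.DataFrame,
    person: pd.DataFrame,
    conditions: pd.DataFrame,
    charlson_weights: dict[str, int],
    comorbidities: list[str] | None = None,
    recent_only: frozenset[str] = RECENT_ONLY,
    recent_days: int = 365,
) -> pd.DataFrame:
    """Baseline-characteristics table: n, % male, mean age, mean Charlson
    index, and per-comorbidity percentages (any time prior to index; the
    previous year only for concepts in ``recent_only``).

    ``comorbidities`` defaults to every concept present in the condition
    table other than the cohort diseases.  Charlson weights must cover every
    Charlson category encountered via ``charlson_weights``; the index for a
    patient is the sum of weights over the (weighted) categories present
    before index.
    """
    n = len(cohort)
    if comorbidities is None:
        comorbidities = sorted(set(conditions["concept"]) - {"asthma", "copd"})
    for concept in comorbidities:
        if concept in charlson_weights and not isinstance(charlson_weights[concept], int):
            raise ValueError(f"non-integer Charlson weight for {concept!r}")

    rows: list[dict] = []
    sex = person.set_index("person_id")["sex"].reindex(cohort["person_id"])
    known = sex[sex.isin(["male", "female"])]
    rows.append({"characteristic": "n", "value": float(n)})
    rows.append(
        {"characteristic": "pct_male",
         "value": round(100.0 * (known == "male").sum() / len(known), 1) if len(known) else float("nan")}
    )
    rows.append(
        {"characteristic": "mean_age",
         "value": round(float(cohort["age_at_index"].mean()), 1) if n else float("nan")}
    )

    idx = cohort.set_index("person_id")["index_day"]
    cond = conditions[conditions["person_id"].isin(idx.index)]
    present: dict[str, set[str]] = {}
    charlson_per_person = {pid: 0 for pid in idx.index}
    for concept, grp in cond.groupby("concept"):
        if concept in ("asthma", "copd"):
            continue
        person_days = grp.merge(idx.rename("index_day"), left_on="person_id", right_index=True)
        if concept in recent_only:
            prior = person_days[
                (person_days["day"] < person_days["index_day"])
                & (person_days["day"] >= person_days["index_day"] - recent_days)
            ]
        else:
            prior = person_days[person_days["day"] < person_days["index_day"]]
        who = set(prior["person_id"])
        present[concept] = who
        w = charlson_weights.get(concept)
        if w:
            for pid in who:
                charlson_per_person[pid] += w

    rows.append(
        {"characteristic": "mean_charlson",
         "value": round(sum(charlson_per_person.values()) / n, 1) if n else float("nan")}
    )
    for concept in comorbidities:
        who = present.get(concept, set())
        rows.append(
            {"characteristic": f"pct_{concept}",
             "value": round(100.0 * len(who) / n, 1) if n else float("nan")}
        )
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def charlson_index(present_concepts: set[str], weights: dict[str, int]) -> int:
    """Charlson index of one patient: sum of configured weights over present
    categories.  Raises when a configured category lacks a weight."""
    total = 0
    for concept in present_concepts:
        if concept not in weights:
            raise KeyError(f"no Charlson weight configured for {concept!r}")
        total += weights[concept]
    return total


# ---------------------------------------------------------------------------
# First-line treatment distribution
# ---------------------------------------------------------------------------

def first_line_distribution(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Percentage of first treatment labels over treated members (1-decimal,
    sums to 100 up to rounding), most frequent first."""
    treated = trajectories[trajectories["treated"]]
    counts: dict[str, int] = {}
    for labels in treated["labels"]:
        counts[labels[0]] = counts.get(labels[0], 0) + 1
    n = len(treated)
    rows = [
        {"label": lab, "n": c, "percent": round(100.0 * c / n, 1)}
        for lab, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["label", "n", "percent"])
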