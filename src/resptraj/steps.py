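"""Step-up/step-down classification of first treatment transitions.

Every treated patient's first-to-second treatment transition is classified
into one of seven broad categories (step-up, step-down, switching, start of
acute exacerbation, end of acute exacerbation, no follow-up treatment,
other) by comparing event labels on a guideline-derived intensity ladder.
Steroid bursts act as exacerbation markers, not maintenance intensity: a
burst appearing (disappearing) marks the start (end) of an acute
exacerbation, and when both sides of a transition contain a burst the
remaining classes are compared instead.

Guideline conformance is the percentage of patients with a second treatment
whose (first, second) pair belongs to a strict transition set — a literal
reading of the guideline.  Both the ladders and the strict sets ship as
editable YAML data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .config import RunConfig, STEROID_BURST, label_classes, canonical_label

#: Broad categories in the fixed reporting order.
CATEGORIES = (
    "step_up",
    "step_down",
    "switching",
    "exacerbation_start",
    "exacerbation_end",
    "no_followup",
    "other",
)


@dataclass(frozen=True)
class StepLadder:
    """Intensity ladder plus strict transition set for one disease."""

    disease: str
    levels: dict[str, int]
    contains_levels: dict[str, int]
    allowed_strict_transitions: frozenset[tuple[str, str]]

    def level(self, label: str) -> int | None:
        """Ladder level for a canonical label; None when unclassified."""
        if label in self.levels:
            return self.levels[label]
        hits = [lvl for cls, lvl in self.contains_levels.items() if cls in label_classes(label)]
        return max(hits) if hits else None


def _load_packaged(name: str) -> dict:
    with resources.files("resptraj").joinpath("data", name).open() as fh:
        return yaml.safe_load(fh)


def load_ladder(disease: str, config: RunConfig | None = None) -> StepLadder:
    """Build the ladder for a disease from config overrides or packaged data."""
    ladders = (config.ladders if config and config.ladders else None) or _load_packaged("ladders.yaml")
    strict = (
        config.strict_transitions if config and config.strict_transitions else None
    ) or _load_packaged("strict_transitions.yaml")
    if disease not in ladders:
        raise ValueError(f"no ladder defined for disease {disease!r}")
    entry = ladders[disease]
    return StepLadder(
        disease=disease,
        levels={str(k): int(v) for k, v in (entry.get("levels") or {}).items()},
        contains_levels={str(k): int(v) for k, v in (entry.get("contains_levels") or {}).items()},
        allowed_strict_transitions=frozenset(
            (str(a), str(b)) for a, b in (strict.get(disease) or [])
        ),
    )


def classify_transition(
    first_label: str, second_label: str | None, ladder: StepLadder
) -> str:
    """Classify one (first, second) label pair into a broad category.

    Precedence: no second treatment → no_followup; a steroid burst appearing
    → exacerbation_start; a burst disappearing → exacerbation_end; otherwise
    compare ladder levels (higher → step_up, lower → step_down, equal →
    switching); anything unclassifiable → other.
    """
    if second_label is None or second_label == "":
        return "no_followup"
    burst_first = STEROID_BURST in label_classes(first_label)
    burst_second = STEROID_BURST in label_classes(second_label)
    if burst_second and not burst_first:
        return "exacerbation_start"
    if burst_first and not burst_second:
        return "exacerbation_end"
    if burst_first and burst_second:
        # Bursts mark exacerbations, not intensity: compare the remaining
        # classes on both sides.
        a = label_classes(first_label) - {STEROID_BURST}
        b = label_classes(second_label) - {STEROID_BURST}
        if not a or not b or a == b:
            return "other"
        first_label, second_label = canonical_label(a), canonical_label(b)
    lv1, lv2 = ladder.level(first_label), ladder.level(second_label)
    if lv1 is None or lv2 is None:
        return "other"
    if lv2 > lv1:
        return "step_up"
    if lv2 < lv1:
        return "step_down"
    return "switching"


def _first_two(labels: tuple[str, ...]) -> tuple[str, str | None]:
    return labels[0], (labels[1] if len(labels) > 1 else None)


def transition_table(trajectories: pd.DataFrame, ladder: StepLadder) -> pd.DataFrame:
    """Broad-definition category percentages over treated cohort members.

    One category per treated patient (the first transition after first-line
    treatment); percentages are over treated members, rounded to 1 decimal,
    in the fixed seven-row order.  Empty for a cohort with no treated member.
    """
    treated = trajectories[trajectories["treated"]]
    if len(treated) == 0:
        return pd.DataFrame(columns=["category", "n", "percent"])
    counts = {cat: 0 for cat in CATEGORIES}
    for labels in treated["labels"]:
        first, second = _first_two(labels)
        counts[classify_transition(first, second, ladder)] += 1
    n = len(treated)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "n": [counts[c] for c in CATEGORIES],
            "percent": [round(100.0 * counts[c] / n, 1) for c in CATEGORIES],
        }
    )


def classify_all_transitions(trajectories: pd.DataFrame, ladder: StepLadder) -> pd.DataFrame:
    """Per-transition classification over whole trajectories (extra output,
    separate from the first-transition table)."""
    rows = []
    for r in trajectories.itertuples():
        labels = r.labels
        for k in range(max(len(labels) - 1, 0)):
            rows.append(
                (r.person_id, k + 1, labels[k], labels[k + 1],
                 classify_transition(labels[k], labels[k + 1], ladder))
            )
    return pd.DataFrame(rows, columns=["person_id", "transition", "from_label", "to_label", "category"])


def guideline_conformance(trajectories: pd.DataFrame, ladder: StepLadder) -> float | None:
    """Percentage of patients with a second treatment whose first transition
    is in the strict set; ``None`` when nobody has a second treatment."""
    pairs = [
        _first_two(labels)
        for labels in trajectories.loc[trajectories["treated"], "labels"]
    ]
    with_second = [(a, b) for a, b in pairs if b is not None]
    if not with_second:
        return None
    ok = sum(1 for p in with_second if p in ladder.allowed_strict_transitions)
    return round(100.0 * ok / len(with_second), 1)
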