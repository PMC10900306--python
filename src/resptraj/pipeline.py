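"""End-to-end orchestration: validated tables in, study outputs out."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohorts import assert_disjoint, build_cohort, census
from .config import RunConfig, logger
from .eras import build_eras, classify_steroids
from .io import TableBundle, write_outputs
from .reporting import (
    baseline_table,
    count_trajectories,
    first_line_distribution,
    render_sunburst,
    to_sunburst,
)
from .steps import guideline_conformance, load_ladder, transition_table, classify_all_transitions
from .trajectories import percent_treated, trajectories_for_cohort


def _charlson_weights(config: RunConfig) -> dict[str, int]:
    if config.charlson_weights:
        return dict(config.charlson_weights)
    from .steps import _load_packaged

    return {str(k): int(v) for k, v in _load_packaged("charlson_weights.yaml").items()}


def run_pipeline(bundle: TableBundle, disease: str, config: RunConfig) -> dict:
    """Run the full analysis for one cohort.

    Builds both cohorts (asserting their disjointness), then for the
    requested disease: drug eras from index onward, per-patient events and
    trajectories, the first-transition table and guideline conformance, the
    trajectory counts with the 0.5% retention rule, the sunburst tree and
    the baseline table.  Returns a dict of result objects keyed by output
    file name plus in-memory extras under non-file keys.
    """
    cohorts = {d: build_cohort(bundle, d, config) for d in ("asthma", "copd")}
    assert_disjoint(cohorts["asthma"][0], cohorts["copd"][0])
    cohort, attrition = cohorts[disease]
    logger.info("%s cohort: %d members", disease, len(cohort))

    index_by_person = dict(zip(cohort["person_id"], cohort["index_day"]))
    eras = build_eras(bundle.drug_exposure, config, index_by_person)
    eras = classify_steroids(eras, config)

    events_df, traj_df = trajectories_for_cohort(eras, cohort, config)
    pct = percent_treated(traj_df)

    ladder = load_ladder(disease, config)
    transitions = transition_table(traj_df, ladder)
    conformance = guideline_conformance(traj_df, ladder)
    all_transitions = classify_all_transitions(traj_df, ladder)

    retained, other_count, untreated_count = count_trajectories(traj_df, config)
    tree = to_sunburst(retained, other_count, config)
    counts_df = pd.DataFrame(
        [{"trajectory": "|".join(t), "n": c} for t, c in sorted(retained.items(), key=lambda kv: (-kv[1], kv[0]))]
        + [{"trajectory": "<other>", "n": other_count}, {"trajectory": "<untreated>", "n": untreated_count}],
        columns=["trajectory", "n"],
    )

    baseline = baseline_table(
        cohort, bundle.person, bundle.condition_occurrence, _charlson_weights(config)
    )

    summary = census(cohort, bundle.person)
    summary["percent_treated"] = pct
    summary["guideline_conformance"] = conformance
    summary["disease"] = disease

    return {
        "cohort.csv": cohort.drop(columns=[], errors="ignore"),
        "attrition.csv": attrition,
        "drug_eras.csv": eras,
        "events.csv": events_df,
        "trajectories.csv": traj_df.drop(columns=["labels"]),
        "transition_table.csv": transitions,
        "all_transitions.csv": all_transitions,
        "trajectory_counts.csv": counts_df,
        "first_line.csv": first_line_distribution(traj_df),
        "baseline.csv": baseline,
        "summary.json": summary,
        "sunburst.json": [nd.to_dict() for nd in tree],
        # non-file extras for programmatic use
        "_trajectories": traj_df,
        "_tree": tree,
        "_retained": retained,
        "_other_count": other_count,
        "_untreated_count": untreated_count,
    }


def write_results(results: dict, out_dir: str | Path) -> pd.DataFrame:
    """Write all file-keyed results plus the rendered sunburst; return the
    checksum manifest."""
    out_dir = Path(out_dir)
    files = {k: v for k, v in results.items() if not k.startswith("_")}
    summary = results.get("summary.json", {})
    out_dir.mkdir(parents=True, exist_ok=True)
    render_sunburst(
        results["_tree"],
        out_dir / "sunburst.html",
        n=summary.get("n"),
        pct_treated=summary.get("percent_treated"),
        title=f"Treatment trajectories ({summary.get('disease', '')})",
    )
    manifest = write_outputs(files, out_dir)
    html = out_dir / "sunburst.html"
    import hashlib

    row = pd.DataFrame(
        [{"file": "sunburst.html", "sha256": hashlib.sha256(html.read_bytes()).hexdigest(), "bytes": html.stat().st_size}]
    )
    manifest = pd.concat([manifest, row], ignore_index=True).sort_values("file").reset_index(drop=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
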