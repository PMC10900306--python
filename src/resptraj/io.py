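"""Reading, validating and writing the OMOP-subset tables and run outputs.

The pipeline consumes four tables shaped like a minimal class-level subset of
the OMOP common data model: ``person``, ``observation_period``,
``condition_occurrence`` and ``drug_exposure``.  Dates arrive as ISO-8601
strings (CSV) or date columns (Parquet) and are converted to integer day
indices on read; every downstream module sees only validated bundles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import RunConfig, VOCABULARY, date_from_day, logger

TABLE_NAMES = ("person", "observation_period", "condition_occurrence", "drug_exposure")

_SCHEMAS: dict[str, list[str]] = {
    "person": ["person_id", "birth_year", "sex"],
    "observation_period": ["person_id", "start_date", "end_date"],
    "condition_occurrence": ["person_id", "concept", "date"],
    "drug_exposure": ["person_id", "drug_class", "start_date", "end_date"],
}

SEXES = ("male", "female", "unknown")


class SchemaError(ValueError):
    """A table violates the expected schema or an invariant."""


@dataclass
class TableBundle:
    """The four validated tables with dates converted to day indices.

    Columns after validation:

    - ``person``: person_id, birth_year, sex
    - ``observation_period``: person_id, start_day, end_day
    - ``condition_occurrence``: person_id, concept, day
    - ``drug_exposure``: person_id, drug_class, start_day, end_day
    """

    person: pd.DataFrame
    observation_period: pd.DataFrame
    condition_occurrence: pd.DataFrame
    drug_exposure: pd.DataFrame

    def row_counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLE_NAMES}


def _date_cols_to_days(frame: pd.DataFrame, table: str) -> pd.DataFrame:
    from .config import EPOCH

    out = frame.copy()
    epoch = pd.Timestamp(EPOCH)
    for col in list(out.columns):
        if col in ("start_date", "end_date", "date"):
            try:
                dates = pd.to_datetime(out[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{table}.{col}: unparseable date ({exc})") from None
            newcol = {"start_date": "start_day", "end_date": "end_day", "date": "day"}[col]
            out[newcol] = (dates - epoch).dt.days.astype("int64") if len(out) else pd.Series([], dtype="int64")
            out = out.drop(columns=[col])
    return out


def _read_one(path: Path) -> pd.DataFrame:
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def validate_bundle(tables: dict[str, pd.DataFrame], config: RunConfig | None = None) -> TableBundle:
    """Validate raw tables (date columns still present) into a TableBundle.

    Raises :class:`SchemaError` naming the offending table, column or rows on
    any violation: missing columns, unparseable dates, end before start,
    duplicate person ids, more than one observation period per person,
    drug classes outside the vocabulary, or condition days outside the
    person's observation period.
    """
    for name in TABLE_NAMES:
        if name not in tables:
            raise SchemaError(f"missing table {name!r}")
        missing = [c for c in _SCHEMAS[name] if c not in tables[name].columns]
        if missing:
            raise SchemaError(f"{name}: missing columns {missing}")

    person = tables["person"][_SCHEMAS["person"]].copy()
    person["person_id"] = person["person_id"].astype(str)
    person["birth_year"] = person["birth_year"].astype(int)
    if person["person_id"].duplicated().any():
        dup = person.loc[person["person_id"].duplicated(), "person_id"].tolist()
        raise SchemaError(f"person: duplicate person_id {dup[:5]}")
    bad_sex = sorted(set(person["sex"]) - set(SEXES))
    if bad_sex:
        raise SchemaError(f"person.sex: unknown levels {bad_sex}")

    obs = _date_cols_to_days(tables["observation_period"][_SCHEMAS["observation_period"]], "observation_period")
    obs["person_id"] = obs["person_id"].astype(str)
    if obs["person_id"].duplicated().any():
        raise SchemaError("observation_period: more than one period per person; pre-merge periods")
    bad = obs[obs["end_day"] < obs["start_day"]]
    if len(bad):
        raise SchemaError(f"observation_period: end before start for persons {bad['person_id'].tolist()[:5]}")

    cond = _date_cols_to_days(tables["condition_occurrence"][_SCHEMAS["condition_occurrence"]], "condition_occurrence")
    cond["person_id"] = cond["person_id"].astype(str)
    cond["concept"] = cond["concept"].astype(str)

    drug = _date_cols_to_days(tables["drug_exposure"][_SCHEMAS["drug_exposure"]], "drug_exposure")
    drug["person_id"] = drug["person_id"].astype(str)
    drug["drug_class"] = drug["drug_class"].astype(str)
    unknown = sorted(set(drug["drug_class"]) - VOCABULARY)
    if unknown:
        raise SchemaError(f"drug_exposure.drug_class: unknown classes {unknown}")
    bad = drug[drug["end_day"] < drug["start_day"]]
    if len(bad):
        raise SchemaError(
            "drug_exposure: end_day < start_day at rows "
            f"{bad.index.tolist()[:5]} (persons {bad['person_id'].tolist()[:5]})"
        )

    # Condition days must fall inside the person's observation period.
    if len(cond):
        merged = cond.merge(obs, on="person_id", how="left")
        outside = merged[
            merged["start_day"].isna()
            | (merged["day"] < merged["start_day"])
            | (merged["day"] > merged["end_day"])
        ]
        if len(outside):
            raise SchemaError(
                "condition_occurrence: day outside observation period for persons "
                f"{outside['person_id'].tolist()[:5]}"
            )

    # Birth years must be plausible.
    if len(person):
        max_year = date_from_day(int(obs["end_day"].max())).year if len(obs) else 2100
        bad_year = person[(person["birth_year"] < 1900) | (person["birth_year"] > max_year)]
        if len(bad_year):
            raise SchemaError(f"person.birth_year: out of range for {bad_year['person_id'].tolist()[:5]}")

    bundle = TableBundle(
        person=person.reset_index(drop=True),
        observation_period=obs[["person_id", "start_day", "end_day"]].reset_index(drop=True),
        condition_occurrence=cond[["person_id", "concept", "day"]].reset_index(drop=True),
        drug_exposure=drug[["person_id", "drug_class", "start_day", "end_day"]].reset_index(drop=True),
    )
    logger.info("validated bundle: %s", bundle.row_counts())
    return bundle


def read_tables(paths: dict[str, str | Path] | str | Path, config: RunConfig | None = None) -> TableBundle:
    """Read the four tables from explicit paths or a directory and validate.

    ``paths`` may be a mapping ``{table_name: path}`` or a directory holding
    ``<table>.csv`` / ``<table>.parquet`` files.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        mapping: dict[str, Path] = {}
        for name in TABLE_NAMES:
            for ext in (".csv", ".parquet"):
                cand = root / f"{name}{ext}"
                if cand.exists():
                    mapping[name] = cand
                    break
            else:
                raise SchemaError(f"no file for table {name!r} under {root}")
    else:
        mapping = {k: Path(v) for k, v in paths.items()}
        for name in TABLE_NAMES:
            if name not in mapping:
                raise SchemaError(f"missing path for table {name!r}")
            if not mapping[name].exists():
                raise FileNotFoundError(mapping[name])
    return validate_bundle({name: _read_one(p) for name, p in mapping.items()}, config)


def write_tables(bundle: TableBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to per-table CSVs with ISO dates (round-trippable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in TABLE_NAMES:
        frame = getattr(bundle, name).copy()
        for col in list(frame.columns):
            if col.endswith("_day") or col == "day":
                newcol = {"start_day": "start_date", "end_day": "end_date", "day": "date"}[col]
                frame[newcol] = frame[col].map(lambda d: date_from_day(d).isoformat())
                frame = frame.drop(columns=[col])
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path
    return written


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(obj: object):
    """Collapse numpy scalars to plain Python numbers for JSON output."""
    import numpy as np

    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_outputs(results: dict[str, object], out_dir: str | Path) -> pd.DataFrame:
    """Write pipeline result artefacts and return a checksum manifest.

    ``results`` maps file names to objects: DataFrames are written as CSV,
    strings as text, anything else as JSON.  Output is deterministic: rows
    are written in the order produced by the (seeded) pipeline and floats use
    pandas' default round-trip formatting, so identical results yield
    byte-identical files.
    """
    import json

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from None

    rows = []
    for name, obj in sorted(results.items()):
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        elif isinstance(obj, str):
            path.write_text(obj)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        rows.append({"file": name, "sha256": _sha256(path), "bytes": path.stat().st_size})
    manifest = pd.DataFrame(rows, columns=["file", "sha256", "bytes"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
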