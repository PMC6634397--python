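"""Reading and writing the cohort tables (CSV), notes (JSON Lines) and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import CohortTables

__all__ = [
    "write_tables",
    "read_tables",
    "write_notes_jsonl",
    "read_notes_jsonl",
    "write_manifest",
]

_TIME_COLS = {
    "encounters": ["admit_time", "discharge_time", "first_vital_time", "naloxone_time"],
    "uds": ["order_time"],
    "medications": ["event_time"],
}

_TABLE_NAMES = ("encounters", "uds", "medications", "diagnoses", "tract", "ground_truth")


def write_tables(tables: CohortTables, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in _TABLE_NAMES:
        path = outdir / f"{name}.csv"
        getattr(tables, name).to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(indir: str | Path) -> CohortTables:
    indir = Path(indir)
    frames = {}
    for name in _TABLE_NAMES:
        df = pd.read_csv(indir / f"{name}.csv")
        for col in _TIME_COLS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        frames[name] = df
    gt = frames["ground_truth"]
    if len(gt):
        gt["true_misuse"] = gt["true_misuse"].astype(bool)
        gt["true_class"] = gt["true_class"].astype("Int64")
    return CohortTables(**frames)


def write_notes_jsonl(notes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in notes.iterrows():
            fh.write(json.dumps({
                "note_id": int(row["note_id"]),
                "encounter_id": int(row["encounter_id"]),
                "concept_counts": {k: int(v) for k, v in row["concept_counts"].items()},
            }) + "\n")


def read_notes_jsonl(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return pd.DataFrame(rows, columns=["note_id", "encounter_id", "concept_counts"])


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
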