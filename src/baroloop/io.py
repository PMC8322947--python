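"""Reading and writing the tilt-study table schema and report JSON.

The on-disk schema is a delimited text table (CSV by default) with a
required header::

    subject_id,condition,angle_deg,ap_mmHg,hr_bpm,pne_pg_ml

``condition`` is ``baseline`` or ``blockade``; ``angle_deg`` is signed
(head-down negative); ``hr_bpm`` may be empty, ``ap_mmHg`` and
``pne_pg_ml`` may not.  Pressures are assumed referenced to clavicle /
baroreceptor level; that convention is recorded in the provenance sidecar
rather than corrected for.

Numeric columns round-trip at full ``repr`` precision, so a write-then-read
of any generated dataset is lossless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .estimation import BASELINE, BLOCKADE, MeasurementRow, SubjectRecord
from .exceptions import SchemaError
from .synthetic import CohortConfig, StudyDataset

REQUIRED_COLUMNS = ("subject_id", "condition", "angle_deg", "ap_mmHg", "pne_pg_ml")
OPTIONAL_COLUMNS = ("hr_bpm",)
AP_REFERENCE = "clavicle (baroreceptor level); no hydrostatic correction applied"


def subjects_to_frame(subjects: tuple[SubjectRecord, ...] | list[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "condition": r.condition,
            "angle_deg": r.angle_deg,
            "ap_mmHg": r.ap,
            "hr_bpm": r.hr,
            "pne_pg_ml": r.pne,
        }
        for s in subjects
        for r in s.rows
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[:3]) + ["ap_mmHg", "hr_bpm", "pne_pg_ml"])


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    subjects = []
    for sid, group in df.groupby("subject_id", sort=False):
        rows = []
        for idx, row in group.iterrows():
            for col in ("ap_mmHg", "pne_pg_ml", "angle_deg"):
                if pd.isna(row[col]):
                    raise SchemaError(f"row {idx}: column {col!r} is empty")
            condition = str(row["condition"])
            if condition not in (BASELINE, BLOCKADE):
                raise SchemaError(
                    f"row {idx}: condition must be '{BASELINE}' or '{BLOCKADE}', "
                    f"got {condition!r}"
                )
            hr = row.get("hr_bpm")
            rows.append(
                MeasurementRow(
                    condition=condition,
                    angle_deg=float(row["angle_deg"]),
                    ap=float(row["ap_mmHg"]),
                    pne=float(row["pne_pg_ml"]),
                    hr=None if hr is None or pd.isna(hr) else float(hr),
                )
            )
        subjects.append(SubjectRecord(subject_id=str(sid), rows=tuple(rows)))
    return subjects


def write_study_table(dataset: StudyDataset, path: str | Path, sep: str = ",") -> Path:
    """Write a simulated dataset as a study table plus a YAML provenance sidecar."""
    path = Path(path)
    df = subjects_to_frame(dataset.subjects)
    # shortest-roundtrip repr for floats so write-then-read is lossless
    # (pandas' own float formatting rounds the 17th significant digit)
    for col in ("angle_deg", "ap_mmHg", "hr_bpm", "pne_pg_ml"):
        df[col] = df[col].map(lambda v: "" if v is None else repr(float(v)))
    df.to_csv(path, sep=sep, index=False)
    sidecar = {
        "generator_version": dataset.generator_version,
        "seed": dataset.config.seed,
        "ap_reference": AP_REFERENCE,
        "config": dataset.config.model_dump(mode="json"),
    }
    sidecar_path = path.with_suffix(path.suffix + ".provenance.yaml")
    sidecar_path.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def read_study_table(path: str | Path, sep: str = ",") -> list[SubjectRecord]:
    """Read a study table, validating the schema row by row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise SchemaError(f"cannot parse {path}: {err}") from err
    return frame_to_subjects(df)


def read_sidecar_config(path: str | Path) -> CohortConfig:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".provenance.yaml")
    payload = yaml.safe_load(sidecar_path.read_text())
    return CohortConfig.model_validate(payload["config"])


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return {"flag": "non-finite", "repr": repr(obj)}
    return obj


def write_report_json(report: dict[str, Any], path: str | Path) -> Path:
    """Serialize a report dictionary (dataclasses allowed) to pretty JSON.

    Values are stored at full precision; rounding is a presentation-layer
    concern.  Non-finite floats are flagged explicitly rather than emitted
    as bare NaN, keeping the JSON standard-conformant.
    """
    path = Path(path)
    path.write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
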