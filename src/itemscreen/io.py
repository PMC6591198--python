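"""Readers and writers for the pipeline's file formats.

All formats are plain text:

* ``responses.csv`` — header ``patient_id,<item_id>,...``; integer cells,
  empty cell = missing response (never a sentinel number).
* debriefing files — ``flags.csv`` (long: patient_id,item_id,flag with
  flag in {upsetting, difficult, priority}), ``times.csv``
  (patient_id,completion_minutes) and ``issues.csv``
  (patient_id,issue_label).
* ``questionnaire.yaml`` — item metadata including reverse_coded markers.
* ``scales.yaml`` — scale name -> list of item ids.
* ``thresholds.yaml`` — overrides of the default criterion thresholds.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .types import (
    CriteriaThresholds,
    DebriefRecord,
    ItemMetadata,
    ResponseMatrix,
    ScaleDefinition,
    ValidationError,
    build_items,
)

__all__ = [
    "read_responses",
    "write_responses",
    "read_questionnaire",
    "write_questionnaire",
    "read_debrief",
    "write_debrief",
    "read_scales",
    "read_thresholds",
]

_FLAG_ATTR = {
    "upsetting": "upsetting_items",
    "difficult": "difficult_items",
    "priority": "priority_items",
}


def read_questionnaire(path: str | Path) -> dict[str, ItemMetadata]:
    """Load item metadata from YAML (``items:`` list of mappings)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "items" not in doc:
        raise ValidationError(f"{path}: expected a mapping with an 'items' list")
    metas = []
    for entry in doc["items"]:
        if isinstance(entry, str):
            entry = {"item_id": entry}
        metas.append(ItemMetadata(
            item_id=str(entry["item_id"]),
            wording=str(entry.get("wording", "")),
            reverse_coded=bool(entry.get("reverse_coded", False)),
            response_min=int(entry.get("response_min", 1)),
            response_max=int(entry.get("response_max", 4)),
        ))
    return build_items(metas)


def write_questionnaire(items: dict[str, ItemMetadata], path: str | Path) -> None:
    doc = {"items": [
        {
            "item_id": m.item_id,
            "wording": m.wording,
            "reverse_coded": m.reverse_coded,
            "response_min": m.response_min,
            "response_max": m.response_max,
        }
        for m in items.values()
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_responses(path: str | Path,
                   items: dict[str, ItemMetadata]) -> ResponseMatrix:
    """Parse a responses CSV into a validated ResponseMatrix.

    Rejects out-of-range cells (naming the offending item and patients)
    and header columns absent from the questionnaire metadata.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    if "patient_id" not in df.columns:
        raise ValidationError(f"{path}: first column must be patient_id")
    df = df.set_index("patient_id")
    unknown = sorted(set(df.columns) - set(items))
    if unknown:
        raise ValidationError(f"{path}: unknown item columns {unknown}")
    return ResponseMatrix(df, items)


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a responses CSV; missing responses become empty cells."""
    out = matrix.data.copy()
    # integer cells, empty for missing
    text = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    text.index.name = "patient_id"
    text.to_csv(path)


def read_debrief(directory: str | Path,
                 items: dict[str, ItemMetadata],
                 patient_ids: Sequence[str] | None = None) -> list[DebriefRecord]:
    """Assemble DebriefRecords from flags.csv / times.csv / issues.csv.

    Any of the three files may be absent; patients appearing in none of
    them (but listed in ``patient_ids``) get an empty record, so the
    cohort denominator is preserved.
    """
    directory = Path(directory)
    flags: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    times: dict[str, float] = {}
    issues: dict[str, list[str]] = defaultdict(list)

    flag_path = directory / "flags.csv"
    if flag_path.exists():
        with open(flag_path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                flag = row["flag"].strip()
                if flag not in _FLAG_ATTR:
                    raise ValidationError(
                        f"{flag_path} row {i + 2}: unknown flag {flag!r}")
                flags[row["patient_id"]][flag].add(row["item_id"])
    times_path = directory / "times.csv"
    if times_path.exists():
        with open(times_path, newline="") as fh:
            for row in csv.DictReader(fh):
                cell = row["completion_minutes"].strip()
                if cell:
                    times[row["patient_id"]] = float(cell)
    issues_path = directory / "issues.csv"
    if issues_path.exists():
        with open(issues_path, newline="") as fh:
            for row in csv.DictReader(fh):
                issues[row["patient_id"]].append(row["issue_label"].strip())

    pids = list(patient_ids) if patient_ids is not None else sorted(
        set(flags) | set(times) | set(issues))
    records = []
    for pid in pids:
        rec = DebriefRecord(
            patient_id=pid,
            completion_minutes=times.get(pid),
            upsetting_items=frozenset(flags[pid]["upsetting"]),
            difficult_items=frozenset(flags[pid]["difficult"]),
            priority_items=frozenset(flags[pid]["priority"]),
            missing_issues=tuple(issues.get(pid, ())),
        )
        rec.validate_against(items)
        records.append(rec)
    return records


def write_debrief(records: Sequence[DebriefRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "flags.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "item_id", "flag"])
        for rec in records:
            for flag, attr in _FLAG_ATTR.items():
                for item_id in sorted(getattr(rec, attr)):
                    w.writerow([rec.patient_id, item_id, flag])
    with open(directory / "times.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "completion_minutes"])
        for rec in records:
            t = "" if rec.completion_minutes is None else rec.completion_minutes
            w.writerow([rec.patient_id, t])
    with open(directory / "issues.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "issue_label"])
        for rec in records:
            for label in rec.missing_issues:
                w.writerow([rec.patient_id, label])


def read_scales(path: str | Path,
                items: dict[str, ItemMetadata] | None = None) -> list[ScaleDefinition]:
    """Load hypothesised scale memberships (name -> item id list)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected mapping of scale name -> items")
    scales = [ScaleDefinition(name, tuple(ids)) for name, ids in doc.items()]
    if items is not None:
        for sc in scales:
            unknown = set(sc.item_ids) - set(items)
            if unknown:
                raise ValidationError(
                    f"scale {sc.name}: unknown item(s) {sorted(unknown)}")
    return scales


def read_thresholds(path: str | Path) -> CriteriaThresholds:
    """Load criterion-threshold overrides; absent keys keep defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    valid = set(CriteriaThresholds.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ValidationError(f"{path}: unknown threshold key(s) {sorted(unknown)}")
    return CriteriaThresholds(**doc)
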