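"""Recoding and per-item descriptive statistics.

Conventions (forced by the arithmetic of the published per-item table):

* Category fractions (share scoring 1-2, share scoring 3-4) and every
  debriefing fraction use the **enrolled cohort size** as denominator,
  so frac_low + frac_high equals the completion rate identically and a
  missing response counts in neither category.
* The item mean and observed range use **only non-missing responses**
  (a cohort-denominator mean would drop below the scale minimum for
  low-compliance items).
* Fractions are kept at full precision; rounding to two decimals
  happens only at report rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    DebriefRecord,
    ItemMetadata,
    ItemStatistics,
    ResponseMatrix,
    ValidationError,
)

__all__ = [
    "recode_reverse",
    "compute_item_stats",
    "completion_time_summary",
    "cohort_summary",
    "TimeSummary",
]


def recode_reverse(matrix: ResponseMatrix) -> ResponseMatrix:
    """Recode reverse-coded items so higher always means more problems.

    A non-missing response x on a reverse-coded item becomes
    (response_min + response_max) - x, i.e. 5 - x on a 1-4 scale;
    missing cells and all other items are untouched. Applying the
    operation twice restores the original matrix.
    """
    data = matrix.data.copy()
    for item_id, meta in matrix.items.items():
        if meta.reverse_coded:
            data[item_id] = (meta.response_min + meta.response_max) - data[item_id]
    return ResponseMatrix(data, dict(matrix.items))


def _debrief_fractions(debrief: Sequence[DebriefRecord],
                       item_id: str, n: int) -> tuple[float, float, float]:
    if n == 0:
        return 0.0, 0.0, 0.0
    ups = sum(item_id in r.upsetting_items for r in debrief)
    dif = sum(item_id in r.difficult_items for r in debrief)
    pri = sum(item_id in r.priority_items for r in debrief)
    return ups / n, dif / n, pri / n


def compute_item_stats(matrix: ResponseMatrix,
                       debrief: Sequence[DebriefRecord] = (),
                       ) -> list[ItemStatistics]:
    """Per-item descriptives over the enrolled cohort.

    Expects reverse-coded items to have been recoded already.  An item
    with zero non-missing responses is emitted with mean and range
    undefined (None) and completion 0 rather than raising, so screening
    completes on arbitrary cohorts.
    """
    n = matrix.n_patients
    if n < 1:
        raise ValidationError("empty cohort")
    seen = set()
    for rec in debrief:
        if rec.patient_id in seen:
            raise ValidationError(f"duplicate debrief record for {rec.patient_id}")
        seen.add(rec.patient_id)
        rec.validate_against(matrix.item_ids)

    out = []
    for item_id in matrix.item_ids:
        col = matrix.data[item_id]
        obs = col.dropna()
        meta = matrix.items[item_id]
        # low half: 1-2 on a 1-4 scale; the halves partition the
        # completers, so completion is their sum by construction and
        # frac_low + frac_high == completion holds exactly in floats
        half = (meta.response_min + meta.response_max) // 2
        frac_low = float((obs <= half).sum()) / n
        frac_high = float((obs > half).sum()) / n
        ups, dif, pri = _debrief_fractions(debrief, item_id, n)
        if len(obs) == 0:
            stat = ItemStatistics(item_id, None, None, None,
                                  0.0, 0.0, 0.0, ups, dif, pri)
        else:
            stat = ItemStatistics(
                item_id=item_id,
                mean=float(obs.mean()),
                observed_min=int(obs.min()),
                observed_max=int(obs.max()),
                frac_low=frac_low,
                frac_high=frac_high,
                completion=frac_low + frac_high,
                frac_upsetting=ups,
                frac_difficult=dif,
                frac_priority=pri,
            )
        out.append(stat)
    return out


@dataclass(frozen=True)
class TimeSummary:
    median: float
    mean: float
    min: float
    max: float
    n: int


def completion_time_summary(debrief: Sequence[DebriefRecord]) -> TimeSummary:
    """Median/mean/range of questionnaire completion time in minutes.

    The median of an even count is the midpoint of the two central
    values. Raises if no record carries a time.
    """
    times = [r.completion_minutes for r in debrief
             if r.completion_minutes is not None]
    if not times:
        raise ValidationError("no completion times recorded")
    arr = np.asarray(times, dtype=float)
    return TimeSummary(
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        min=float(arr.min()),
        max=float(arr.max()),
        n=len(arr),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cohort_summary(clinical: pd.DataFrame,
                   categorical: Sequence[str] = (),
                   numeric: Sequence[str] = (),
                   vocab: Mapping[str, Sequence[str]] | None = None,
                   ) -> dict[str, pd.DataFrame]:
    """Cohort characteristics table: counts with integer percentages for
    categorical fields, median/mean/range for numeric fields.

    Percentages round half away from zero to the nearest integer
    (21 of 48 -> 44%). ``vocab`` optionally declares the admissible
    categories per field; an observed value outside it is an error.
    """
    n = len(clinical)
    if n == 0:
        raise ValidationError("empty clinical table")
    out: dict[str, pd.DataFrame] = {}
    cat_rows = []
    for field in categorical:
        counts = clinical[field].value_counts()
        levels = list(vocab[field]) if vocab and field in vocab else list(counts.index)
        if vocab and field in vocab:
            unknown = set(counts.index) - set(levels)
            if unknown:
                raise ValidationError(
                    f"{field}: unknown categor{'y' if len(unknown)==1 else 'ies'} "
                    f"{sorted(unknown)}")
        for level in levels:
            c = int(counts.get(level, 0))
            cat_rows.append({"field": field, "category": level,
                             "n": c, "percent": _round_half_away(100.0 * c / n)})
    if cat_rows:
        out["categorical"] = pd.DataFrame(cat_rows)
    num_rows = []
    for field in numeric:
        vals = clinical[field].dropna().astype(float)
        num_rows.append({
            "field": field,
            "median": float(vals.median()),
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
        })
    if num_rows:
        out["numeric"] = pd.DataFrame(num_rows)
    return out
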