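"""End-to-end orchestration and tabular report rendering.

The report mirrors the published per-item table's column order:
mean | crit1 | frac_high | crit2 | frac_low | crit3 | range | crit4 |
upsetting | crit5 | difficult | crit6 | compliance | crit7 |
priority | crit8 | overall | decision, plus a Total row of the
per-criterion counts. Fractions are carried at full precision
internally and rounded to two decimals only when rendered; the CSV
rendering additionally carries the full-precision values in mirror
columns (suffix ``_full``).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .criteria import (
    FlagTotals,
    MissingIssue,
    RosterReport,
    apply_group_decisions,
    evaluate_criteria,
    missing_issue_screen,
    tabulate_flags,
)
from .reliability import ScaleReliability, scale_report
from .stats import TimeSummary, completion_time_summary, compute_item_stats, recode_reverse
from .types import (
    CriteriaThresholds,
    CriterionFlags,
    DebriefRecord,
    GroupDecision,
    ItemStatistics,
    ResponseMatrix,
    ScaleDefinition,
    ValidationError,
)

__all__ = ["run_pipeline", "render_table", "PipelineBundle"]

_NUM_COLS = ["mean", "frac_high", "frac_low", "frac_upsetting",
             "frac_difficult", "completion", "frac_priority"]


@dataclass
class PipelineBundle:
    """Everything one pipeline run computes."""

    stats: list[ItemStatistics]
    flags: list[CriterionFlags]
    totals: FlagTotals
    missing_issues: list[MissingIssue]
    time_summary: TimeSummary | None
    alphas: list[ScaleReliability] | None
    roster: RosterReport | None
    provenance: dict

    @property
    def degenerate_items(self) -> list[str]:
        return [f.item_id for f in self.flags if f.degenerate]


def run_pipeline(matrix: ResponseMatrix,
                 debrief: Sequence[DebriefRecord] = (),
                 thresholds: CriteriaThresholds = CriteriaThresholds(),
                 scales: Sequence[ScaleDefinition] | None = None,
                 decisions: Sequence[GroupDecision] | None = None,
                 ) -> PipelineBundle:
    """Recode -> per-item stats -> criteria -> (alpha) -> report bundle.

    The scale-reliability and decision-bookkeeping stages run only when
    scale definitions / recorded decisions are supplied. Identical
    inputs produce identical bundles.
    """
    recoded = recode_reverse(matrix)
    stats = compute_item_stats(recoded, debrief)
    flags = [evaluate_criteria(s, thresholds,
                               matrix.items[s.item_id].response_min,
                               matrix.items[s.item_id].response_max)
             for s in stats]
    totals = tabulate_flags(flags)
    issues = missing_issue_screen(debrief, thresholds)
    times = None
    if any(r.completion_minutes is not None for r in debrief):
        times = completion_time_summary(debrief)
    alphas = scale_report(recoded, scales) if scales else None
    roster = apply_group_decisions(flags, decisions) if decisions else None
    provenance = {
        "n_patients": matrix.n_patients,
        "n_items": len(matrix.item_ids),
        "thresholds": {k: getattr(thresholds, k)
                       for k in thresholds.__dataclass_fields__},
        "responses_sha256": _digest_matrix(matrix),
    }
    return PipelineBundle(stats, flags, totals, issues, times,
                          alphas, roster, provenance)


def _digest_matrix(matrix: ResponseMatrix) -> str:
    buf = _io.StringIO()
    matrix.data.to_csv(buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def _report_frame(stats: Sequence[ItemStatistics],
                  flags: Sequence[CriterionFlags],
                  decisions: Sequence[GroupDecision] | None) -> pd.DataFrame:
    fmap = {f.item_id: f for f in flags}
    if set(fmap) != {s.item_id for s in stats}:
        raise ValidationError("stats and flags cover different item sets")
    dmap = {}
    if decisions is not None:
        dmap = {d.item_id: d for d in decisions}
        if not set(fmap) <= set(dmap):
            raise ValidationError("decisions missing for some items")
    rows = []
    for s in stats:
        f = fmap[s.item_id]
        rng = ("" if s.degenerate
               else f"{s.observed_min} to {s.observed_max}")
        d = dmap.get(s.item_id)
        rows.append({
            "item_id": s.item_id,
            "mean": s.mean,
            "c1": int(f.c1),
            "frac_high": s.frac_high,
            "c2": int(f.c2),
            "frac_low": s.frac_low,
            "c3": int(f.c3),
            "range": rng,
            "c4": int(f.c4),
            "frac_upsetting": s.frac_upsetting,
            "c5": int(f.c5),
            "frac_difficult": s.frac_difficult,
            "c6": int(f.c6),
            "completion": s.completion,
            "c7": int(f.c7),
            "frac_priority": s.frac_priority,
            "c8": int(f.c8),
            "overall": int(f.screen_keep),
            "decision": d.action if d else "",
            "status": ("retained" if d and d.action != "DELETE" else
                       "removed" if d else ""),
        })
    return pd.DataFrame(rows)


def render_table(stats: Sequence[ItemStatistics],
                 flags: Sequence[CriterionFlags],
                 decisions: Sequence[GroupDecision] | None = None,
                 fmt: str = "csv") -> str:
    """Render the per-item report with its totals row as csv or markdown.

    Both formats show the same rounded (2-decimal) numeric content; the
    CSV additionally mirrors the unrounded fractions in ``*_full``
    columns.
    """
    if fmt not in ("csv", "markdown"):
        raise ValidationError(f"unknown format {fmt!r}")
    frame = _report_frame(stats, flags, decisions)
    totals = tabulate_flags(flags)
    rounded = frame.copy()
    for col in _NUM_COLS:
        rounded[col] = rounded[col].map(
            lambda v: "" if pd.isna(v) else f"{v:.2f}")
    total_row = {c: "" for c in rounded.columns}
    total_row.update({"item_id": "Total",
                      **{f"c{i}": getattr(totals, f"c{i}") for i in range(1, 9)},
                      "overall": totals.overall})
    rounded = pd.concat([rounded, pd.DataFrame([total_row])], ignore_index=True)

    if fmt == "markdown":
        cols = list(rounded.columns)
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "|".join("---" for _ in cols) + "|"]
        for _, row in rounded.iterrows():
            lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
        return "\n".join(lines) + "\n"

    for col in _NUM_COLS:  # full-precision mirror columns
        full = list(frame[col]) + [""]
        rounded[col + "_full"] = [
            "" if isinstance(v, str) or pd.isna(v) else repr(float(v))
            for v in full]
    buf = _io.StringIO()
    rounded.to_csv(buf, index=False)
    return buf.getvalue()


def write_provenance(bundle: PipelineBundle, path: str | Path,
                     extra: dict | None = None) -> None:
    """Write the run's provenance record (thresholds, sizes, digests)."""
    doc = dict(bundle.provenance)
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
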