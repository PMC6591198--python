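"""The eight a-priori retention criteria and decision bookkeeping.

An item is screened as *keep* when at least five of criteria 1-7 hold,
or criterion 8 holds:

1. relevance — mean > 1.5 on the 1-4 scale
2. relevance — more than 50% of the cohort score 3 or 4
3. no floor/ceiling — more than 10% score 1-2 AND more than 10% score 3-4
4. range — observed responses span the full scale
5. acceptability — fewer than 5% found the item upsetting
6. easiness — fewer than 5% found it difficult to understand
7. compliance — more than 95% completed the item
8. priority — at least 2% named the item especially relevant

Inequality strictness follows the published rule verbatim: strict for
criteria 1-7, non-strict (>=) for criterion 8 only.

The engine never deletes anything itself: it emits a screening verdict
per item, and the final roster comes from recorded expert-panel
decisions, which may legitimately override the screen.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import (
    CriteriaThresholds,
    CriterionFlags,
    DebriefRecord,
    GroupDecision,
    ItemStatistics,
    ValidationError,
)

__all__ = [
    "evaluate_criteria",
    "screen_decision",
    "tabulate_flags",
    "missing_issue_screen",
    "apply_group_decisions",
    "FlagTotals",
    "MissingIssue",
    "RosterReport",
]


def evaluate_criteria(stats: ItemStatistics,
                      thresholds: CriteriaThresholds = CriteriaThresholds(),
                      response_min: int = 1,
                      response_max: int = 4) -> CriterionFlags:
    """Evaluate the eight criteria for one item.

    A degenerate item (zero completion: mean and range undefined) fails
    criteria 1-4 rather than raising, and is flagged as degenerate.
    """
    t = thresholds
    degenerate = stats.degenerate
    if degenerate:
        c1 = c2 = c3 = c4 = False
    else:
        c1 = stats.mean > t.mean_floor
        c2 = stats.frac_high > t.high_majority
        c3 = (stats.frac_low > t.floor_ceiling) and (stats.frac_high > t.floor_ceiling)
        c4 = (stats.observed_min == response_min
              and stats.observed_max == response_max)
    c5 = stats.frac_upsetting < t.upsetting_max
    c6 = stats.frac_difficult < t.difficult_max
    c7 = stats.completion > t.compliance_min
    c8 = stats.frac_priority >= t.priority_min
    keep = (sum((c1, c2, c3, c4, c5, c6, c7)) >= t.keep_count) or c8
    return CriterionFlags(stats.item_id, c1, c2, c3, c4, c5, c6, c7, c8,
                          screen_keep=keep, keep_count=t.keep_count,
                          degenerate=degenerate)


def screen_decision(flags: CriterionFlags,
                    thresholds: CriteriaThresholds = CriteriaThresholds()) -> bool:
    """The keep rule: at least keep_count of criteria 1-7, or criterion 8."""
    return (sum(flags.first_seven()) >= thresholds.keep_count) or flags.c8


@dataclass(frozen=True)
class FlagTotals:
    """Per-criterion pass counts plus the overall keep-rule count."""

    c1: int
    c2: int
    c3: int
    c4: int
    c5: int
    c6: int
    c7: int
    c8: int
    overall: int
    n_items: int

    def as_tuple(self) -> tuple[int, ...]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5,
                self.c6, self.c7, self.c8, self.overall)


def tabulate_flags(flags: Iterable[CriterionFlags]) -> FlagTotals:
    """Column totals of a flag table (the printed table's Total row)."""
    flags = list(flags)
    ids = [f.item_id for f in flags]
    dup = [i for i, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValidationError(f"duplicate item ids in flag table: {sorted(dup)}")
    counts = [0] * 8
    overall = 0
    for f in flags:
        for k, v in enumerate(f.as_tuple()):
            counts[k] += bool(v)
        overall += bool(f.screen_keep)
    return FlagTotals(*counts, overall=overall, n_items=len(flags))


@dataclass(frozen=True)
class MissingIssue:
    label: str
    n_patients: int
    add: bool


def missing_issue_screen(debrief: Sequence[DebriefRecord],
                         thresholds: CriteriaThresholds = CriteriaThresholds(),
                         ) -> list[MissingIssue]:
    """Screen debriefing 'missing issue' mentions for additions.

    Counts *distinct patients* per canonical issue label; a label is
    marked for addition when at least ``missing_issue_min_patients``
    patients mentioned it. Sorted by descending count then label.
    """
    patients_per_label: dict[str, set[str]] = {}
    for rec in debrief:
        for label in set(rec.missing_issues):
            patients_per_label.setdefault(label, set()).add(rec.patient_id)
    out = [
        MissingIssue(label, len(pids),
                     add=len(pids) >= thresholds.missing_issue_min_patients)
        for label, pids in patients_per_label.items()
    ]
    out.sort(key=lambda m: (-m.n_patients, m.label))
    return out


@dataclass(frozen=True)
class RosterReport:
    """Outcome of applying recorded expert decisions to the item set."""

    final_item_count: int
    n_keep: int
    n_delete: int
    n_change: int
    n_expand: int
    #: items where the expert action disagrees with the screening verdict
    #: (kept/changed/expanded despite screen-drop, or deleted despite
    #: screen-keep); overrides are legitimate, this is bookkeeping.
    discordant: tuple[str, ...]


def apply_group_decisions(flags: Sequence[CriterionFlags],
                          decisions: Sequence[GroupDecision]) -> RosterReport:
    """Apply expert decisions: final roster size and screen concordance.

    Requires exactly one decision per flagged item. The final roster
    size is the sum of each decision's resulting item count (1 for
    KEEP/CHANGE, 0 for DELETE, >= 2 for EXPAND).
    """
    by_item = {}
    for d in decisions:
        if d.item_id in by_item:
            raise ValidationError(f"duplicate decision for {d.item_id}")
        by_item[d.item_id] = d
    flag_ids = [f.item_id for f in flags]
    if set(by_item) != set(flag_ids) or len(flag_ids) != len(set(flag_ids)):
        missing = sorted(set(flag_ids) - set(by_item))
        extra = sorted(set(by_item) - set(flag_ids))
        raise ValidationError(
            f"decisions do not match items: missing {missing}, extra {extra}")

    actions = Counter(d.action for d in decisions)
    discordant = []
    for f in flags:
        retained = by_item[f.item_id].action != "DELETE"
        if retained != f.screen_keep:
            discordant.append(f.item_id)
    return RosterReport(
        final_item_count=sum(d.resulting_item_count for d in decisions),
        n_keep=actions.get("KEEP", 0),
        n_delete=actions.get("DELETE", 0),
        n_change=actions.get("CHANGE", 0),
        n_expand=actions.get("EXPAND", 0),
        discordant=tuple(sorted(discordant)),
    )
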