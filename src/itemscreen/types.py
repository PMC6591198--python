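"""Domain types for Likert questionnaire item analysis.

The pipeline works on four-point Likert responses (1 "not at all" to
4 "very much") from a small enrolled cohort, plus structured debriefing
records collected after completion (whether each item was upsetting,
difficult to understand, or especially relevant, how long completion
took, and whether anything was felt to be missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemMetadata",
    "ResponseMatrix",
    "DebriefRecord",
    "ItemStatistics",
    "CriteriaThresholds",
    "CriterionFlags",
    "ScaleDefinition",
    "GroupDecision",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass(frozen=True)
class ItemMetadata:
    """A single questionnaire item.

    Reverse-coded items are worded so that a high raw response means
    *fewer* problems; the pipeline recodes them to the common
    higher-is-worse orientation before any statistics are computed.
    """

    item_id: str
    wording: str = ""
    reverse_coded: bool = False
    response_min: int = 1
    response_max: int = 4

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValidationError(
                f"{self.item_id}: response_min must be < response_max "
                f"({self.response_min} >= {self.response_max})"
            )


@dataclass
class ResponseMatrix:
    """Patients x items ordinal responses with missing entries.

    Backed by a float DataFrame (index: patient ids, columns: item ids)
    where NaN marks a missing response. Cells are validated against each
    item's declared response range on construction.
    """

    data: pd.DataFrame
    items: dict[str, ItemMetadata]

    def __post_init__(self) -> None:
        if set(self.data.columns) != set(self.items):
            unknown = sorted(set(self.data.columns) - set(self.items))
            missing = sorted(set(self.items) - set(self.data.columns))
            raise ValidationError(
                f"column set mismatch: unknown columns {unknown}, "
                f"absent columns {missing}"
            )
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate patient ids")
        self.data = self.data.astype(float)
        for item_id, meta in self.items.items():
            col = self.data[item_id]
            obs = col.dropna()
            if ((obs < meta.response_min) | (obs > meta.response_max)).any():
                bad = obs[(obs < meta.response_min) | (obs > meta.response_max)]
                raise ValidationError(
                    f"item {item_id}: value(s) {sorted(set(bad))} outside "
                    f"[{meta.response_min}, {meta.response_max}] "
                    f"(patients {list(bad.index)})"
                )
            if (obs != obs.round()).any():
                raise ValidationError(f"item {item_id}: non-integer responses")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.data.copy(), dict(self.items))


@dataclass
class DebriefRecord:
    """One patient's structured debriefing interview.

    ``missing_issues`` holds canonical issue labels (free text is mapped
    to labels upstream, by hand); a patient may mention a label more
    than once, but the missing-issue rule counts distinct patients.
    """

    patient_id: str
    completion_minutes: float | None = None
    upsetting_items: frozenset[str] = frozenset()
    difficult_items: frozenset[str] = frozenset()
    priority_items: frozenset[str] = frozenset()
    missing_issues: tuple[str, ...] = ()

    def validate_against(self, item_ids: Iterable[str]) -> None:
        known = set(item_ids)
        for attr in ("upsetting_items", "difficult_items", "priority_items"):
            unknown = set(getattr(self, attr)) - known
            if unknown:
                raise ValidationError(
                    f"patient {self.patient_id}: {attr} references unknown "
                    f"item(s) {sorted(unknown)}"
                )
        if self.completion_minutes is not None and self.completion_minutes <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: non-positive completion time"
            )


@dataclass(frozen=True)
class ItemStatistics:
    """Per-item descriptives feeding the retention criteria.

    Category and debriefing fractions use the enrolled cohort size as
    denominator, so that frac_low + frac_high == completion holds
    identically (missing responses count in neither category). The mean
    and observed range use only non-missing responses; for an item with
    zero non-missing responses they are None and completion is 0.
    """

    item_id: str
    mean: float | None
    observed_min: int | None
    observed_max: int | None
    frac_low: float
    frac_high: float
    completion: float
    frac_upsetting: float
    frac_difficult: float
    frac_priority: float

    def __post_init__(self) -> None:
        for name in ("frac_low", "frac_high", "completion",
                     "frac_upsetting", "frac_difficult", "frac_priority"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.item_id}: {name}={v} outside [0, 1]")

    @property
    def degenerate(self) -> bool:
        return self.mean is None


@dataclass(frozen=True)
class CriteriaThresholds:
    """Thresholds of the eight a-priori retention criteria.

    Defaults are the published phase-III values: an item is screened as
    keep when at least ``keep_count`` of criteria 1-7 hold, or criterion
    8 (priority) holds. A missing issue is added to the questionnaire
    when at least ``missing_issue_min_patients`` distinct patients
    mention it.
    """

    mean_floor: float = 1.5
    high_majority: float = 0.50
    floor_ceiling: float = 0.10
    upsetting_max: float = 0.05
    difficult_max: float = 0.05
    compliance_min: float = 0.95
    priority_min: float = 0.02
    keep_count: int = 5
    missing_issue_min_patients: int = 5

    def __post_init__(self) -> None:
        for name in ("high_majority", "floor_ceiling", "upsetting_max",
                     "difficult_max", "compliance_min", "priority_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1)")
        if not 1 <= self.keep_count <= 7:
            raise ValidationError(f"keep_count={self.keep_count} outside 1..7")

    def replace(self, **kwargs) -> "CriteriaThresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CriterionFlags:
    """The eight criterion booleans plus the screening verdict for one item.

    ``screen_keep`` must equal (sum(c1..c7) >= keep_count) or c8; the
    keep_count used is recorded so the invariant is self-contained.
    """

    item_id: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool
    c8: bool
    screen_keep: bool
    keep_count: int = 5
    degenerate: bool = False

    def __post_init__(self) -> None:
        expected = (sum(self.first_seven()) >= self.keep_count) or self.c8
        if self.screen_keep != expected:
            raise ValidationError(
                f"{self.item_id}: screen_keep={self.screen_keep} inconsistent "
                f"with flags {self.as_tuple()} at keep_count={self.keep_count}"
            )

    def first_seven(self) -> tuple[bool, ...]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6, self.c7)

    def as_tuple(self) -> tuple[bool, ...]:
        return self.first_seven() + (self.c8,)


_ACTIONS = ("KEEP", "DELETE", "CHANGE", "EXPAND")


@dataclass(frozen=True)
class ScaleDefinition:
    """A named hypothesised scale: a set of >= 2 items presumed to
    measure one construct (e.g. fatigue), defined before validation."""

    name: str
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.item_ids) < 2:
            raise ValidationError(f"scale {self.name}: needs >= 2 items")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError(f"scale {self.name}: duplicate item ids")


@dataclass(frozen=True)
class GroupDecision:
    """Recorded outcome of the expert panel for one item.

    KEEP and CHANGE leave one item in the final roster, DELETE none,
    EXPAND splits one item into two or more.
    """

    item_id: str
    action: str
    rationale: str = ""
    resulting_item_count: int | None = None

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValidationError(
                f"{self.item_id}: action {self.action!r} not in {_ACTIONS}"
            )
        default = {"KEEP": 1, "CHANGE": 1, "DELETE": 0, "EXPAND": 2}[self.action]
        count = default if self.resulting_item_count is None else self.resulting_item_count
        object.__setattr__(self, "resulting_item_count", count)
        ok = {
            "KEEP": count == 1,
            "CHANGE": count == 1,
            "DELETE": count == 0,
            "EXPAND": count >= 2,
        }[self.action]
        if not ok:
            raise ValidationError(
                f"{self.item_id}: resulting_item_count={count} inconsistent "
                f"with action {self.action}"
            )


def build_items(metadata: Sequence[ItemMetadata]) -> dict[str, ItemMetadata]:
    """Index metadata by item id, rejecting duplicates."""
    out: dict[str, ItemMetadata] = {}
    for meta in metadata:
        if meta.item_id in out:
            raise ValidationError(f"duplicate item id {meta.item_id}")
        out[meta.item_id] = meta
    return out
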