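"""Packaged per-item table of the published phase-III study.

The QLQ-AA/PNH development study administered 69 provisional items to
48 patients with aplastic anaemia and/or PNH and printed, for every
item, its mean, category fractions, debriefing fractions, compliance,
the eight criterion flags, the overall keep-rule column, and the expert
panel's decision with its rationale. That table is transcribed once
into ``data/phase3_item_table.csv`` and loaded here.

The printed flags are stored as data rather than recomputed, because
the fractions are rounded to two decimals and one row (s69, upsetting
fraction printed as 0.05 with criterion 5 passing) sits exactly on the
rounded 5% boundary where the unrounded value evidently fell below it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import CriterionFlags, GroupDecision, ItemStatistics, ValidationError

__all__ = ["load_phase3_item_table", "load_phase3_dataframe",
           "PHASE3_REVERSE_CODED", "PHASE3_N_PATIENTS", "PHASE3_N_ITEMS"]

#: items worded positively in the provisional questionnaire, recoded 5 - x
PHASE3_REVERSE_CODED = frozenset(
    {"s25", "s27", "s45", "s46", "s49", "s66", "s67", "s68"})
PHASE3_N_PATIENTS = 48
PHASE3_N_ITEMS = 69


def load_phase3_dataframe() -> pd.DataFrame:
    """The raw transcribed table as a DataFrame, one row per item."""
    ref = resources.files("itemscreen").joinpath("data/phase3_item_table.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return df


def load_phase3_item_table() -> tuple[
        list[ItemStatistics], list[CriterionFlags], list[GroupDecision]]:
    """Load the transcribed study table as typed records.

    Returns per-item statistics (printed two-decimal fractions), the
    printed criterion flags (with the printed overall column as the
    screening verdict), and the recorded expert decisions.

    Raises
    ------
    ValidationError
        If the packaged table does not contain exactly 69 rows or a row
        is internally inconsistent.
    """
    df = load_phase3_dataframe()
    if len(df) != PHASE3_N_ITEMS or df.item_id.duplicated().any():
        raise ValidationError(
            f"packaged item table corrupt: {len(df)} rows, expected "
            f"{PHASE3_N_ITEMS} unique items")

    stats, flags, decisions = [], [], []
    for row in df.itertuples(index=False):
        stats.append(ItemStatistics(
            item_id=row.item_id,
            mean=float(row.mean),
            observed_min=int(row.observed_min),
            observed_max=int(row.observed_max),
            frac_low=float(row.frac_low),
            frac_high=float(row.frac_high),
            completion=float(row.completion),
            frac_upsetting=float(row.frac_upsetting),
            frac_difficult=float(row.frac_difficult),
            frac_priority=float(row.frac_priority),
        ))
        flags.append(CriterionFlags(
            item_id=row.item_id,
            c1=bool(row.c1), c2=bool(row.c2), c3=bool(row.c3),
            c4=bool(row.c4), c5=bool(row.c5), c6=bool(row.c6),
            c7=bool(row.c7), c8=bool(row.c8),
            screen_keep=bool(row.overall),
        ))
        decisions.append(GroupDecision(
            item_id=row.item_id,
            action=row.action,
            rationale=row.rationale,
            resulting_item_count=int(row.resulting_item_count),
        ))
    return stats, flags, decisions
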