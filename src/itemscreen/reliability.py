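"""Internal consistency of hypothesised scales (Cronbach's alpha).

alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total score))

for a k-item scale, with variances taken over listwise-complete
patients using the sample (n-1) divisor. Equivalently, with S the
item covariance matrix, alpha = k/(k-1) * (1 - tr(S) / 1'S1); the
test suite pins the implementation to that closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ResponseMatrix, ScaleDefinition, ValidationError

__all__ = ["cronbach_alpha", "scale_report", "ScaleReliability"]

#: fewest listwise-complete patients for which alpha is reported
MIN_COMPLETE = 3


def _alpha_from_frame(frame: pd.DataFrame) -> float:
    """Alpha of a complete-case numeric frame; NaN if undefined."""
    n, k = frame.shape
    if n < MIN_COMPLETE:
        return math.nan
    total_var = frame.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return math.nan
    item_var = frame.var(ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def cronbach_alpha(matrix: ResponseMatrix | pd.DataFrame,
                   scale: ScaleDefinition,
                   missing_policy: str = "listwise") -> float:
    """Cronbach's alpha of one hypothesised scale.

    Accepts a ResponseMatrix (recode reverse-coded items first — alpha
    assumes all items point the same way) or a bare numeric DataFrame
    (e.g. continuous latent scores). Returns NaN when alpha is
    undefined: fewer than MIN_COMPLETE listwise-complete patients, or
    zero total-score variance.

    Raises
    ------
    ValidationError
        If the scale has fewer than 2 items, references unknown items,
        or ``missing_policy`` is not 'listwise'.
    """
    if missing_policy != "listwise":
        raise ValidationError(f"unsupported missing_policy {missing_policy!r}")
    data = matrix.data if isinstance(matrix, ResponseMatrix) else matrix
    unknown = set(scale.item_ids) - set(data.columns)
    if unknown:
        raise ValidationError(
            f"scale {scale.name}: unknown item(s) {sorted(unknown)}")
    frame = data[list(scale.item_ids)].dropna(axis=0, how="any").astype(float)
    return _alpha_from_frame(frame)


@dataclass(frozen=True)
class ScaleReliability:
    name: str
    k: int
    n_complete: int
    alpha: float  # NaN when undefined


def scale_report(matrix: ResponseMatrix | pd.DataFrame,
                 scales: Sequence[ScaleDefinition]) -> list[ScaleReliability]:
    """One reliability row per hypothesised scale.

    A scale whose alpha is undefined (e.g. all items missing for every
    patient) is reported with alpha NaN rather than aborting the table.
    """
    data = matrix.data if isinstance(matrix, ResponseMatrix) else matrix
    rows = []
    for sc in scales:
        frame = data[list(sc.item_ids)].dropna(axis=0, how="any").astype(float)
        rows.append(ScaleReliability(
            name=sc.name,
            k=len(sc.item_ids),
            n_complete=len(frame),
            alpha=_alpha_from_frame(frame),
        ))
    return rows
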