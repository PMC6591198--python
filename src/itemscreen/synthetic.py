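"""Synthetic cohorts with the structure the item analysis assumes.

Generative model
----------------
Each item belongs to exactly one hypothesised scale s. For patient p
and item i in scale s, a continuous standardised score is drawn as

    x_pi = mu_s + lambda_s * F_ps + sqrt(1 - lambda_s^2) * eps_pi

with F_ps (one factor per patient and scale) and eps_pi independent
standard normals, so the marginal of x_pi is N(mu_s, 1) and two items
of the same scale correlate r = lambda_s^2. The ordinal response is the
category of x_pi under the item's three strictly increasing cut points;
cells are then set missing completely at random with the item's
missingness probability. Reverse-coded items are *emitted on the
reversed scale*, so the analysis pipeline must recode them.

Debriefing flags (upsetting / difficult / priority) are independent
Bernoulli draws per patient-item, independent of the responses, which
keeps their rates analytically checkable. Completion times are
log-normal around a 10-minute median, clipped to 5-20 minutes.

All randomness flows through one NumPy Generator seeded explicitly;
the same seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    DebriefRecord,
    ItemMetadata,
    ResponseMatrix,
    ScaleDefinition,
    ValidationError,
    build_items,
)

__all__ = [
    "ScaleModel",
    "CohortConfig",
    "generate_cohort",
    "default_study_config",
    "category_probabilities",
    "expected_alpha",
]

#: default cut points: marginal category masses ~(0.23, 0.37, 0.30, 0.11),
#: item mean ~2.3 and frac_high ~0.40 at mu = 0 — a typical row of the
#: published per-item table
DEFAULT_CUTS = (-0.75, 0.25, 1.25)


@dataclass(frozen=True)
class ScaleModel:
    """One generating scale: its items, common loading, latent mean."""

    definition: ScaleDefinition
    loading: float = 0.7
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading < 1.0:
            raise ValidationError(
                f"scale {self.definition.name}: loading {self.loading} "
                "outside [0, 1)")


@dataclass
class CohortConfig:
    """Parameters of a synthetic phase-III-style cohort.

    Per-item mappings fall back to the scalar defaults for items they
    omit. Singleton scales are allowed via ``singletons`` (a
    ScaleDefinition requires >= 2 items; a singleton item is modelled
    as loading 0, i.e. pure noise around ``mu``).
    """

    n_patients: int = 48
    scales: Sequence[ScaleModel] = ()
    singletons: Sequence[str] = ()
    items: dict[str, ItemMetadata] | None = None
    cuts: Mapping[str, tuple[float, float, float]] | None = None
    default_cuts: tuple[float, float, float] = DEFAULT_CUTS
    missingness: Mapping[str, float] | None = None
    default_missingness: float = 0.03
    p_upsetting: float = 0.005
    p_difficult: float = 0.01
    p_priority: float = 0.01
    issue_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        owned = [i for m in self.scales for i in m.definition.item_ids]
        owned += list(self.singletons)
        if len(set(owned)) != len(owned):
            raise ValidationError("an item belongs to more than one scale")
        if not owned:
            raise ValidationError("config defines no items")
        if self.items is None:
            self.items = build_items([ItemMetadata(i) for i in owned])
        if set(self.items) != set(owned):
            raise ValidationError("items metadata does not match scale items")
        for item_id in owned:
            c = self.cuts_for(item_id)
            if not (c[0] < c[1] < c[2]):
                raise ValidationError(
                    f"item {item_id}: cut points {c} not strictly increasing")
            m = self.missingness_for(item_id)
            if not 0.0 <= m < 1.0:
                raise ValidationError(f"item {item_id}: missingness {m}")

    def cuts_for(self, item_id: str) -> tuple[float, float, float]:
        if self.cuts and item_id in self.cuts:
            return tuple(self.cuts[item_id])
        return self.default_cuts

    def missingness_for(self, item_id: str) -> float:
        if self.missingness and item_id in self.missingness:
            return self.missingness[item_id]
        return self.default_missingness

    @property
    def item_ids(self) -> list[str]:
        ids = [i for m in self.scales for i in m.definition.item_ids]
        return ids + list(self.singletons)


def generate_cohort(config: CohortConfig,
                    ) -> tuple[ResponseMatrix, list[DebriefRecord], pd.DataFrame]:
    """Draw one cohort: responses, debriefing records, latent scores.

    The third element is the continuous score matrix *before*
    discretization, reversal and missingness — the quantity whose
    inter-item correlation structure the reliability tests check.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    item_ids = config.item_ids
    patient_ids = [f"p{i + 1:03d}" for i in range(n)]

    latent = pd.DataFrame(index=patient_ids, columns=item_ids, dtype=float)
    groups = [(m.definition.item_ids, m.loading, m.mu) for m in config.scales]
    groups += [((i,), 0.0, 0.0) for i in config.singletons]
    for ids, lam, mu in groups:
        factor = rng.standard_normal(n)
        for item_id in ids:
            eps = rng.standard_normal(n)
            latent[item_id] = mu + lam * factor + math.sqrt(1 - lam * lam) * eps

    values = pd.DataFrame(index=patient_ids, columns=item_ids, dtype=float)
    for item_id in item_ids:
        cuts = np.asarray(config.cuts_for(item_id))
        cat = np.searchsorted(cuts, latent[item_id].to_numpy()) + 1
        meta = config.items[item_id]
        if meta.reverse_coded:
            cat = (meta.response_min + meta.response_max) - cat
        miss = rng.random(n) < config.missingness_for(item_id)
        col = cat.astype(float)
        col[miss] = np.nan
        values[item_id] = col
    matrix = ResponseMatrix(values, dict(config.items))

    # debriefing: independent flags, log-normal completion times
    minutes = np.clip(np.round(rng.lognormal(math.log(10.0), 0.25, n)), 5, 20)
    k = len(item_ids)
    ups_mat = rng.random((n, k)) < config.p_upsetting
    dif_mat = rng.random((n, k)) < config.p_difficult
    pri_mat = rng.random((n, k)) < config.p_priority
    labels = list(config.issue_rates)
    issue_mat = rng.random((n, len(labels))) < np.asarray(
        [config.issue_rates[l] for l in labels])
    records = []
    for p, pid in enumerate(patient_ids):
        ups = frozenset(i for i, hit in zip(item_ids, ups_mat[p]) if hit)
        dif = frozenset(i for i, hit in zip(item_ids, dif_mat[p]) if hit)
        pri = frozenset(i for i, hit in zip(item_ids, pri_mat[p]) if hit)
        issues = tuple(l for l, hit in zip(labels, issue_mat[p]) if hit)
        records.append(DebriefRecord(
            patient_id=pid,
            completion_minutes=float(minutes[p]),
            upsetting_items=ups,
            difficult_items=dif,
            priority_items=pri,
            missing_issues=issues,
        ))
    return matrix, records, latent


#: hypothesised-scale layout of the default synthetic study: the eleven
#: constructs named in the development study, with memberships assigned
#: here (the published report does not list them)
_DEFAULT_SCALE_SIZES = (
    ("fatigue", 9),
    ("infections", 4),
    ("other_symptoms", 7),
    ("physical_functioning", 7),
    ("role_functioning", 6),
    ("emotional_functioning", 8),
    ("fear_of_progression", 7),
    ("illness_intrusiveness", 8),
    ("stigmatisation", 6),
    ("body_image", 4),
    ("social_support", 3),
)

_REVERSE_CODED = frozenset(
    {"s25", "s27", "s45", "s46", "s49", "s66", "s67", "s68"})


def default_study_config(seed: int = 0, n_patients: int = 48,
                         loading: float = 0.7) -> CohortConfig:
    """The study-sized default: 48 patients, 69 four-point items in the
    eleven named hypothesised scales, eight reverse-coded items."""
    scales = []
    next_id = 1
    metas = []
    for name, size in _DEFAULT_SCALE_SIZES:
        ids = tuple(f"s{j:02d}" for j in range(next_id, next_id + size))
        next_id += size
        scales.append(ScaleModel(ScaleDefinition(name, ids), loading=loading))
        metas += [ItemMetadata(i, reverse_coded=i in _REVERSE_CODED) for i in ids]
    return CohortConfig(
        n_patients=n_patients,
        scales=scales,
        items=build_items(metas),
        seed=seed,
    )


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def category_probabilities(mu: float,
                           cuts: Sequence[float] = DEFAULT_CUTS,
                           ) -> tuple[float, ...]:
    """Exact marginal category masses implied by the generative model
    (the marginal continuous score is N(mu, 1) for any loading)."""
    cdf = [0.0] + [_phi(c - mu) for c in cuts] + [1.0]
    return tuple(cdf[j + 1] - cdf[j] for j in range(len(cuts) + 1))


def expected_alpha(k: int, loading: float) -> float:
    """Population alpha of k continuous items with common loading:
    k*r / (1 + (k-1)*r) with inter-item correlation r = loading^2."""
    r = loading * loading
    return k * r / (1.0 + (k - 1) * r)
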