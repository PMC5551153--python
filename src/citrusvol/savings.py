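"""Field-evaluation arithmetic: mix-volume reduction, product savings,
tank counts and refill-time savings.

Labels for citrus in Spain express the dose as a concentration of the tank
mix, so reducing the volume rate reduces the amount of product applied in
the same proportion:

    reduction (%)       = 100 · (Vc − Va) / Vc
    product saved /ha   = (concentration/100) · (Vc − Va)

Tank counts use the whole-area convention: the number of refills needed to
spray A hectares at rate V with a tank of capacity C is ceil(V·A / C) — the
sprayer carries a partial last tank rather than refilling per hectare.
Refill-time savings then value each avoided refill at a fixed time
(default 40 min, transit to the water source included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

#: default time per tank refill, minutes (equipment transit included)
DEFAULT_REFILL_MINUTES = 40.0


@dataclass(frozen=True)
class Ingredient:
    name: str
    concentration_pct: float  # % of tank mix

    def __post_init__(self):
        if not 0 < self.concentration_pct < 100:
            raise ValidationError(
                f"concentration must be in (0, 100) %, got {self.concentration_pct}"
            )


@dataclass(frozen=True)
class ApplicationRecord:
    """One paired conventional/adjusted application in a field trial."""

    orchard_id: str
    date: str
    pest: str
    vc: float  # conventional volume rate, L/ha
    va: float  # adjusted volume rate, L/ha
    tank_capacity: float  # L
    ingredients: tuple[Ingredient, ...] = ()

    def __post_init__(self):
        if not self.va > 0:
            raise ValidationError(f"va must be strictly positive, got {self.va}")
        if self.vc < self.va:
            raise ValidationError(
                f"vc ({self.vc}) must be >= va ({self.va}); "
                "the adjusted rate cannot exceed the conventional one"
            )
        if not self.tank_capacity > 0:
            raise ValidationError("tank_capacity must be strictly positive")


def mix_reduction(vc: float, va: float) -> float:
    """Percentage reduction of mix volume, 100·(Vc − Va)/Vc."""
    if not va > 0:
        raise ValidationError(f"va must be strictly positive, got {va}")
    if vc < va:
        raise ValidationError(f"vc ({vc}) must be >= va ({va})")
    return 100.0 * (vc - va) / vc


def ppp_savings(concentration_pct: float, vc: float, va: float) -> float:
    """Product saved per hectare (kg or L, following the formulation).

    With concentration-based labels the product applied is proportional to
    the mix volume, so savings = (concentration/100)·(Vc − Va).
    """
    if not 0 < concentration_pct < 100:
        raise ValidationError(
            f"concentration must be in (0, 100) %, got {concentration_pct}"
        )
    if not va > 0 or vc < va:
        raise ValidationError(f"require vc >= va > 0, got vc={vc}, va={va}")
    return concentration_pct / 100.0 * (vc - va)


def tanks_needed(volume_rate: float, area_ha: float, capacity: float) -> int:
    """Number of tank fills to spray ``area_ha`` at ``volume_rate``.

    Whole-area ceiling: ceil(rate·area / capacity), never below 1.
    """
    for name, v in (("volume_rate", volume_rate), ("area_ha", area_ha),
                    ("capacity", capacity)):
        if not v > 0:
            raise ValidationError(f"{name} must be strictly positive, got {v}")
    return max(1, math.ceil(volume_rate * area_ha / capacity))


def refill_time_savings(
    vc: float,
    va: float,
    capacity: float,
    area_ha: float,
    refill_minutes: float = DEFAULT_REFILL_MINUTES,
) -> float:
    """Hours of refill time saved by the adjusted rate over ``area_ha``."""
    saved_tanks = tanks_needed(vc, area_ha, capacity) - tanks_needed(
        va, area_ha, capacity
    )
    return saved_tanks * refill_minutes / 60.0


def summarize_trials(
    records: Iterable[ApplicationRecord],
    areas_ha: tuple[float, ...] = (1.0, 10.0, 100.0),
    refill_minutes: float = DEFAULT_REFILL_MINUTES,
) -> "TrialSummary":
    """Per-application reductions, product savings and time savings.

    The overall reduction statistics are unweighted across applications
    (every application counts once regardless of its orchard or the number
    of tank mixes involved).
    """
    records = list(records)
    if not records:
        raise ValidationError("summarize_trials requires at least one record")
    app_rows, ingredient_rows = [], []
    for r in records:
        red = mix_reduction(r.vc, r.va)
        row = {
            "orchard_id": r.orchard_id,
            "date": r.date,
            "pest": r.pest,
            "vc": r.vc,
            "va": r.va,
            "reduction_pct": red,
        }
        for a in areas_ha:
            row[f"time_saved_h_{a:g}ha"] = refill_time_savings(
                r.vc, r.va, r.tank_capacity, a, refill_minutes
            )
        app_rows.append(row)
        for ing in r.ingredients:
            ingredient_rows.append(
                {
                    "orchard_id": r.orchard_id,
                    "date": r.date,
                    "ingredient": ing.name,
                    "concentration_pct": ing.concentration_pct,
                    "savings_per_ha": ppp_savings(
                        ing.concentration_pct, r.vc, r.va
                    ),
                }
            )
    applications = pd.DataFrame(app_rows)
    ingredients = pd.DataFrame(ingredient_rows)
    red = applications["reduction_pct"]
    return TrialSummary(
        applications=applications,
        ingredients=ingredients,
        mean_reduction_pct=float(red.mean()),
        min_reduction_pct=float(red.min()),
        max_reduction_pct=float(red.max()),
    )


@dataclass
class TrialSummary:
    applications: pd.DataFrame
    ingredients: pd.DataFrame
    mean_reduction_pct: float
    min_reduction_pct: float
    max_reduction_pct: float
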