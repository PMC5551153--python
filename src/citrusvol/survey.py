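"""Leaf-area-density estimation from the cube-sampling field protocol.

A cube of known volume (default 0.343 m³, i.e. 70 × 70 × 70 cm) is placed in
a canopy quadrant without disturbing the vegetation; every leaf inside is
collected and weighed.  A subsample of leaves is weighed and its one-sided
area measured, giving a specific leaf area in cm²/g.  The quadrant's leaf
area density is then

    LAD (m²/m³) = (leaf mass in cube / cube volume) · (subsample area /
                   subsample mass) · 10⁻⁴

Quadrant values are averaged within each repetition and repetition means are
averaged to the orchard value; for balanced designs (equal quadrant counts
per repetition) the nesting does not matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ValidationError

#: cube volume of the standard 70 cm sampling frame, m³
DEFAULT_CUBE_VOLUME = 0.343

_CM2_TO_M2 = 1e-4


@dataclass(frozen=True)
class CubeSample:
    """One cube sample from one canopy quadrant.

    Attributes
    ----------
    quadrant_id : free-text quadrant label (e.g. "top-N", "bottom-SE")
    leaf_mass_in_cube : g of fresh leaves collected inside the cube
    subsample_mass : g of the leaf subsample weighed in the laboratory
    subsample_area : cm² one-sided area of that subsample
    repetition : grouping key for averaging; defaults to a single repetition
    cube_volume : m³, the sampling-frame volume
    """

    quadrant_id: str
    leaf_mass_in_cube: float
    subsample_mass: float
    subsample_area: float
    repetition: str = "1"
    cube_volume: float = DEFAULT_CUBE_VOLUME

    def __post_init__(self):
        for name in ("leaf_mass_in_cube", "subsample_mass", "subsample_area",
                     "cube_volume"):
            if not getattr(self, name) > 0:
                raise ValidationError(
                    f"{name} must be strictly positive, got {getattr(self, name)}"
                )


@dataclass
class LadEstimate:
    """Orchard-level LAD estimate with its between-repetition spread."""

    mean: float  # m² leaf / m³ canopy
    se: Optional[float]  # standard error over repetitions; None if only one
    n_repetitions: int
    repetition_means: dict[str, float] = field(default_factory=dict)


def quadrant_lad(sample: CubeSample) -> float:
    """LAD (m² leaf / m³ canopy) of a single quadrant cube sample.

    Invariant to the subsample size: scaling subsample mass and area
    together leaves the result unchanged.
    """
    g_per_m3 = sample.leaf_mass_in_cube / sample.cube_volume
    cm2_per_g = sample.subsample_area / sample.subsample_mass
    return g_per_m3 * cm2_per_g * _CM2_TO_M2


def orchard_lad(samples: Iterable[CubeSample]) -> LadEstimate:
    """Orchard-level LAD: quadrants averaged within repetitions, then across.

    The standard error is over repetition means (the protocol's unit of
    replication); it is None when only one repetition is supplied.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("orchard_lad requires at least one cube sample")
    per_rep: dict[str, list[float]] = {}
    for s in samples:
        per_rep.setdefault(s.repetition, []).append(quadrant_lad(s))
    rep_means = {rep: sum(v) / len(v) for rep, v in per_rep.items()}
    values = list(rep_means.values())
    mean = sum(values) / len(values)
    se = None
    if len(values) > 1:
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        se = math.sqrt(var / len(values))
    return LadEstimate(
        mean=mean, se=se, n_repetitions=len(values), repetition_means=rep_means
    )


def read_samples(path: Union[str, Path]) -> list[CubeSample]:
    """Read cube samples from a CSV file.

    Required columns: ``repetition``, ``quadrant_id``, ``leaf_mass_in_cube``,
    ``subsample_mass``, ``subsample_area``; optional ``cube_volume``.
    """
    df = pd.read_csv(path)
    required = {
        "repetition", "quadrant_id", "leaf_mass_in_cube",
        "subsample_mass", "subsample_area",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample table is missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        out.append(
            CubeSample(
                quadrant_id=str(row.quadrant_id),
                leaf_mass_in_cube=float(row.leaf_mass_in_cube),
                subsample_mass=float(row.subsample_mass),
                subsample_area=float(row.subsample_area),
                repetition=str(row.repetition),
                cube_volume=float(getattr(row, "cube_volume", DEFAULT_CUBE_VOLUME)),
            )
        )
    return out
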