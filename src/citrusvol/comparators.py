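"""Classical dose-expression systems for side-by-side comparison.

Three widely used crop-adapted dose expressions are implemented against the
same orchard geometry the recommendation engine consumes:

* **TRV** (Tree Row Volume): each row is a rectangular box of height h and
  width Ø_across running the full row length; foliage volume per hectare is
  h·Ø_across·(10⁴/sp_row) m³/ha, and the volume rate follows from an
  optimum rate per m³ of foliage (0.094 L/m³ for the reference apple
  orchard of 39,907 m³/ha).  The box deliberately overstates an ellipsoidal
  canopy — that contrast is the point of the comparator.
* **LWA** (Leaf Wall Area): the canopy as a vertical wall facing the spray;
  two-sided by default, 2·h·(10⁴/sp_row) m²/ha.
* **UCR** (Unit Canopy Row): canopy expressed in units of 100 m³
  (1 m high × 1 m wide × 100 m of row); UCR/ha = h·Ø_across·(10⁴/sp_row)/100.

TRV and UCR convert to L/ha given a rate per unit; LWA is reported as the
crop metric only (no citrus rate per m² of wall is established).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel

from .canopy import OrchardGeometry, canopy_volume_case1, tree_density

#: optimum TRV volume rate for the reference apple orchard, L/m³
DEFAULT_TRV_RATE = 0.094

#: foliage volume of the reference "standard apple orchard", m³/ha
STANDARD_ORCHARD_TRV = 39907.0


class Method(str, enum.Enum):
    TRV = "TRV"
    LWA = "LWA"
    UCR = "UCR"
    CITRUSVOL = "CitrusVol"


class ComparisonResult(BaseModel):
    method: Method
    crop_metric: float
    crop_metric_units: str
    volume_rate: Optional[float] = None  # L/ha


def _row_metres_per_ha(sp_row: float) -> float:
    return 10000.0 / sp_row


def trv(geom: OrchardGeometry, rate_per_m3: float = DEFAULT_TRV_RATE) -> ComparisonResult:
    """Tree-Row-Volume foliage volume (m³/ha) and volume rate (L/ha)."""
    volume = geom.h * geom.d_across * _row_metres_per_ha(geom.sp_row)
    return ComparisonResult(
        method=Method.TRV,
        crop_metric=volume,
        crop_metric_units="m3 foliage/ha",
        volume_rate=volume * rate_per_m3,
    )


def lwa(geom: OrchardGeometry, one_sided: bool = False) -> ComparisonResult:
    """Leaf-Wall-Area treated wall surface (m²/ha).

    Both wall faces are counted by default; ``one_sided=True`` gives the
    single-face variant some national schemes use.
    """
    faces = 1.0 if one_sided else 2.0
    area = faces * geom.h * _row_metres_per_ha(geom.sp_row)
    return ComparisonResult(
        method=Method.LWA, crop_metric=area, crop_metric_units="m2 wall/ha"
    )


def ucr_units(
    geom: OrchardGeometry, rate_per_ucr: Optional[float] = None
) -> ComparisonResult:
    """Unit-Canopy-Row count per hectare, optionally with a rate in L/UCR."""
    units = geom.h * geom.d_across * _row_metres_per_ha(geom.sp_row) / 100.0
    return ComparisonResult(
        method=Method.UCR,
        crop_metric=units,
        crop_metric_units="UCR/ha",
        volume_rate=units * rate_per_ucr if rate_per_ucr is not None else None,
    )


def compare_all(
    geom: OrchardGeometry,
    trv_rate_per_m3: float = DEFAULT_TRV_RATE,
    citrusvol_rate: Optional[float] = None,
    citrusvol_metric: Optional[float] = None,
) -> list[ComparisonResult]:
    """All comparators for one geometry, plus the CitrusVol result if given."""
    out = [trv(geom, trv_rate_per_m3), lwa(geom), ucr_units(geom)]
    if citrusvol_rate is not None:
        if citrusvol_metric is None:
            # total ellipsoid canopy volume per hectare
            citrusvol_metric = canopy_volume_case1(
                geom.h, geom.d_across, geom.d_along
            ) * tree_density(geom.sp_tree, geom.sp_row)
        out.append(
            ComparisonResult(
                method=Method.CITRUSVOL,
                crop_metric=citrusvol_metric,
                crop_metric_units="m3 canopy/ha (ellipsoid x N)",
                volume_rate=citrusvol_rate,
            )
        )
    return out
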