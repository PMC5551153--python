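"""Canopy geometry: planting density, apparent volume, leaf surface.

The citrus canopy is modelled as an ellipsoid with axes given by the canopy
height ``h`` (bottom of canopy to top, not ground to top) and the two mean
diameters measured across and along the row.  Apparent volume per tree:

    VT1 = (π/6) · h · Ø_across · Ø_along          (isolated/touching crowns)
    VT2 = (π/6) · h · Ø_across · sp_tree          (hedgerow assumption)

VT2 replaces the along-row diameter by the tree spacing and is relevant when
crowns do not meet (Ø_along < sp_tree) but the sprayer cannot shut nozzles
off in the gaps.  One-sided leaf surface follows from the leaf area density,
S = LAD · VT, and the surface to be wetted counts both leaf faces scaled by
the target factor, S_W = 2 · S · f_target.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from pydantic import BaseModel, model_validator

log = logging.getLogger(__name__)

#: Reject dimensions beyond this as physically implausible for citrus (m).
MAX_DIMENSION_M = 15.0


class OrchardGeometry(BaseModel):
    """Orchard planting framework and mean canopy dimensions, all in metres."""

    h: float  # canopy height, bottom of canopy to top
    d_across: float  # mean crown diameter perpendicular to the row
    d_along: float  # mean crown diameter parallel to the row
    sp_tree: float  # spacing between trunks within a row
    sp_row: float  # spacing between rows

    @model_validator(mode="after")
    def _plausible(self) -> "OrchardGeometry":
        for name in ("h", "d_across", "d_along", "sp_tree", "sp_row"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
            if v > MAX_DIMENSION_M:
                raise ValueError(
                    f"{name} = {v} m exceeds the plausibility limit of "
                    f"{MAX_DIMENSION_M} m"
                )
        return self

    @property
    def hedged(self) -> bool:
        """True when crowns meet or overlap along the row."""
        return self.d_along >= self.sp_tree


class CanopyMetrics(BaseModel):
    """Per-tree canopy quantities feeding the dose computation.

    ``vt2``/``s2``/``sw2`` are present only when the along-row diameter is
    smaller than the tree spacing (gapped rows).
    """

    n_trees: float  # trees/ha, not rounded
    vt1: float  # m³/tree
    s1: float  # m² leaf (one side)/tree
    sw1: float  # m² leaf (both sides, target-weighted)/tree
    vt2: Optional[float] = None
    s2: Optional[float] = None
    sw2: Optional[float] = None


def tree_density(sp_tree: float, sp_row: float) -> float:
    """Planting density N (trees/ha) from tree and row spacing (m).

    Kept as a real number; the model is linear in N and never needs whole
    trees.
    """
    if sp_tree <= 0 or sp_row <= 0:
        raise ValueError("spacings must be strictly positive")
    return 10000.0 / (sp_tree * sp_row)


def canopy_volume_case1(h: float, d_across: float, d_along: float) -> float:
    """Ellipsoid apparent canopy volume VT1 (m³/tree)."""
    if h <= 0 or d_across <= 0 or d_along <= 0:
        raise ValueError("canopy dimensions must be strictly positive")
    return math.pi / 6.0 * h * d_across * d_along


def canopy_volume_case2(h: float, d_across: float, sp_tree: float) -> float:
    """Apparent canopy volume VT2 (m³/tree) with tree spacing as the
    along-row axis — the volume a gap-blind sprayer effectively treats."""
    if h <= 0 or d_across <= 0 or sp_tree <= 0:
        raise ValueError("canopy dimensions and spacing must be strictly positive")
    return math.pi / 6.0 * h * d_across * sp_tree


def leaf_surface(lad: float, vt: float) -> float:
    """One-sided leaf surface per tree S = LAD · VT (m² leaf/tree)."""
    if lad <= 0:
        raise ValueError("lad must be strictly positive")
    if vt <= 0:
        raise ValueError("vt must be strictly positive")
    return lad * vt


def wetted_surface(s: float, f_target: float) -> float:
    """Leaf surface to be wetted S_W = 2 · S · f_target (m² leaf/tree).

    Both leaf faces receive spray, hence the factor 2; ``f_target`` scales
    down to the canopy fraction the application must reach.
    """
    if s <= 0:
        raise ValueError("s must be strictly positive")
    if not 0 < f_target <= 1:
        raise ValueError(f"f_target must be in (0, 1], got {f_target}")
    return 2.0 * s * f_target


def canopy_metrics(
    geom: OrchardGeometry, lad: float, f_target: float
) -> CanopyMetrics:
    """Compute all per-tree canopy quantities for one orchard.

    The hedgerow quantities (case 2) are filled in only when the along-row
    diameter is smaller than the tree spacing; the boundary
    ``d_along == sp_tree`` belongs to case 1.
    """
    n = tree_density(geom.sp_tree, geom.sp_row)
    vt1 = canopy_volume_case1(geom.h, geom.d_across, geom.d_along)
    s1 = leaf_surface(lad, vt1)
    sw1 = wetted_surface(s1, f_target)
    metrics = CanopyMetrics(n_trees=n, vt1=vt1, s1=s1, sw1=sw1)
    if not geom.hedged:
        vt2 = canopy_volume_case2(geom.h, geom.d_across, geom.sp_tree)
        s2 = leaf_surface(lad, vt2)
        metrics.vt2 = vt2
        metrics.s2 = s2
        metrics.sw2 = wetted_surface(s2, f_target)
    log.debug(
        "canopy metrics: N=%.2f trees/ha VT1=%.3f m3 S1=%.3f m2 SW1=%.3f m2 VT2=%s",
        n, vt1, s1, sw1, f"{metrics.vt2:.3f} m3" if metrics.vt2 else "n/a",
    )
    return metrics
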