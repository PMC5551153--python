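"""Volume-rate recommendation engine.

From the minimum leaf deposit D (µL/cm²) and the wetted leaf surface per
tree, the theoretical volume rate is

    V (L/ha) = D · S_W · 0.01 · f_lab_field · N

where 0.01 converts (µL/cm²)·(m² leaf) into litres (10⁴ cm²/m² × 10⁻⁶ L/µL)
and ``f_lab_field`` (default 0.8) discounts the laboratory-derived deposit
for the lower survival of pests under field conditions.  The recommended
rate corrects for application efficiency — the fraction of sprayed liquid
that actually reaches the target canopy with an airblast sprayer:

    V_R = V / f_E        (f_E defaults to 0.6: ~50% canopy recovery with
                          water alone, +20% from the adjuvant)

For gapped rows (Ø_along < sp_tree) two recommendations are issued: V_R1
from the true ellipsoid volume (valid for sprayers with canopy-detection
that shut nozzles in the gaps) and V_R2 from the hedgerow volume (gap-blind
conventional sprayers), together with the volume saved by detection.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, field_validator

from .canopy import CanopyMetrics, OrchardGeometry, canopy_metrics
from .reference import (
    CultivarGroup,
    LadDatabase,
    MoaClass,
    ProductRegistry,
    ProductSpec,
    PruningLevel,
    TargetDatabase,
    TargetSpec,
)

#: litres per (µL/cm² · m² leaf): 10⁴ cm²/m² · 10⁻⁶ L/µL
_UL_CM2_M2_TO_L = 0.01


class DoseConstants(BaseModel):
    """Empirical correction factors of the dose model."""

    f_lab_field: float = 0.8  # field/lab survival correction
    f_e: float = 0.6  # airblast application efficiency with adjuvant

    @field_validator("f_lab_field", "f_e")
    @classmethod
    def _in_unit_interval(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError(f"factor must be in (0, 1], got {v}")
        return v


class Recommendation(BaseModel):
    """A volume-rate recommendation with its full calculation trace."""

    v_r1: float  # L/ha, canopy-detection (or hedged-row) recommendation
    v_r2: Optional[float] = None  # L/ha, gap-blind sprayer recommendation
    sensor_savings_pct: Optional[float] = None
    warnings: list[str] = []
    # trace
    metrics: CanopyMetrics
    lad: float
    target: TargetSpec
    product: ProductSpec
    constants: DoseConstants
    v1: float  # theoretical volume, case 1
    v2: Optional[float] = None


def theoretical_volume(
    deposit: float, s_w: float, n_trees: float, f_lab_field: float
) -> float:
    """Theoretical volume rate V (L/ha) to reach the required deposit.

    Parameters
    ----------
    deposit : µL/cm², minimum deposit for maximum efficacy
    s_w : m² leaf/tree, surface to be wetted
    n_trees : trees/ha
    f_lab_field : dimensionless lab→field survival correction
    """
    for name, v in (
        ("deposit", deposit),
        ("s_w", s_w),
        ("n_trees", n_trees),
        ("f_lab_field", f_lab_field),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return deposit * s_w * _UL_CM2_M2_TO_L * f_lab_field * n_trees


def recommended_volume(v: float, f_e: float) -> float:
    """Recommended volume rate V_R = V / f_E (L/ha)."""
    if not v > 0:
        raise ValueError(f"theoretical volume must be strictly positive, got {v}")
    if not 0 < f_e <= 1:
        raise ValueError(f"f_e must be in (0, 1], got {f_e}")
    return v / f_e


def recommend(
    geom: OrchardGeometry,
    cultivar_group: CultivarGroup | str,
    pruning: PruningLevel | str,
    target: str,
    product: str,
    constants: Optional[DoseConstants] = None,
    *,
    moa_class: Optional[MoaClass | str] = None,
    targets_db: Optional[TargetDatabase] = None,
    lad_db: Optional[LadDatabase] = None,
    products_db: Optional[ProductRegistry] = None,
) -> Recommendation:
    """Full pipeline: geometry + databases → volume-rate recommendation.

    Looks up the target factor, leaf area density and required deposit,
    computes the canopy metrics, and applies the dual-case logic.  The
    label-check warning is always attached; target- and product-specific
    warnings are appended after it.
    """
    constants = constants or DoseConstants()
    targets_db = targets_db or TargetDatabase.load()
    lad_db = lad_db or LadDatabase.load()
    products_db = products_db or ProductRegistry.load()

    target_spec = targets_db.lookup(target)
    product_spec = products_db.lookup(product, moa_class=moa_class)
    lad = lad_db.lookup(cultivar_group, pruning)

    metrics = canopy_metrics(geom, lad, target_spec.f_target)
    v1 = theoretical_volume(
        product_spec.deposit, metrics.sw1, metrics.n_trees, constants.f_lab_field
    )
    v_r1 = recommended_volume(v1, constants.f_e)

    warnings = ["label_check"]
    warnings += target_spec.warnings
    warnings += product_spec.label_warnings

    rec = Recommendation(
        v_r1=v_r1,
        warnings=warnings,
        metrics=metrics,
        lad=lad,
        target=target_spec,
        product=product_spec,
        constants=constants,
        v1=v1,
    )
    if metrics.sw2 is not None:
        v2 = theoretical_volume(
            product_spec.deposit, metrics.sw2, metrics.n_trees, constants.f_lab_field
        )
        rec.v2 = v2
        rec.v_r2 = recommended_volume(v2, constants.f_e)
        rec.sensor_savings_pct = 100.0 * (rec.v_r2 - rec.v_r1) / rec.v_r2
    return rec


def invert_deposit(
    v_r: float, s_w: float, n_trees: float, constants: Optional[DoseConstants] = None
) -> float:
    """Recover the deposit D (µL/cm²) implied by a recommendation.

    Algebraic inverse of the V → V_R chain; used for parameter-recovery
    checks and for reverse-engineering an observed volume rate.
    """
    constants = constants or DoseConstants()
    if not v_r > 0:
        raise ValueError("v_r must be strictly positive")
    v = v_r * constants.f_e
    return v / (s_w * _UL_CM2_M2_TO_L * constants.f_lab_field * n_trees)


# re-export for convenient single-import use
__all__ = [
    "DoseConstants",
    "Recommendation",
    "theoretical_volume",
    "recommended_volume",
    "recommend",
    "invert_deposit",
]
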