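# citrusvol

Adjusting pesticide mix volume rates to the orchard being sprayed — instead
of applying a blanket rate per hectare — is one of the simplest levers for
reducing plant-protection-product (PPP) use in citrus. `citrusvol`
recommends the spray volume (L/ha) for airblast applications in citrus
orchards from the canopy's size and geometry, its leaf area density, the
pest or disease to be controlled, and the product's mode of action. It also
ships the savings calculators used to evaluate the approach in commercial
orchards, and classical dose-expression comparators (TRV, LWA, UCR) for
side-by-side comparison.

Intended users: agronomists, spray-application researchers and IPM advisors
who want a scriptable, inspectable version of this dose-adjustment logic.

## The model

The recommendation targets a minimum leaf deposit *D* (µL/cm²) needed for
maximum control efficacy — 3.41 for contact products (organophosphate
reference), 4.72 for suffocating products (mineral-oil reference). The chain
from orchard to volume rate is:

```
N    = 10⁴ / (sp_tree · sp_row)            trees/ha
VT₁  = (π/6) · h · Ø_across · Ø_along      m³/tree   (ellipsoidal canopy)
VT₂  = (π/6) · h · Ø_across · sp_tree      m³/tree   (hedgerow assumption)
S    = LAD · VT                            m² leaf/tree
S_W  = 2 · S · f_target                    m² leaf to wet/tree
V    = D · S_W · 0.01 · f_lab-field · N    L/ha      (theoretical)
V_R  = V / f_E                             L/ha      (recommended)
```

where `LAD` (m² leaf/m³ canopy) comes from a cultivar-density × pruning
lookup table, `f_target` ∈ {1, 0.75, 0.49} encodes whether the application
must reach the whole canopy, two thirds, or the outer third,
`f_lab-field = 0.8` discounts laboratory deposits for field pest survival,
and `f_E = 0.6` is the fraction of sprayed liquid an airblast sprayer
actually lands on the canopy (with adjuvant). When crowns do not meet along
the row (`Ø_along < sp_tree`) two rates are issued: `V_R1` for sprayers with
canopy detection and `V_R2` for gap-blind sprayers, with the detection
saving `100·(1 − Ø_along/sp_tree)` %.

A survey module estimates LAD from the cube-sampling field protocol
(70 cm cube, leaf mass per canopy volume × specific leaf area), and a
savings module computes mix-volume reduction, per-ingredient product
savings and tank-refill time savings for paired conventional/adjusted
applications.

## Worked example

Orchard P1 of the shipped trial tables: Clemenules on a 6 m × 3 m frame,
canopy 2.51 m high, 4.33 m across the row, 3.08 m along it, normal pruning,
treating California red scale with chlorpyrifos:

```sh
citrusvol recommend --height 2.51 --d-across 4.33 --d-along 3.08 \
    --sp-tree 3 --sp-row 6 --cultivar Clemenules --pruning normal \
    --target "California red scale" --product chlorpyrifos
```

```
Recommended volume rate: 3276 L/ha
Trace:
  N        = 555.56 trees/ha
  VT1      = 17.53 m3/tree
  LAD      = 3.70 m2/m3 | f_target = 1.0
  S1       = 64.85 m2/tree | S_W1 = 129.70 m2/tree
  D        = 3.41 uL/cm2 (contact)
  V1       = 1965.7 L/ha | f_lab-field = 0.8 | f_E = 0.6
Warnings:
  - Check the technical data sheet of the product to verify if it is
    authorized for this use and/or if there are limits of maximum
    application volume rate or maximum dose.
```

The crowns touch along the row (3.08 m ≥ 3 m spacing), so a single rate is
issued. 3276 L/ha sits within 1% of the 3255 L/ha actually applied in the
field trial in this orchard — against the 4905 L/ha the farmer used
conventionally, a 34% reduction in mix and product. Comparing classical
dose expressions for the same geometry:

```
citrusvol compare-methods --height 2.51 --d-across 4.33 --d-along 3.08 \
    --sp-tree 3 --sp-row 6

      TRV: 18113.8 m3 foliage/ha      1702.7 L/ha
      LWA: 8366.7 m2 wall/ha          -
      UCR: 181.1 UCR/ha               -
```

Other subcommands: `evaluate-trials` (summarize the shipped paired-trial
tables), `lad-estimate` (orchard LAD from a CSV of cube samples),
`validate-db` (schema-check reference databases, including user-edited
ones). Everything is also importable: see `citrusvol.recommend`,
`citrusvol.summarize_trials`, `citrusvol.orchard_lad`.

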