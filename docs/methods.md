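# Methods

## Model and assumptions

The recommendation engine converts a required leaf deposit into a ground
volume rate through a chain of multiplicative factors. Its structural
assumptions:

1. **Ellipsoidal canopy.** A citrus crown is treated as an ellipsoid with
   axes `h` (canopy height, measured bottom-of-canopy to top — not from the
   ground), `Ø_across` and `Ø_along` (mean crown diameters perpendicular
   and parallel to the row). Apparent volume per tree is
   `VT₁ = (π/6)·h·Ø_across·Ø_along`.
2. **Homogeneous leaf distribution.** One-sided leaf area per tree is
   `S = LAD·VT` with a single orchard-level leaf area density; within-crown
   gradients are not modelled.
3. **Deposit-driven efficacy.** Maximum control is reached at a minimum
   deposit `D` on the leaf surface: 3.41 µL/cm² for contact products
   (organophosphate reference) and 4.72 µL/cm² for suffocating products
   (mineral-oil reference). These are safety-side constants covering all
   pest generations; the engine does not distinguish first-generation
   treatments, for which a lower deposit would suffice.
4. **Both leaf faces, target-weighted.** The surface to wet is
   `S_W = 2·S·f_target`, with `f_target` fixed by the application class:
   internal 1.0 (whole canopy: scales, mites, mealybugs…), intermediate
   0.75 (two thirds: thrips, aphids, leafminer…), external 0.49 (outer
   third: medfly). These class constants are authoritative lookups: the
   geometric derivation from ellipsoid shells is not reproduced here (a
   naive outer-third shell-volume fraction of an ellipsoid is ≈0.70, not
   0.49), and no attempt is made to reverse-engineer it.
5. **Two empirical corrections.** `f_lab-field = 0.8` scales laboratory
   deposits down for the lower survival of pests in the field;
   `f_E = 0.6` is the fraction of sprayed liquid an airblast sprayer lands
   on the intended canopy in Mediterranean citrus (≈0.5 with water alone,
   +20% with the adjuvant practically always present). Both are
   user-overridable within (0, 1].

Units: `V = D·S_W·0.01·f_lab-field·N` L/ha, the 0.01 being the exact
conversion (µL/cm²)·(m² leaf) → L (10⁴ cm²/m² × 10⁻⁶ L/µL). It is validated
by the near-reproduction of a trial orchard's adjusted rate (see below).

### Dual-case logic

If crowns meet along the row (`Ø_along ≥ sp_tree`) a single rate `V_R1` is
issued; the boundary case of exact equality belongs here. Otherwise the
engine also computes `VT₂ = (π/6)·h·Ø_across·sp_tree` — the volume a
sprayer that cannot shut nozzles off in the gaps effectively treats — and
issues `V_R2 ≥ V_R1` for gap-blind equipment. Because the two cases differ
only in the third ellipsoid factor and the whole chain is linear, the
volume saved by canopy detection is exactly `100·(1 − Ø_along/sp_tree)` %;
this closed form serves as an internal oracle in the property tests.

## Reference data

Targets, the LAD table, the product registry and the cultivar-group map
ship as editable YAML/CSV under `citrusvol/data/` and are re-validated on
every load (shipped or user-supplied): application classes and pruning
levels must be from their enums, `f_target` is derived from the class (not
stored), and the LAD table must be strictly increasing both along
severe → normal → no pruning and along low → medium → high density.
Products not covered by a deposit model of their own (abamectin,
spirotetramat, etc.) are classed `contact`, i.e. assigned the 3.41 µL/cm²
reference; the classification lives in the data file so it can be revised
without code changes. Warning texts travel as message identifiers and are
rendered to English only at the CLI layer.

## LAD survey estimator

The cube protocol: a 0.343 m³ frame (70 cm cube) per canopy quadrant, all
leaves inside weighed fresh; a laboratory subsample gives specific leaf
area (cm²/g). Quadrant LAD = (g/m³)·(cm²/g)·10⁻⁴. Quadrants are averaged
within each repetition first, repetition means then averaged to the orchard
value with their standard error; for balanced designs the nesting order is
immaterial, and the loader accepts any quadrant count per repetition. The
estimator is exactly invariant to subsample size.

## Savings arithmetic

With concentration-expressed labels (the norm for citrus in Spain),
reducing the volume rate reduces product use proportionally:
reduction % = `100·(Vc−Va)/Vc`, product saved = `(c/100)·(Vc−Va)` per
hectare. Tank counts use the whole-area ceiling convention
`ceil(V·A/C)` — the sprayer carries a partial last tank rather than
refilling per hectare. This convention is not a free choice: it is the only
one consistent with all 42 published time-savings cells of the evaluation
campaign (per-hectare rounding cannot produce, e.g., 0.67 h/ha alongside
7.33 h/10 ha), and a regression test asserts every cell at ±0.02 h (print
rounding). Each avoided refill is valued at 40 min, transit to the water
source included. Campaign-level reduction statistics are unweighted across
applications.

Two printed reduction cells of the shipped trial table disagree with their
own volume-rate pairs (orchard P6, 12 Aug: printed 20.81% vs computed
50.93%; P2, 09 Sep: printed 22.28% vs 22.99%) — almost certainly
copy-and-paste misprints. The fixtures preserve the printed values; tests
assert the discrepancy instead of silently correcting it. The published
campaign mean of 31.5% is the mean of the printed column; recomputing from
the volume rates gives 33.7%.

## Comparators

TRV treats each row as a rectangular box (`h·Ø_across·row-length`,
10⁴/sp_row row metres per hectare) with a default optimum of 0.094 L/m³
(the reference "standard apple orchard" of 39,907 m³/ha); the box profile
deliberately overstates an ellipsoidal canopy, which is the point of
showing it. LWA counts the vertical wall, two-sided by default
(`2·h·row-length`) with a one-sided flag, since no single equation is
standardized; no citrus rate per m² is established, so LWA reports the
crop metric only. UCR counts 100 m³ canopy units
(`h·Ø_across·row-length/100`). A cross-method invariant — box volume over
total ellipsoid volume equals `6·sp_tree/(π·Ø_along)` — is tested.

## Numerical and design choices

* Planting density `N = 10⁴/(sp_tree·sp_row)` is kept real-valued; nothing
  in the chain needs whole trees, and the trial spacings are non-integer.
* Geometry validation rejects non-positive dimensions and anything over
  15 m (implausible for citrus) but deliberately allows crown diameters
  exceeding spacings: hedged rows are real.
* The CLI rounds recommendations to whole litres; full precision is kept in
  the trace and the library API.
* All computation is closed-form and deterministic; there is no random
  number generator anywhere in the package.
* No default cultivar group or pruning level: the user must choose, as in
  the original drop-down interface.

## Validation scope and limitations

The regression fixtures are the published evaluation tables from seven
commercial Clementine orchards (14 paired applications, 2015–2016,
Valencia). Passing them shows the arithmetic chain reproduces the
published evaluation; it does not re-validate the underlying
deposit–efficacy models, which enter only through the two deposit
constants. The full pipeline on orchard P1's rounded printed dimensions
lands within ~1% of the adjusted rate actually applied (3276 vs 3255
L/ha); exact agreement is impossible because the original recommendations
were computed from unrounded field measurements, and the tests therefore
assert a 5% band for this end-to-end check. The LAD table covers three
density groups × three pruning levels for mature orchards; young or
heavily gapped canopies outside those combinations require a user-supplied
LAD. Efficacy itself (cull-fruit outcomes) is reported in the source
campaign only descriptively and is out of scope here, as are nozzle
selection, sprayer calibration and drift.
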