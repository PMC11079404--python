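# Methods

## Model overview

`pestsafe` implements a Mamdani fuzzy inference system that maps five
crisp ecotoxicological descriptors of a pesticide to a safety level point
on a 0–10 universe. The design separates three concerns:

1. **Membership calibration** (`pestsafe.model`): each parameter is a
   linguistic variable with a universe, ordered categories (best → worst)
   and one membership function per category.
2. **Rule-base generation** (`pestsafe.model.generate_rule_base`): the
   full category product (108 combinations) is enumerated and each
   combination classified Safe / NotSafe by a weighted-code threshold.
3. **Inference and defuzzification** (`pestsafe.engine`): min
   conjunction within rules, max disjunction across rules per consequent,
   Mamdani clipping of the output sets, centroid defuzzification.

## Membership calibration (model card)

Universes and category boundaries follow the published parameter table;
shapes and breakpoints:

| parameter | category | shape / breakpoints | provenance |
|---|---|---|---|
| persistency (days, [0, 200]) | non-persistent | trap (0, 0, 30, 65) | published |
| | moderate persistent | tri (15, 65, 150) | published |
| | persistent | trap (65, 100, 200, 200) | published |
| AEQ (–, [0, 20]) | high contaminate | trap (0, 0, 1, 1.25) | reconstructed |
| | moderate contaminate | tri (0.5, 1.5, 2.5) | reconstructed |
| | low contaminate | trap (1.5, 2, 20, 20) | reconstructed |
| LD50 bee (µg/bee, [0, 200]) | high toxicity | trap (0, 0, 1, 50.5) | reconstructed |
| | moderate toxicity | tri (0.5, 50.5, 125) | reconstructed |
| | low toxicity | trap (50.5, 100, 200, 200) | reconstructed |
| exposure (score, [0, 4]) | no likely exposure | z (1, 3) | published |
| | high exposure | s (1, 3) | published |
| MRL (mg/kg, [0, 400]) | low residue limit | z (100, 400) | reconstructed |
| | high residue limit | s (100, 400) | reconstructed |
| output ([0, 10]) | NotSafe | trap (0, 0, 3, 7) | reconstructed |
| | Safe | trap (3, 7, 10, 10) | reconstructed |

Only the persistency and exposure functions are published explicitly; the
rest are reconstructions, constrained as tightly as the published worked
assessments allow and flagged as such here:

* **AEQ**: category boundaries 1 and 2 come from the published category
  table. The high-contaminate shoulder 1.25 together with the moderate
  rising edge (0.5 → 1.5) is fixed by the fenthion assessment (AEQ 1.11
  must give moderate degree 0.61 and high degree (1.25−1.11)/0.25 = 0.56
  to land on the published 2.93).
* **LD50**: boundaries 1 and 100 from the category table; shoulders at
  the inter-boundary midpoint 50.5. The moderate triangle's upper vertex
  (125) must lie at or below 145 so that dodine (LD50 145) activates no
  NotSafe rule and scores 7.37; the high-toxicity falling edge 1 → 50.5
  gives DDT (LD50 8.8) degree 0.842 and its published 2.75.
* **MRL**: the z/s pair crosses at the published category boundary 250.
  All sample MRLs are ≤ 10 mg/kg and saturate at degree 1/0, so the
  sample scores are insensitive to the transition width.
* **Output sets**: the symmetric trapezoid pair is the unique
  one-parameter-free choice whose full-activation centroids are
  79/30 ≈ 2.633 and 10 − 79/30 ≈ 7.367, matching the published
  end-member scores 2.63 / 7.37 and the published mixed case 5.44.
* **z/s shapes** are the smooth quadratic-spline saturation curves
  (value ½ at the midpoint), the convention of mainstream fuzzy-control
  toolboxes; every sample record sits at saturation (exposure score 3),
  so sample reproduction is insensitive to this choice.

## Weights and the rule threshold

Two experts rated each parameter's importance on a 0–5 scale: (2, 3, 5,
4, 1) and (5, 3, 2, 1, 4) in the order persistency, AEQ, LD50, exposure,
MRL. Each expert's ratings are normalized by their sum and the two
normalized vectors averaged; all arithmetic uses exact fractions, giving
weights (7/30, 6/30, 7/30, 5/30, 5/30). Two-decimal values (0.23, 0.20,
0.23, 0.17, 0.17) are display rounding only — exact fractions matter
because 6 of the 108 combinations sit exactly on the 0.5 threshold and
must be classified Safe deterministically (the threshold is *strictly
greater than* 0.5 for NotSafe; the tie-goes-to-Safe direction is the one
consistent with the published rule-table rows, e.g. codes (0,1,1,0,1) →
0.60 → Not Safe but (0,1,1,0,0) → 13/30 → Safe). MRL codes are inverted
relative to the raw value: a *low* legal residue limit marks the more
hazardous compound (code 1).

## Numerical choices

* **Implication** is Mamdani clipping (min of activation and consequent
  membership); aggregation is pointwise max. Clipping is the choice
  consistent with the published end-member centroids — product (scaling)
  implication would give different mixed-case scores.
* **Defuzzification** integrates the clipped-max curve on a uniform grid
  of step 0.01 over [0, 10] (sum of x·µ over sum of µ). Reported scores
  are rounded half-up to 2 dp.
* **Oracle**: an independent closed-form centroid computes exact polygon
  moments of the piecewise-linear clipped union (breakpoints + clip
  crossings + pairwise segment intersections; per-segment area
  `(y0+y1)/2·dx` and moment `dx·(x0(2y0+y1)+x1(y0+2y1))/6`). Grid and
  oracle agree within 10⁻² at step 0.01 and 10⁻³ at step 0.001 over
  random aggregate pairs; each assessment carries a verification value
  (1 iff the routes agree to 2 dp).
* **Clamping**: inputs outside a universe are truncated to the nearest
  bound with a logged warning (a 2000-day half-life is assessed as the
  200-day universe maximum), matching the published input-handling rule.
* **Degenerate inputs**: a missing or non-finite field is a validation
  error, not a default; "no rule fired" (both aggregates zero) is an
  error because the calibrated model cannot reach it — it signals a
  mis-configured custom model.
* **AEQ dose-unit factor 1000**: applying the exposure chain to the
  dose table (mL/ha) and LD50s (µg/bee) reproduces the published
  quotients only with an additional ×1000 on the dose. The factor is a
  named, overridable calibration constant
  (`AEQInputs.dose_unit_factor`); its physical reading (a mL→µL-scale
  conversion) is deliberately not asserted.

## What the sample data does and does not show

The embedded fixtures are the published ten-pesticide sample with its
doses, expert ratings and expected outputs. They exercise every category
of every parameter at saturation and several partial activations
(clofentezine's split persistency, DDT's partial LD50 membership,
fenthion's between-category AEQ), plus both clamping directions. They do
*not* exercise the exposure and MRL transition regions (all samples
saturate there), so the reconstructed transition widths for those two
parameters are untested by reproduction — custom records falling in
those regions depend on the reconstruction stated above.

## Known limitations

* The crisp score is **not pointwise monotone** along a single-parameter
  sweep: one parameter's weighted code (max 7/30) can never cross the
  0.5 rule threshold by itself, so the consequent is unchanged while the
  aggregate activation dips below 1 at category crossovers, and the
  clipped-set centroid dips and recovers (e.g. 7.37 → 7.06 → 7.37 along
  the persistency axis with everything else at its best). This is an
  inherent Mamdani-centroid artifact, not a calibration error. The
  properties that do hold, and are tested: no degraded input ever scores
  above the all-best baseline, and degradation across saturated category
  prototypes is monotone non-increasing.
* Scores compress onto [2.63, 7.37]; differences near the floor (2.63
  vs 2.64 vs 2.65) reflect partial memberships, not meaningful hazard
  gradations.
* The AEQ sub-model covers a single active ingredient per product;
  multi-residue colony-level extensions (brood/population factors) are
  out of scope, as is eliciting new expert weights or learning
  membership breakpoints from data.
* Only bisector-free centroid defuzzification and min/max connectives
  are implemented; alternative t-norms and defuzzifiers are non-goals.
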