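# Methods

## Positional model

The primitive datum is one fracture line on one rib, reduced to its
percentage position along the rib: D1/(D1+D2) × 100, where D1 is the
along-bone distance from the costovertebral joint to the fracture site and D2
the remaining distance to the costochondral junction. 0 % is therefore
posterior (at the spine) and 100 % anterior. The orientation is corroborated
by the group comparisons the package produces: scapular fractures (a
posterior injury) pull the mean position down, sternal fractures (anterior)
push it up.

The along-bone distance is realized as **centerline polyline arc length**.
A fracture position is a 1D fraction, so a centerline carries all the
information the mapping uses; measuring over a volumetric bone surface would
change the absolute millimetre lengths but not the fraction, which is the
quantity every statistic consumes. Arc length is the sum of Euclidean segment
lengths, and positions map to 3D points (and back) by linear interpolation in
cumulative arc length. The inverse mapping projects a query point onto every
segment and takes the nearest; points farther than a tolerance (default
10 mm) from the curve are rejected rather than silently snapped.

Multiple fracture lines on one rib are independent records; no deduplication
is performed. The package reports fracture-*line* counts and rib-involvement
counts only, labeled as such (it does not attempt to distinguish a separate
"fracture event" notion).

## The thorax template

The built-in template is parametric, not patient-derived: 24 planar-ish
elliptical arcs (one per rib and side) whose half-axes, span angle and
inferior droop vary smoothly with rib index. Floating ribs 11–12 sweep a
shorter arc and end at the anatomical rib tip, which plays the role of the
100 % landmark since they have no costochondral junction. The template's
`scale` parameter multiplies every linear dimension of each curve, so arc
lengths scale exactly linearly — a similarity-scaling invariant the tests
exercise. Real geometry can replace it: one polyline per rib as an
ordered-vertex CSV (`rib,side,x,y,z`, row order = curve order) or an ASCII
PLY with vertex+edge elements (a small dedicated reader/writer, since the
mesh library does not round-trip edge-element PLY). Centerline extraction
from meshes is out of scope.

Left and right sides are kept separate by default. Aggregations accept a
`side_scope` of `left`, `right`, `pooled`, or `mirrored`; `mirrored` pools
both sides' counts (positions are side-symmetric fractions, so the counts
equal `pooled`) and paints them onto a single hemithorax. Pooled-all is the
default for the position histogram.

## Sectors and bins

CWIS sector boundaries default to equal thirds (33.33 / 66.67) because the
consensus taxonomy deliberately leaves the precise boundaries open; they are
a configuration parameter, never hard-coded in logic. Sector assignment is
half-open (posterior [0,b1), lateral [b1,b2), anterior [b2,100]); position
bins are left-closed with the final bin closed at 100 so that 100 % falls in
the 90–100 % bin. Percent values are stored at full precision; two-decimal
rounding applies only in display tables.

## Densities and heat maps

The along-rib density is a Gaussian kernel sum in percent coordinates with a
single reflection at each boundary (images at −p and 200−p), evaluated on a
0.5-point grid. Each record then contributes one unit of mass inside
[0, 100] up to a truncation error that is negligible for bandwidths well
below the domain width, so the trapezoidal integral of each profile equals
its record count within 1 % without any post-hoc rescaling. Bandwidth
defaults to 5 percent points — narrow enough to keep the two position modes
separated, wide enough to smooth a ~100-patient cohort. A rib with no records
yields an explicit all-zero profile.

The 3D heat map assigns every template vertex the density (or bin count) at
its own arc-length percentage and maps the scalars through a monotone
blue-to-red colormap. The color range is fixed per figure (global maximum
across ribs), so inter-rib frequency differences remain visible. Tubes are
swept along the centerlines with parallel-transport frames (radius 4 mm,
16 sides) and exported as PLY with per-vertex RGB; STL export drops color.

## Statistics

*Positional comparisons.* The statistical unit is the fracture record: each
fracture line contributes one observation, grouped by its patient's flag.
This matches the magnitude of rank-sum statistics produced by record-level
analyses of cohorts with ~900 fracture lines; a patient-level variant
(per-patient mean position) is available via `unit="patient"`. The test is
the two-sided Mann–Whitney U with midrank ties. For pooled sizes ≤ 12 the
p-value is exact, by enumerating every assignment of the pooled midranks to
the smaller group and accumulating the two-sided tail around the null mean
n_a·n_b/2. Larger samples use the normal approximation with tie-corrected
variance and no continuity correction (the convention of the major
statistical packages' asymptotic rank-sum test). U is reported for the
flag-positive sample; U_yes + U_no = n_yes·n_no.

*Contingency tests.* 2×2 tables use the uncorrected chi-square by default,
with Yates' correction available by flag (the analysis convention here does
not apply a continuity correction unless asked); `auto` routes to Fisher's
exact test when any expected cell is below 5. The clavicle × upper-rib test
is per patient: the indicator is "any fracture line on ribs 1–3". If the
indicator is constant across the cohort the association is undefined and the
result is returned with method `"degenerate"` and p = 1 so the group rates
remain readable.

*Count tables.* The per-rib table reports left/right/total counts and each
rib's share of the grand total. Combined shares of rib ranges are displayed
as sums of the two-decimal per-rib shares, matching the way such tables are
conventionally summarized (the full-precision ratio can differ in the last
digit).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
every default chosen to match the observed cohort summaries:

| parameter | default | meaning |
|---|---|---|
| fracture count | round(N(7, 3.87)), min 1 | fracture lines per patient |
| flag prevalence | 25.5 / 19.6 / 10.8 / 3.9 % | clavicle / scapula / vertebra / sternum |
| rib weights | published per-rib shares | probability of each rib per fracture |
| side split | 52 % left | per-fracture side |
| position mixture | modes 25 / 65, SDs 15, weight 0.55 posterior | bimodal percent distribution |
| effect shifts | scapula −7.5, sternum +12.0 | percent points added per flagged patient |
| clavicle_upper_boost | 3.1 | multiplier on rib 1–3 mass for clavicle patients |

The count model is a rounded truncated normal rather than a negative
binomial: only a mean and SD are available to match, and truncation at 1
keeps both approximately attainable. Flag effects are additive location
shifts on the percent scale, consistent with group comparisons that show
near-equal SDs across groups; positions are clipped to [0, 100] afterwards
and the clipped fraction (~3 % under defaults) is recorded in the ground
truth. The mixture modes 25/65 with SD 15 and posterior weight 0.55 place
the histogram's global mode in the 20–30 % bin and a secondary local mode in
the 60–70 % bin. The upper-rib boost of 3.1 was obtained by root-solving
E_k[1 − (1 − w′)^k] = 0.92 over the exact count distribution, so
clavicle-positive patients' expected rib 1–3 involvement is 92 %.

What the generator deliberately does not emulate: flags are drawn
independently (only marginal prevalences are specified), fracture counts are
independent of flags, and rib indices are drawn independently per fracture —
real trauma fractures cluster on consecutive ribs, which is why the
generator's baseline rib 1–3 involvement (~77 %) is higher than a clustered
cohort would show (~70 %). Passing tests therefore validate the estimators
under a location-shift, independent-draws world; they do not certify
behavior under within-patient correlation structures the generator lacks.

## Problem sizes and calibration checks

Parameter recovery runs at 2,000 patients (seeded): the scapula shift is
recovered within ±3 points of −7.5 and the sternum shift within ±4 of +12.0
(the sternum band is wider because only ~4 % of patients carry the flag),
each with p < 0.05, and the clavicle × upper-rib association is detected.
Null calibration uses 500 replicate cohorts of 300 patients with all shifts
zero — 300 is large enough that even the rarest flag essentially never has an
empty group — and requires each flag's rejection rate at α = 0.05 to fall in
[3 %, 7 %]. Marginal-structure checks (rib-weight total-variation distance
< 0.02, left share ±0.02, mean count ±0.2, bimodality) run at ~50,000
fracture lines.

## Numerical and interface choices

- Percent positions round-trip losslessly through the cohort CSV schema
  (floats written with shortest-round-trip repr; the reader uses exact float
  parsing).
- Side labels accept `left`/`right` and the `L`/`R` shorthand and are
  normalized on input.
- Validation errors name the offending 0-based data row.
- All randomness flows from a single integer seed through one generator per
  cohort draw; identical configurations produce byte-identical outputs, and
  the pipeline's JSON report is deterministic end to end.

## Known limitations

- The parametric template is a geometric idealization; heat-map colors are
  exact in percent coordinates but their 3D placement is only as anatomical
  as the template.
- The record-level comparison treats fracture lines within a patient as
  independent observations; with strong within-patient position correlation
  its p-values would be anti-conservative (the patient-level unit is the
  conservative alternative).
- Sector boundaries are a convention, not a measurement; results that depend
  on sector assignment should be reported together with the boundaries used.
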