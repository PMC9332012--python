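# Methods

## The counting principle

Rice develops lateral tillers in near-lockstep with leaf appearance on the
main stem (a new tiller emerges roughly three nodes below the newest main-stem
leaf), so during the vegetative and reproductive stages

N_tiller + main stem = N_leaf on main stem ≈ N_leaf tips above momentum height.

Long leaves borne on main stems reach above the canopy's centre of mass, while
short leaves on young tillers stay low.  The pipeline therefore counts
skeleton leaf-tip endpoints that lie above the *momentum height* — the
unweighted centroid row of the binary plant mask — and reports that count as
the per-hill stem estimate.  The raw count runs about one high relative to the
true tiller number (it includes the main stem); `subtract_main_stem` removes
that offset when a strict tiller count is wanted, but comparisons against
field counts conventionally use the raw count.

## Pipeline stages and parameters

1. **Decorrelation stretch.**  The 3×3 channel covariance over all pixels is
   eigendecomposed, the symmetric (ZCA) whitening applied, each component
   rescaled to the original channel standard deviation and the channel means
   restored.  The output covariance is exactly diagonal in the float domain;
   the uint8 output is the clipped, rounded version.  A constant-colour patch
   has singular covariance and is passed through unchanged with a warning.
   This transform suppresses correlated brightness variation (illumination,
   water-surface shading) while preserving hue differences — the regime where
   mean-relative thresholding is reliable.

2. **Green thresholding.**  A pixel is plant iff its stretched green value is
   ≥ *k* × the whole-patch mean of the stretched green channel.  Ties count as
   plant.  *k* is the only parameter re-tuned per observation date (one value
   per date); the implementation accepts [0.5, 2.0] and field practice sits in
   [0.9, 1.1].  The default is k = 1.1, the top of that range: with plant
   cover in the 10–25 % typical of a single-hill patch, the patch mean sits
   barely above the background mode, and only the upper end of the range puts
   the cut safely between the two modes.  "Whole-patch mean" is read as the
   mean of the green channel (not of all three channels), since the
   classification statistic itself is the green value.

3. **Small-component removal.**  8-connected components with area strictly
   below 500 px are deleted; a component of exactly 500 px survives.  This
   removes specular water reflections (typically 100–500 px) without touching
   leaves.  8-connectivity is used because anti-aliased diagonal leaf edges
   fragment under 4-connectivity.

4. **Line-following skeletonization** (step = 7 px).  Non-iterative tracing:
   from the current decision point, the mask is sampled on a circle of radius
   `step` restricted to a ±90° forward sector; contiguous angular runs of hits
   are formed; the next decision point is the centroid of the largest run
   (ties broken toward the current heading), and every other run of at least
   two samples spawns a branch polyline that inherits the parent point.  A
   trace terminates when its forward sector is empty, which bounds the
   endpoint-to-extremity distance by step − 1 = 6 px.  Seeds are the
   horizontal-run centroid of the topmost mask pixels (leftmost run on ties),
   so a seed placed at a leaf tip starts at most half a tip-width off the true
   tip.  After each trace, mask pixels within 1.5 × step of the drawn skeleton
   count as covered and the largest uncovered remainder is re-seeded, so each
   leaf of a hill blob (all leaves merge at the base) receives its own
   centerline.  Tracing is fully deterministic.  The choice of 7 px balances
   two failure modes: smaller steps turn boundary unevenness into spurious
   branches, larger steps merge neighbouring leaves into one line.

5. **Peak-in-window tip detection.**  Candidates are *all* skeleton decision
   points strictly above the momentum row (interior points are cheap to
   reject and the windows do it correctly), scanned top-to-bottom then
   left-to-right.  A candidate at (r, c) is accepted iff

   * **Condition 1** — no skeleton pixel in the 25 × 12 window spanning rows
     [r−12, r−1] and columns c ± 12 (no leaf area lies above a genuine tip).
     The candidate's own incident-segment pixels within a 1-px Chebyshev
     radius of (r, c) are excluded, so the first pixel of the candidate's own
     centerline cannot veto it.  The window is 25 px wide because two
     non-overlapping leaves of ≥ 12 px width keep their centerlines ≥ 6+6 px
     apart, and the traced endpoint adds up to 6 px of slack.  (An alternative
     reading of the window geometry as 12 px wide exists; the 25 × 12 form is
     the one consistent with that spacing argument.)
   * **Condition 2** — no already-accepted tip in the 31 × 20 window spanning
     rows [r−20, r] and columns c ± 15.  The zigzag of a line-following
     skeleton can place several near-duplicate candidates on one leaf; scanning
     downward and testing only already-accepted tips keeps the uppermost
     (most tip-like) candidate deterministically.  The window includes the
     candidate's own row so same-row duplicates are caught.

   Windows are clipped at the image border rather than rejected, so tips at
   the patch edge stay detectable.  Window sizes are fixed across dates.

6. **Estimate.**  `tip_count` is the number of accepted tips;
   `tiller_estimate` is `tip_count` or `max(0, tip_count − 1)` under
   `subtract_main_stem`.

## The synthetic scene generator

Scenes emulate a proximal, slightly oblique view of one hill: quadratic
Bézier leaf blades fanning from a basal point near the bottom centre of a
560 × 420 px frame over a brownish water/soil background.  Width tapers
linearly from a base width drawn in 12–18 px (the minimum leaf width the
window sizes assume) to 6 px at the tip.  Control points keep each arc
monotone in the row coordinate (the tip is the blade's topmost point, as for
upright leaves) and bow the blade toward the clump, which keeps a leaf's
upper centerline on its own side of the fan.  Long-leaf tips land in the
upper third of the frame, at least ~26 px apart in column, and each placement
is rejection-sampled until no foreign centerline crosses the detection window
above any tip; infeasible requests raise.  Short leaves stay well below the
mask centroid.  Ground truth is analytic: tip coordinates and the count of
in-frame hill-leaf tips above the rendered mask's centroid row.

Rendering uses leaf colour (100, 152, 92) on background (112, 102, 94) with
noise that is predominantly *correlated brightness* (SD 12 shared across
channels) plus small per-channel noise (SD 1.5), then a light Gaussian blur
(σ = 0.5) for edge anti-aliasing.  The colour difference is deliberately
concentrated along the green axis: whitening rescales every direction of the
channel covariance to equal variance, so only the component of the class
difference that survives in the green channel after that rescaling is usable
by the threshold.  Brightness-correlated noise with a green-dominant class
difference is exactly the structure the decorrelation stretch is designed
for, and mirrors real canopy imagery, where illumination varies much more
than hue.  With these defaults the stretched green distributions of plant and
background are separated by many within-class standard deviations and k in
[0.9, 1.1] binarizes cleanly.

Stress modes reproduce the field error taxonomy: *overlap* moves one long
leaf's tip within 12 px of a neighbour's (merged tip regions → undercount);
*intrusion* adds a leaf entering from a side border with its tip above the
centroid (→ overcount); *edge* routes a long leaf out through a side border
(its true tip leaves the frame and the skeleton is clipped); *elevation*
raises short leaves above the centroid (→ overcount, as under too-steep
camera elevation).  Specular reflections are elliptical blobs with drawn area
sampled in [100, 460] px — inside the sub-500-px band the area filter must
delete, with head-room so that blur and thresholding cannot push a blob over
the 500-px survival boundary — placed at least 8 px clear of the plant and of
each other so they cannot merge into a ≥ 500 px component.

What the generator does *not* emulate: perspective foreshortening and lens
distortion, wind-deformed or motion-blurred leaves, senescent/yellowing
tissue, panicles, and the continuous canopy of neighbouring hills.  Passing
on synthetic scenes therefore demonstrates the internal consistency of the
method (each stage meets its stated guarantee, and the stages compose), not
field-level accuracy; the packaged field histograms are the record of the
latter.

## Evaluation statistics

Errors are `estimate − truth`.  Histograms use unit bins from −6 to +6 with
open-ended bins at |error| ≥ 7 (the published table layout).  The
count-weighted mean values the open bins at exactly ±7; this choice
reproduces the published means in every column where the computation is
decidable from the binned counts, and those three recomputable values
(−1.16, −1.14, +1.03) are pinned in the tests.  The published per-column
"error variance" rows are not reproducible from binned counts under any
open-bin valuation and are therefore not recomputed.  Percentages round to
the nearest integer and means to two decimals, the published precisions.
`fraction_within` rejects k > 6 because the open bins would make the result a
bound rather than a value.  `group_average_error` samples groups of hills
uniformly at random (the original multi-hill experiment used spatial
neighbourhoods, whose layout is not recoverable); only the monotone shrinkage
of the group-error SD and the 1/√n law for independent errors are asserted.

## Problem sizes used in the shipped checks

The validation suite and the reproduction script use 100 single-leaf scenes
for the endpoint guarantee, 100 clean + 40 overlap scenes (5–17 long leaves,
the observed per-hill tiller range) for end-to-end recovery, 50 random
blob masks up to 200 × 200 px for detector–oracle equivalence, 30 reflection
blobs for filter semantics, and 2000 replicates for the group-averaging law.
At these sizes the whole suite runs in well under two minutes on one core
while keeping the binomial noise on every pass-rate far below the margins
being asserted.

## Known limitations

* The tracer places decision points at run centroids, so on strongly curved
  leaves the polyline cuts the inside of the curve; endpoint accuracy is
  unaffected but mid-blade deviation can approach the step size.  No
  curvature correction is applied.
* Overlapping leaf tips are fundamentally ambiguous after binarization; the
  detector undercounts them by design rather than guessing.
* A leaf exiting the frame leaves a clipped skeleton whose border endpoint
  may still be counted; single-hill cropping should keep leaves in frame.
* The momentum-height screen assumes the hill fills most of the patch; a
  patch dominated by background shifts the centroid downward and can admit
  short-leaf tips.
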