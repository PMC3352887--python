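# Methods

## Tracking model

The tracker assumes a static scene: a dark fly on a light background inside a
fixed region of interest (ROI), one fly per ROI, ROIs pairwise disjoint.  The
reference image is the pixel-wise **median** of the supplied frames rather
than a single snapshot: the median is robust to a fly transiently occupying a
pixel in a minority of frames, so a usable reference can be built even from a
stream in which the arena was never perfectly empty.  The reference is never
updated during a run; slow illumination drift is therefore a known failure
mode and should be handled by re-capturing a reference.

Segmentation is `|frame − reference| > θ` with θ (`contrast_threshold`,
default 60 intensity units on an 8-bit scale) followed by 8-connected
component labelling, an area filter `[min_area, max_area]` (defaults 6–400
px) and selection of the largest survivor; area ties break toward the
smaller top-left bounding-box corner so output is deterministic.  The
original rig's threshold and size window were never published; these defaults
suit the bundled renderer (fly at intensity 40 on background 220) and are
config-exposed, not validated against any physical camera.

Centroids are the arithmetic mean of member-pixel coordinates and are kept
**sub-pixel**; quantising to whole pixels would alias displacements near the
2 px (20 % FBL) threshold.  The component's length is its largest pairwise
pixel-centre distance plus one (pixel centres d apart span d+1 pixels), so a
straight 10-pixel fly measures 10.0; the body-length estimate is the median
over detections.  On detection failure the last valid position is carried
forward with `valid=False` — downstream stages never score displacement
across an invalid sample, and runs of more than 60 s of invalid data flag
their minute bins in QC output.

Colour input is collapsed with ITU-R 601 luma weights.

## Movement scoring

Both displacement cutoffs are round-half-up of FBL × fraction, floored at
1 px.  Round-half-up is a documented choice: the field expresses settings as
"20 % of a ~10 px fly = 2 px", which any nearest-integer rule reproduces, but
the exact rule for non-integer products is not standardised.  The minimum
threshold is inclusive (the fly must move *at least* that distance).
Displacements above the maximum cutoff (150 % FBL — beyond a fly's attainable
1 s travel) are tracking artifacts: scored 0, flagged, logged, never clamped
or interpolated.  The first second of a trajectory and seconds adjacent to
invalid detections score 0.

Bins are aligned to ZT 0 (lights-on); leading seconds before the first
aligned boundary and partial trailing bins are dropped, because DAM-style
analyses operate on whole bins.  The virtual beam scores second *t* when the
tube-axis positions at *t−1* and *t* lie strictly on opposite sides of the
beam, or when the fly lands exactly on the beam from off-beam; consecutive
on-beam samples count once.  The exact-landing convention is a choice (a
centroid landing on the beam coordinate has measure zero for real data); it
prevents double-counting a fly resting on the beam.

## Sleep architecture

Sleep is the operational standard: ≥ 5 consecutive 1-min bins with zero
counts.  Analysis days are anchored at ZT 0, not at recording start.  A bout
spanning the lights-off boundary contributes its *minutes* to the period in
which they fall (so LP + DP totals always sum to the 24 h total) while the
*bout* — for counts, mean, max and latency — belongs to its onset period;
the alternative (counting boundary bouts in both panels) breaks additivity.
Latency is measured from the period's lights transition and capped at the
period length when no bout starts in the period, so group means remain
defined; capped values are real caps, not missing data.  Days are averaged
within fly before any cross-fly statistic; dispersion is reported as SEM.
Inferential statistics are out of scope — the tidy per-fly × day × period
CSV is designed to feed external stats tools.

## Spatial analytics

Distances use the full 2-D Euclidean step, not the axis projection (in a
5 mm-wide tube the difference is small but systematic), converted to mm by
the linear map ROI-axis-length ↔ 65 mm.  The step from sample *t* to *t+1*
is credited to second *t*, the second during which the movement occurred.
Artifact steps contribute zero distance.  `subsample_distance` applies no
artifact cutoff: it measures pure decimation loss on the recorded polyline,
so stride 1 reproduces the unfiltered 1 Hz total exactly and the triangle
inequality guarantees every coarser stride is ≤ it.

Tube sections are ten equal half-open partitions of the ROI axis with
section 10 adjacent to the food and the food-end boundary point belonging to
section 10.  Occupancy tallies one second per valid sample; columns therefore
sum to valid-tracked seconds per bin, and the asleep/awake matrices partition
the unconditioned matrix cell-wise (a second is "asleep" iff its minute lies
in a sleep bout).  Population occupancy can be pooled across flies or
averaged per fly; both are available since the two differ only by 1/N when
all flies are fully tracked.

## Synthetic data

The generator is the package's ground-truth source and defines the study
conditions used throughout the tests:

| parameter | default | why |
|---|---|---|
| cycle | 12:12 LD, days anchored at ZT 0 | standard entrainment schedule |
| tube axis | 260 px ↔ 65 mm (0.25 mm/px) | a 10 px fly is then ~2.5 mm, a typical body length |
| FBL | 10 px | the package's reference sensitivity anchor |
| rest/active bout means | 10/10 min (light), 24/6 min (dark) | exponential, phase-switched; expected rest fraction 0.5 by day, 0.8 by night → ~65 %/day, a wild-type-like sleep amount with a clear nocturnal bias |
| active step speed | N(4, 2) px/s, capped at 14 px | ~1 mm/s walking; the cap keeps every true step below the 15 px artifact cutoff |
| rest jitter | σ = 0.3 px | posture noise far below the 2 px (20 % FBL) threshold, so true rest scores immobile at every sensitivity |
| food bias | 0.3 | probability bias toward the food end at heading reversals; produces a dwell gradient peaking at the food section |
| rendering | fly 40 on background 220, 8-bit | arbitrary high-contrast fixture constants |

Exponential bout durations are the minimal memoryless model and make the
expected rest fraction analytic (rest_mean/(rest_mean+active_mean) per
phase); bout means switch by the phase at bout onset.  Ground-truth rest
bouts are expressed on the minute grid — a rest minute contains no active
second — as maximal runs ≥ 5 min, i.e. what a perfect 1-min binning would
score.  With the defaults the simulator produces ~30–37 m/day of travel and
~400 beam crossings/day, the right order for wild-type flies.

What the simulator does **not** emulate: grooming and feeding micro-movements,
posture changes that displace the centroid without locomotion, illumination
drift between the red-light and white-light phases, optical blur, multi-fly
occlusion, or mutant-specific phenotypes.  Passing recovery tests therefore
demonstrates internal consistency of the pipeline under a clean motion model,
not scoring accuracy on real video.

Decimating simulator trajectories to 5 s sampling loses ~25–30 % of total
distance under the default motion model; the loss fraction depends entirely
on the reversal statistics of the walk, so it is a qualitative property
(strictly positive loss whenever reversals occur), not a calibrated estimate
of any particular rig's loss.

## Numerical and format choices

- Coordinates are 0-based pixels, origin top-left, y downward; the tube axis
  is the longer ROI dimension.
- Light intervals are half-open: ZT 0 is light, the lights-off minute is the
  first dark minute.
- Coordinate files are a versioned, self-describing tab-delimited dialect
  (the historical single-text-file layout was never published); floats are
  written with shortest round-trip repr, so read∘write is bit-exact.
- DAM output adopts the Trikinetics 32-channel monitor layout, date format
  "D Mon YY"; populations beyond 32 flies split across suffixed files.
- All timestamps are experiment-relative integer seconds; a single absolute
  anchor lives in file headers.
- Test and acceptance problem sizes (single-fly days, 500-frame render
  round-trips, 10–20-seed ensembles) were chosen so the full suite completes
  in a couple of minutes while keeping Monte-Carlo tolerances derivable from
  renewal-theory variance rather than tuned.

## Known limitations

- Static reference image; no background adaptation.
- One fly per ROI; no identity maintenance if two flies share a tube.
- Latency capping and the bout-onset attribution rule are conventions; other
  packages may report boundary bouts differently.
- The contrast threshold and blob size window have no empirical calibration
  against physical rigs.
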