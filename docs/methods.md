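# Methods

`egohand` measures functional hand use from egocentric (first-person)
video. The target population is people with impaired upper-extremity
function (e.g. cervical spinal cord injury), for whom the frequency and
duration of hand–object interaction at home is a candidate outcome
measure. The pipeline turns video into a per-hand binary
interaction/no-interaction timeline and reduces each timeline to three
functional metrics.

## Pipeline

Video is analysed at a standard height of 480 pixels (aspect preserved,
width rounded to the nearest even integer), nominally 30 fps. The stages,
each of which is also usable on its own:

1. **Hand detection (pluggable).** The pipeline only needs per-frame
   candidate boxes. Any external detector's output can be loaded from
   CSV; the self-contained baseline thresholds a skin-colour
   back-projection at 0.75 of its per-frame maximum and returns connected
   components above 0.1% of the frame area as tight boxes, scored by mean
   skin probability. Because the baseline's components span hand *and*
   forearm, the palm is localised at the peak of the euclidean distance
   transform inside the component (the palm is the widest part of the
   silhouette); a square box of three times the peak radius is the
   working hand box.

2. **Box verification and handedness (arm-angle feature).** A
   three-rectangle Haar-like feature is swept through 360 one-degree
   steps around the box centre: a centre rectangle extends from the
   centre along the ray to the image border, flanked by two parallel
   rectangles of the same width (half the shorter box side). The
   response is the mean difference between the side rectangles'
   coefficients of variation (population SD / mean of intensity) and the
   centre's; a uniform arm strip in a textured scene maximises it when
   the ray runs along the arm. Responses summed over 5-degree bins give a
   72-value vector used twice: a 150-tree random forest accepts or
   rejects the box (trained on synthetic arm-present/arm-absent scenes),
   and quadrant sums decide the hand — bottom-left quadrant (270–360°)
   = user's left hand, bottom-right (180–270°) = user's right, top half
   (0–180°) = another person's hand. The sums use the positive part of
   the response: positive bins are arm-like evidence, whereas negative
   bins (the centre rectangle busier than its flanks, as happens when it
   crosses a held object) say nothing about where the arm is, and signed
   sums would let a quadrant win by holding the least anti-arm content. The angle convention (0° = image
   west, clockwise through top) is the unique one consistent with that
   quadrant layout. Ties break right > left > other. A rectangle with
   fewer than 4 pixels or mean intensity below 1e-6 is unmeasurable;
   how unmeasurable rectangles enter the response is described under
   numerical choices.

3. **Segmentation.** Inside the (20%-padded) hand box, candidate
   contours are connected components of the skin mask after subtracting
   dilated edge pixels — the subtraction splits skin regions merged
   across object boundaries. The edge operator is pluggable; the baseline
   is Canny at σ = 2 (non-maximum suppression and hysteresis keep region
   boundaries while rejecting surface texture, which a bare gradient
   threshold cannot do because the 0.05-of-maximum rule is relative to
   the frame's single strongest edge). Components with filled area
   below 2% or above 75% of the box area are dropped, as are components
   whose perimeter lies within 90–110% of the box perimeter (box-hugging
   artefacts). The survivor with the highest |filled ∩ dilated edges| /
   |filled| wins (ties to the larger area); its full skin support is then
   recovered by binary propagation of the winner into the skin mask
   (the edge-refined mask is a selection device, not the delineation).
   The box is re-centred on the midpoint of the winning region's centroid
   and topmost pixel — hands sit above forearms in an egocentric view —
   with its size preserved and clipped to the frame.

4. **Interaction features (122 values).**
   - *Motion (60):* dense optical flow between consecutive frames via
     scikit-image's iterative Lucas–Kanade estimator (radius 7, 3 warps;
     fixed, archived in the config). Flow is summarised in three regions —
     segmented hand, re-centred box, background (frame minus box) — as
     L1-normalised 15-bin histograms of magnitude (range 0–20 px,
     overflow in the top bin) and direction (0–360°, unweighted). The
     feature is (hand − box) ++ (background − box), magnitudes before
     directions. A held object moves with the hand, so during interaction
     the box resembles the hand and differs from the background.
   - *Shape (60):* HOG on the box crop resized to 10% of the frame
     height × 15% of the frame width (9 orientations, 4×4-px cells,
     2×2-cell blocks), PCA-reduced to 60 so the families have equal
     dimension. The PCA is fitted on training-fold data only.
   - *Colour (2):* Bhattacharyya distances
     d_B(p,q) = √(1 − Σᵢ√(pᵢqᵢ)) between L1-normalised HSV histograms
     (15 bins per channel, concatenated): d_B(box, hand) and
     d_B(box, background).

5. **Classification.** A single pooled 150-tree random forest
   (scikit-learn, sqrt-features per split, unlimited depth, fixed seed)
   maps the 122-value feature to interaction / no interaction per frame;
   timelines are split by handedness afterwards. Ablations restrict the
   columns to one family under the identical protocol.

6. **Timelines and metrics.** Frames without a verified, segmented
   detection of a hand are missing for that hand. A run of at most 90
   missing frames (3 s) directly after an interaction frame is filled
   with interaction — interactions are prolonged when the hand is
   suddenly lost — and any other missing frame becomes no-interaction.
   The binary timeline is smoothed by a centred 120-frame (4 s)
   equal-weight moving average (edges shrink to the available window),
   min–max normalised over the whole video (a constant signal bypasses
   normalisation) and thresholded at 0.5. From the result:
   * `pct_interaction` = 100 · (interaction frames) / (total frames);
   * `mean_duration_s` = mean length of maximal interaction runs / fps;
   * `interactions_per_hour` = run count / video duration in hours.
   These satisfy pct = n · mean / total · 100 exactly; on a video with
   zero interactions the last two are undefined and reported as null.

7. **Validation statistics.** Predicted metric vectors are compared to
   manually-derived ones across subjects with a one-tailed (right)
   correlation test at α = 0.05: Pearson when both vectors pass
   Shapiro–Wilk normality at α = 0.05, Spearman otherwise.

## Evaluation protocol

Leave-one-subject-out: for each held-out subject the shape PCA and the
forest are refitted on the remaining subjects only (no test-subject frame
enters any fit), and the held-out subject is scored per hand with F1
(2TP/(2TP+FP+FN)) and accuracy. Two scoring modes exist. The default
scores the raw per-frame decisions. The filtered mode
(`smooth_timelines=True`) assembles per-frame decisions into per-hand
timelines, bridges, smooths and thresholds them, applies the identical
filtering to the manually labelled timeline, and scores the filtered
sequences over all frames — the natural protocol when task durations are
long relative to the 4-s filter window (minutes-long real ADL tasks). At
the package's desk-scale default of 600-frame simulated subjects, task
segments are necessarily comparable to the window, filtered scores are
dominated by the filter's edge behaviour rather than by classification
quality, and the raw mode is the meaningful one; it is therefore the
default.

## Synthetic scenes

The generator renders the minimal geometry that exercises every stage —
not photo-realism:

* a skin-coloured elliptical hand (semi-axis 9.5% of the frame height,
  aspect 1.3) with a uniform arm strip (width 0.75 of the hand height)
  running from the hand centre to a frame border; the entry side fixes
  the true arm angle (sampled within the matching quadrant with a 15°
  safety margin) and therefore the ground-truth handedness;
* skin pixels synthesised in YCbCr around the chroma cluster of the
  bundled mixture-of-Gaussians skin model (Cb ≈ 110, Cr ≈ 152), so
  segmentation fixtures are self-consistent with back-projection by
  construction;
* surface texture that translates rigidly with its owner: luma texture of
  amplitude 10 (8-bit) on the skin, 18 on the object, against a static
  background texture of amplitude 15. Rigid texture transport is what
  makes the scene trackable by an optical-flow estimator — per-frame
  independent noise would be untrackable by construction;
* an optional object (distinct colour, textured, with a hand-comparable
  size sampled per scene — ADL objects such as cups, phones and utensils
  span roughly the hand's scale) that either translates rigidly with the
  hand (frames labelled interaction — co-motion operationalises
  "manipulating an object"), follows its own independent path, or is
  absent (both labelled no interaction). Independent objects are kept at
  least 35 px away from the hand trajectory (seeded rejection sampling):
  a non-manipulated object inside the hand's box is indistinguishable
  from a held one at frame level, so scenes violating the separation
  would carry labels that are not decodable from their pixels;
* a smooth reflected random walk for the hand (speed ≤ 3.5 px/frame)
  confined to the workspace adjacent to the arm's entry border — an
  egocentric hand cannot plausibly hover in the far opposite corner with
  its forearm crossing the entire view — or a static pose for
  hand-at-rest scenes.

Default frames are 160×120: large enough for every geometric property
being tested, small enough that a five-subject cross-validation runs on
one CPU in minutes. Simulated cohorts are composed per subject of task
segments alternating interactive and non-interactive scenes at a 48%/52%
frame balance, with left/right entry sides and the two non-interactive
task types rotated across segments and subjects so no hand or subject is
confounded with a task type. Subjects default to 12 short task segments:
the observational regime being emulated involves many distinct ADL tasks per participant,
and the number of distinct scenes — not the number of frames per scene —
is what a cross-subject classifier must generalise over. The trade-off
is that 600-frame subjects cannot simultaneously have many tasks *and*
tasks long relative to the 120-frame filter window, which is why the raw
per-frame scoring is the evaluation default (above).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: camera egomotion (backgrounds are static),
occlusion by caregivers' hands, lighting changes and glare, skin-coloured
distractor surfaces (wood), motion blur, and objects that deform or
rotate in depth. Results on the synthetic cohort are a check of the
machinery, not a clinical validation.

## Numerical choices and degenerate inputs

* Rectangle membership in the arm-angle sweep is by pixel-centre
  inclusion; border rectangles truncate at the image edge. A direction
  whose centre rectangle has fewer than 4 pixels (or near-zero mean) has
  response 0, and the side average uses only side rectangles that are
  themselves measurable — otherwise truncation at the border would
  produce spurious side-minus-zero responses.
* Back-projection support floor: chroma bins below 1% of the histogram
  peak count as zero support, so a skin-free frame yields an empty mask
  rather than masking its least-unlikely colour.
* An edge strength map that is numerically flat (max ≤ 1e-10) yields an
  empty edge image.
* Empty regions produce all-zero histograms; Bhattacharyya distances
  clamp at [0, 1]; the PCA requires more training vectors than
  components (61 for 60).
* All forests run single-threaded with fixed seeds; two runs of the
  pipeline with the same seed are byte-identical, which the test suite
  asserts on the serialized metrics.
* Timeline bridging fills exactly up to 90 absent frames (91 are not
  bridged), and only after an interaction frame.
* The moving average is centred; the choice between centred and trailing
  is genuinely open; centred avoids a 2 s systematic lag.

## Known limitations

* The baseline detector is colour-driven and will fail on gloved hands or
  strongly skin-coloured backgrounds; the detector seam (CSV import)
  exists precisely so a trained detector can replace it.
* The handedness rule assumes the egocentric geometry (user's arms enter
  from the bottom corners); third-person video violates it.
* HOG parameters are fixed by this package's configuration; the raw
  descriptor dimension therefore depends on frame size (360 at 160×120,
  12276 at 854×480), and only the post-PCA dimension (60) is part of the
  feature contract.
* Metrics on videos shorter than the smoothing window are dominated by
  edge effects of the filter.
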