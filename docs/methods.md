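# Methods

This note documents the models, numerical choices and known limitations of
`gaitvqa`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Input model

The sole input is a `PoseSequence`: per-frame multi-person detections in
the layout a multi-person pose detector emits — up to six persons per
frame, each with 17 COCO-ordered keypoints `(y, x, score)` and a bounding
box `(ymin, xmin, ymax, xmax, score)`, all normalized to the frame with
the origin at the top-left and y increasing downward. All internal
geometry stays in normalized units; only the resolution stage converts to
pixels, which keeps every other metric resolution-independent. Frames with
zero detections are legal, propagate as "target absent", and remain in
every frame-percentage denominator. Coordinates must be normalized to the
original frame, not to a padded model input; that burden sits on whatever
adapter produced the file.

## Tracking

The target is chosen non-interactively (detection index, or nearest
reliable centroid to a given point) and followed by nearest-centroid
matching over reliable detections (box confidence ≥ `min_confidence`,
default 0.5, inclusive — detections *below* the minimum are eliminated).
Ties resolve to the lowest candidate index. When the selection frame is
not frame 0 a backward pass covers the earlier frames so whole-video
percentages are defined; `forward_only=True` restores strict
selection-frame-to-end tracking. During detection gaps the last centroid
is carried unchanged — no extrapolation and no re-acquisition distance
gate, so a long gap can in principle hand the track to a different person
who stops near the old centroid. Appearance-based re-identification is out
of scope.

The overlap test defaults to geometric rectangle intersection (the
x-interval *and* y-interval conditions). The disjunctive variant
(`overlap_rule="or"`), which flags a frame when either axis alone
intersects, is retained as a config switch but degenerates in practice:
two standing persons anywhere in a frame almost always share a vertical
range.

## Plane classification

Per-frame torso ratios use only the four shoulder/hip keypoints:
`r1 = D_s/D_rsh`, `r2 = D_lsh/D_s`, `R = r2/r1`. Frames with `D_s = 0` or
`D_rsh = 0` are ratio-undefined and skipped. The R list is filtered to
[P25, P75] inclusive — percentiles by linear interpolation between order
statistics, the numpy default, since no convention is inherent to the
rule — and the filtered mean plus the percentage of filtered values below
0.7 ("low ratios", denominator = filtered length) feed an ordered rule
list: mean < 0.5 → sagittal; mean ∈ [0.5, 1) → sagittal if low% > 40 else
coronal; mean ∈ [1, 2) → coronal; mean ∈ [2, 3) → coronal unless
low% = 0, then transverse; mean ≥ 3 → transverse. The prose rules the
list was distilled from overlap ("mean ≥ 2 → transverse" vs. the low-ratio
clause on [2, 3)); the ordered list honours every specific clause and
gives the blanket clause lowest precedence, with
`plane_rules="mean_ge_2_transverse"` exposing the literal alternative.

A physical caveat, deliberately not "fixed": for a genuinely side-on
subject the shoulder x-distance is small, which makes R large, yet the
rules assign *small* R to the sagittal view. The classifier rules are
implemented as printed, and the synthetic generator targets the printed
regimes rather than a camera-projection model; conclusions about real
camera geometry should not be drawn from the plane module alone.

## Zoom detection and segment extraction

The normalized box-height series (absent frames forward-filled, leading
gaps back-filled) is smoothed with a Gaussian kernel, σ = 2 frames,
reflected edges — chosen because the series is short-range correlated and
reflection avoids edge droop. Differences are taken `s` frames ahead;
`s = 8` at 60 Hz and `round(8·fps/60)` otherwise, keeping the ~133 ms
lookahead constant across frame rates (minimum 1). The threshold τ = 0.05
is a config value. Flagged frames of one direction coalesce into a single
event spanning first flag to last flag plus the lookahead step.

Coronal splitting assigns each frame the sign of its smoothed step
difference; exact zeros continue the previous sign (smoothed data is
rarely exactly zero, and this suppresses spurious single-frame segments).
Each maximal constant-sign run becomes a candidate segment, labelled by
majority facing direction over its frames (left-shoulder x > right-shoulder
x ⇒ facing the camera). Runs whose height trend contradicts their facing
(approaching while shrinking, receding while growing) are zoom artifacts
and are dropped. Sagittal splitting uses the per-frame walking direction
(mean ear x vs. nose x; exact ties carry the previous frame's direction;
frames with both ears below the keypoint-confidence floor are undefined),
majority-smoothed over a 5-frame window; frames `i..i+s` around any
`|Δhᵢ| > τ` are excised — both signs, although the sagittal excision was
originally stated for zoom-in only, because a zoom-out is no less
disruptive and the zoom definition covers both.

Candidates of duration ≤ 3 s (the two-stride floor; the boundary itself is
rejected, consistent with a 3 s segment scoring 0) are discarded, then
same-direction survivors separated by fewer than 5 frames merge, keeping
the first start and last end. Merging is restricted to same-direction
pairs: its purpose is re-joining a walk interrupted by excised zoom
frames, and the two adjacent segments born at every direction turn (a
one-frame gap) must stay distinct or the split would be undone wholesale.
The merge is applied to sagittal as well as coronal segments
(`merge_gap=None` disables it).

Scoring is duration-only: 0 at ≤ 3 s, 100 at ≥ 8 s (about five steps at a
moderate 100 steps/min cadence), and the continuous ramp `100·(d − 3)/5`
between — chosen over the alternative `100·d/8` reading, which is
discontinuous at the 3 s anchor (it would award 37.5 to a clip defined to
score 0); `score_mode="proportional_0_8"` keeps the alternative.

## Resolution

Frames where the subject's box is narrower than 60 px *and* shorter than
80 px — thresholds below which pose estimation degrades sharply, both
configurable — are low-resolution; the score is the percentage of
acceptable frames. The conjunction is the default (`lowres_rule="or"`
available) since a narrow-but-tall subject is typically still usable.
Target-absent frames count as low-resolution by default: an undetectable
subject is unusable footage (config-disablable).

## Quality classification and feedback

The five features — multiple-persons %, overlap %, zoom flag, best
segment score (max over the two per-direction bests), resolution % — feed
a random forest with 50 estimators, unlimited depth, min split 2, min
leaf 1, no bootstrap, fixed seed. The forest's vote fraction for the good
class (the standard forest probability; no calibration is applied) scales
to `o_s = 100·P(good)`; strictly above 50 is good. Transverse videos
bypass the classifier and report a null score rather than 0 — no quality
judgment is made on footage the downstream scoring cannot use. Feedback
emits a fixed suggestion string per criterion scoring below 80 (the zoom
flag triggers on 1; clip length on the best segment score), plus both
camera-placement suggestions when neither a sagittal nor a coronal view
was identified.

Training data: the package trains on labelled synthetic videos by default
(reproducible, seeded) and accepts user-supplied labelled feature tables
(CSV) for retraining on real data via `gaitvqa train`.

## The synthetic generator

`synthgen` emulates the *detector's output*, not video: a walker template
with sinusoidal limb oscillation at ~1 stride/s, 60 Hz capture, 1920×1080
frames by default, keypoint noise sd 0.003 normalized units. Torso
proportions are solved from the requested plane's ratio regime
(`D_s = 0.3·H/√R_target`; defaults R = 0.35 sagittal, 1.4 coronal,
3.5 transverse), walking direction is encoded in the ear/nose x-order and
facing in the shoulder x-order — exactly the cues the pipeline reads.
Coronal walks ramp the apparent height across a wide far/near range
(0.45–1.45 × the configured height fraction) so the monotone trend stays
well above the noise floor of the threshold-free sign split. The bounding
box is the noise-free keypoint extent plus a 2 %-of-height margin with its
own smaller edge noise (half the keypoint sd): a detector's box head is
steadier than its individual keypoints, and deriving box edges from noisy
extremes injects extreme-value noise the printed segmentation rule has no
mechanism to absorb.

Artifacts carry exact constructional truth: injected zoom windows ramp a
scale factor about the box centroid and hold after the window (as a real
zoom does); low-resolution spans shrink the subject below both pixel
thresholds with slow (~2.5 s) ramps that stay under the zoom threshold;
a second walker loiters at the frame edge and, during overlap windows,
shifts until its box intersects the target's while the centroids stay
apart (so the tracker cannot swap identities). The truth label rule is:
good ⇔ no zoom events, at least one valid ≥ 8 s span, no low-resolution
frames, no overlap frames. Dataset generation (`generate_dataset`) draws
coronal/sagittal videos with exact label counts (`round(n·mix)` good,
default mix 0.5), cycling defect types (zoom, short clips 4–6.5 s,
low resolution, overlap) for the manual-edit class; good videos use
one or two 9–13 s legs and occasionally a benign non-overlapping
bystander (coronal only — a sagittal walker traverses the full frame
width and would brush any static bystander).

What the generator does **not** model: camera projection and perspective,
biomechanically validated gait, detector identity switches, confidence
miscalibration, duplicate detections of one person, lighting or
compression effects. Passing tests therefore demonstrate that the
algorithms implement their rules correctly and are mutually consistent,
not that the thresholds transfer to any particular camera or clinic.

## Problem sizes and determinism

The classifier check trains on 200 labelled synthetic videos and evaluates
50 held-out ones (9–22 s each at 60 Hz); property suites use 100-sequence
batches. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical
sequences, tables and model predictions.

## Known limitations

* The published overlap-detection metric row is arithmetically
  inconsistent with its own published confusion matrix (sensitivity
  14/15 = 0.93 vs. 0.94; F1 28/31 = 0.90 vs. 0.91); the metric-reproduction
  test records this as a failure rather than adjusting either side.
* The coronal zoom-elimination rule is blind to zoom-in while approaching
  (and zoom-out while receding), where trend and facing agree; the zoom
  *detector* still flags fast events, but slow same-direction zooms pass.
* A zoom event changes the subject's apparent size permanently, so the
  plane-ratio and resolution stages see post-zoom geometry as-is.
* Overall scores are vote fractions of a small forest and should be read
  ordinally, not as calibrated probabilities.
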