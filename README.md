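# gaitvqa

Automated quality assessment for clinical gait videos, computed entirely
from multi-person pose-keypoint detections.

Observational gait scoring (e.g. the Edinburgh Visual Gait Score, EVGS)
and its automated successors need video that actually supports analysis: a
sagittal or coronal view, a single unoccluded subject, no camera zooming,
at least two full strides of footage, and a subject large enough in the
frame for pose estimation to work. Checking these by hand is tedious and
subjective. `gaitvqa` scores each requirement from the per-frame output of
a multi-person pose detector (up to 6 people, 17 COCO keypoints plus a
bounding box per person, normalized coordinates) and fuses the scores into
an overall quality verdict with actionable feedback for the camera
operator. Running a pose model or decoding video is out of scope: the
input is a detection file (JSON or CSV), and a `VideoPoseAdapter` interface
is declared for third parties that want to plug a detector in.

## Method

Given a tracked target person (nearest-centroid matching across frames,
`d = min_i ((x_t − x_i)² + (y_t − y_i)²)^½` over reliable detections with
box confidence ≥ 0.5), five criterion scores are computed:

1. **Multiple persons** — percentage of frames containing only the
   target's reliable bounding box.
2. **Overlap** — percentage of frames where no other reliable box
   intersects the target's box.
3. **Zoom** — the normalized box height `h = y₂ − y₁` is Gaussian-smoothed
   (σ = 2) and step-differenced, `Δhᵢ = S_{i+s} − Sᵢ` with `s = 8` at
   60 Hz; `Δh > τ` (τ = 0.05) flags zoom-in, `Δh < −τ` zoom-out. Binary
   flag: 1 if any event.
4. **Best zoom-free clip** — the video is split into walking segments
   (coronal: at sign changes of Δh, with segments whose height trend
   contradicts the subject's facing direction dropped as zoom artifacts;
   sagittal: at walking-direction transitions read from the ear/nose
   x-order, with zoom frames excised). Segments of ≤ 3 s are rejected,
   near-adjacent same-direction segments merged, and each survivor scored
   0–100 by duration (≥ 8 s ⇒ 100).
5. **Resolution** — the box is converted to pixels; frames where the
   subject is under 60 px wide and 80 px tall are low-resolution, and
   `r_s = (1 − t_lrf/t_f)·100`.

The viewing plane is classified first from torso geometry: with shoulder
distance `D_s = |x_ls − x_rs|` and vertical shoulder-hip distances
`D_rsh`, `D_lsh`, the per-frame final ratio `R = (D_lsh·D_rsh)/D_s²` is
IQR-filtered; the filtered mean and the share of values below 0.7 decide
sagittal / coronal / transverse. Transverse (overhead) videos cannot be
gait-scored and short-circuit with their own label.

A random forest (50 trees, no bootstrap, unlimited depth) maps the
five-feature vector to good / manual-edit-required; its probability for
the good class becomes the overall score `o_s = 100·P(good)`, with
`o_s > 50` labelled good. Any criterion below 80 triggers a targeted
capture-improvement suggestion.

Because clinical gait video cannot be shared, the package ships a
synthetic-walker generator (`gaitvqa.synthgen`) that emulates the pose
detector's output — plausible keypoint kinematics, per-plane torso-ratio
regimes, direction schedules, and injectable artifacts (second walker,
overlap windows, zoom ramps, low-resolution spans) with exact
constructional ground truth — so the whole pipeline and the classifier are
testable and trainable end to end.

## Worked example

Assess a synthetic sagittal walk (12 s in each direction) with a zoom-in
burst injected at frames 300–306:

```python
from gaitvqa import (WalkerConfig, ArtifactConfig, simulate_walker,
                     inject_artifacts, assess, TargetSelection,
                     train_classifier, FeatureVector, generate_dataset)
from gaitvqa.synthgen import ZoomWindow

_, table = generate_dataset(60, seed=0)          # labelled training videos
model = train_classifier([
    (FeatureVector(r.multiple_persons_score, r.overlap_score, int(r.zoom_flag),
                   r.best_segment_score, r.resolution_score), r.label)
    for r in table.itertuples()
])

cfg = WalkerConfig(plane="sagittal",
                   direction_schedule=(("l2r", 12.0), ("r2l", 12.0)))
seq = simulate_walker(cfg, seed=42)
video = inject_artifacts(seq, ArtifactConfig(zoom_events=(
    ZoomWindow(start_frame=300, end_frame=306,
               direction="zoom_in", magnitude=0.2),)), seed=43, walker_cfg=cfg)

report, result = assess(video.sequence,
                        TargetSelection(frame_index=0, person_index=0), model)
```

Output:

```
plane: sagittal
features: FeatureVector(multiple_persons_score=100.0, overlap_score=100.0,
                        zoom_flag=1, best_segment_score=100.0,
                        resolution_score=100.0)
overall score: 0.0 label: manual_edit_required
 - Keep the camera steady and do not use zoom while recording
segments: [(0, 293, 'left_to_right', 38.0),
           (313, 719, 'left_to_right', 75.7),
           (720, 1439, 'right_to_left', 100.0)]
```

The zoom burst is detected (flag 1), the frames around it are excised —
splitting the left-to-right walk into a 4.9 s and a 6.8 s piece — while
the clean right-to-left walk still yields a full-score 12 s clip. The
forest nevertheless rejects the video (score 0: zoomed videos need manual
editing), and the feedback names the fix.

The same pipeline is available from the shell:

```bash
gaitvqa simulate --plane coronal --duration 10 --legs 2 --seed 7 --out walk.json
gaitvqa assess --in walk.json --select-person 0 --out report.json
```

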