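"""Synthetic labelled gait sequences for testing and classifier training.

Real clinical gait videos cannot be shared, so this module emulates their
pose-detection output directly: a walker whose 17 keypoints follow a
kinematically plausible template (sinusoidal limb oscillation at roughly
one stride per second, bounding box from keypoint extremes with a margin),
captured at 60 Hz by default.

The generator targets the plane-classification ratio regimes directly
rather than modelling camera projection: torso proportions are chosen so
the per-frame final ratio R lands in the band the rules assign to the
requested plane (sagittal: mean below 0.5; coronal: around 1.4; transverse:
3 or more).  Walking direction is encoded through the ear/nose x-order and
facing orientation through the shoulder x-order, exactly the cues the
segmentation stage reads.

Artifacts are injected with exact constructional ground truth: a second
walker with optional overlap windows, zoom events as bounding-box scale
ramps of a stated normalized-height magnitude, and low-resolution spans
where the subject shrinks below the pixel thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .pose_io import (
    BoundingBox,
    FrameDetections,
    Keypoint,
    PersonDetection,
    PoseSequence,
)

DEFAULT_FPS = 60.0
DEFAULT_FRAME_W = 1920
DEFAULT_FRAME_H = 1080
DEFAULT_NOISE_SD = 0.003
STRIDE_HZ = 1.0  # one stride per second, moderate walking cadence
TORSO_FRAC = 0.30  # shoulder-to-hip distance as a fraction of body height

#: default final-ratio targets per plane, inside the classification bands
PLANE_RATIO_TARGETS = {"sagittal": 0.35, "coronal": 1.4, "transverse": 3.5}

Direction = Literal["towards", "away", "l2r", "r2l"]


class ConfigError(Exception):
    """A generator configuration contradicts itself or the plane rules."""


@dataclass(frozen=True, slots=True)
class WalkerConfig:
    """One walker's capture conditions.

    ``direction_schedule`` lists (direction, duration_s) legs: towards/away
    for coronal walks, l2r/r2l for sagittal.  ``subject_height_frac`` is the
    subject's apparent height as a fraction of frame height (coronal walks
    ramp around it as the subject approaches or recedes).  ``ratio_target``
    overrides the plane's default final-ratio regime.
    """

    plane: Literal["sagittal", "coronal", "transverse"]
    direction_schedule: tuple[tuple[Direction, float], ...]
    fps: float = DEFAULT_FPS
    frame_width: int = DEFAULT_FRAME_W
    frame_height: int = DEFAULT_FRAME_H
    subject_height_frac: float = 0.6
    keypoint_noise_sd: float = DEFAULT_NOISE_SD
    ratio_target: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.direction_schedule:
            raise ConfigError("direction_schedule must have at least one leg")
        if any(d <= 0 for _, d in self.direction_schedule):
            raise ConfigError("leg durations must be positive")
        if self.keypoint_noise_sd < 0:
            raise ConfigError("keypoint_noise_sd must be >= 0")
        r = self.ratio_target if self.ratio_target is not None else PLANE_RATIO_TARGETS[self.plane]
        ok = (
            (self.plane == "sagittal" and r < 0.5)
            or (self.plane == "coronal" and 0.5 <= r < 2.0)
            or (self.plane == "transverse" and r >= 3.0)
        )
        if not ok:
            raise ConfigError(
                f"ratio target {r} incompatible with the {self.plane} regime"
            )

    @property
    def effective_ratio_target(self) -> float:
        return (
            self.ratio_target
            if self.ratio_target is not None
            else PLANE_RATIO_TARGETS[self.plane]
        )

    @property
    def n_frames(self) -> int:
        return int(round(sum(d for _, d in self.direction_schedule) * self.fps))

    def leg_frame_ranges(self) -> list[tuple[int, int, Direction]]:
        """(start, end-inclusive, direction) frame span of each leg."""
        out = []
        t = 0.0
        for direction, dur in self.direction_schedule:
            a = int(round(t * self.fps))
            t += dur
            b = min(int(round(t * self.fps)) - 1, self.n_frames - 1)
            out.append((a, b, direction))
        return out


@dataclass(frozen=True, slots=True)
class ExtraPersonConfig:
    entry_frame: int
    exit_frame: int
    overlap_windows: tuple[tuple[int, int], ...] = ()
    confidence: float = 0.9


@dataclass(frozen=True, slots=True)
class ZoomWindow:
    start_frame: int
    end_frame: int
    direction: Literal["zoom_in", "zoom_out"]
    magnitude: float  # normalized-height change across the window


@dataclass(frozen=True, slots=True)
class ArtifactConfig:
    extra_person: Optional[ExtraPersonConfig] = None
    zoom_events: tuple[ZoomWindow, ...] = ()
    lowres_windows: tuple[tuple[int, int], ...] = ()
    lowres_ramp_frames: int = 150


@dataclass(frozen=True, slots=True)
class GroundTruth:
    plane: str
    multiperson_frames: frozenset[int]
    overlap_frames: frozenset[int]
    zoom_events: tuple[ZoomWindow, ...]
    valid_segment_ranges: tuple[tuple[int, int], ...]
    low_res_frames: frozenset[int]
    quality_label: str  # good | manual_edit_required


@dataclass(frozen=True, slots=True)
class LabeledVideo:
    sequence: PoseSequence
    truth: GroundTruth


# ---------------------------------------------------------------------------
# walker kinematics


def _height_profile(cfg: WalkerConfig) -> np.ndarray:
    """Per-frame apparent body height (fraction of frame height).

    Sagittal and transverse subjects keep a constant distance from the
    camera; coronal subjects ramp between a far and a near height as they
    walk away from or towards it.  Consecutive opposite-direction legs
    chain continuously.
    """
    n = cfg.n_frames
    h = np.empty(n)
    if cfg.plane != "coronal":
        h[:] = cfg.subject_height_frac
        return h
    # wide far-to-near ramp: over a ~10 m walkway the apparent height of an
    # approaching subject grows several-fold, and the strong monotone trend
    # keeps the height-sign segmentation well above the noise floor
    h_lo = min(0.88, cfg.subject_height_frac * 0.45)
    h_hi = min(0.92, cfg.subject_height_frac * 1.45)
    for a, b, direction in cfg.leg_frame_ranges():
        ramp = np.linspace(0.0, 1.0, b - a + 1)
        if direction == "towards":
            h[a: b + 1] = h_lo + (h_hi - h_lo) * ramp
        else:
            h[a: b + 1] = h_hi - (h_hi - h_lo) * ramp
    return h


def _x_profile(cfg: WalkerConfig) -> np.ndarray:
    """Per-frame horizontal body-centre position."""
    n = cfg.n_frames
    cx = np.full(n, 0.5)
    if cfg.plane == "sagittal":
        for a, b, direction in cfg.leg_frame_ranges():
            ramp = np.linspace(0.15, 0.85, b - a + 1)
            cx[a: b + 1] = ramp if direction == "l2r" else ramp[::-1]
    else:
        t = np.arange(n) / cfg.fps
        cx += 0.01 * np.sin(2 * math.pi * 0.3 * t)  # gentle lateral sway
    return cx


def _direction_signs(cfg: WalkerConfig) -> tuple[np.ndarray, np.ndarray]:
    """(facing sign, travel sign) per frame.

    Facing sign +1 puts the left shoulder to the viewer's right (subject
    faces the camera); travel sign +1 walks left-to-right (nose leads to
    the right of the ears).
    """
    n = cfg.n_frames
    facing = np.ones(n)
    travel = np.zeros(n)
    for a, b, direction in cfg.leg_frame_ranges():
        if direction == "away":
            facing[a: b + 1] = -1.0
        elif direction == "l2r":
            travel[a: b + 1] = 1.0
        elif direction == "r2l":
            travel[a: b + 1] = -1.0
    return facing, travel


def _build_person(
    cx: float,
    cy: float,
    H: float,
    d_s: float,
    facing: float,
    travel: float,
    phase: float,
    noise: np.ndarray,
    kp_scores: np.ndarray,
    box_score: float,
    box_noise: Optional[np.ndarray] = None,
) -> PersonDetection:
    """Assemble one frame's detection from the walker template.

    ``noise`` is a (17, 2) array of additive normalized-coordinate noise.
    The box is the noise-free keypoint extent plus a 2%-of-height margin,
    perturbed by ``box_noise`` (4 values, one per edge): a detector's box
    head is steadier than its individual keypoints, so box edges get their
    own, smaller jitter rather than inheriting the keypoint extremes'.
    """
    y_top = cy - H / 2.0
    osc = math.sin(phase)
    # relative y positions down the body (fractions of H)
    rel_y = {
        "nose": 0.040, "eye": 0.045, "ear": 0.050,
        "shoulder": 0.180, "elbow": 0.300, "wrist": 0.420,
        "hip": 0.480, "knee": 0.700, "ankle": 0.950,
    }
    half_s = d_s / 2.0
    half_hip = 0.4 * d_s
    if travel != 0.0:  # side view: nose leads the ears in the travel direction
        nose_x = cx + travel * 0.045 * H
        ear_l = ear_r = cx + travel * 0.005 * H
        eye_l = eye_r = cx + travel * 0.030 * H
    else:  # front/back view: symmetric head
        nose_x = cx
        ear_l, ear_r = cx + facing * 0.045 * H, cx - facing * 0.045 * H
        eye_l, eye_r = cx + facing * 0.020 * H, cx - facing * 0.020 * H
    swing = 0.030 * H * osc
    arm = 0.020 * H * osc
    xs = [
        nose_x, eye_l, eye_r, ear_l, ear_r,
        cx + facing * half_s, cx - facing * half_s,              # shoulders
        cx + facing * half_s + arm, cx - facing * half_s - arm,  # elbows
        cx + facing * half_s - arm, cx - facing * half_s + arm,  # wrists
        cx + facing * half_hip, cx - facing * half_hip,          # hips
        cx + facing * half_hip + swing, cx - facing * half_hip - swing,
        cx + facing * half_hip - swing, cx - facing * half_hip + swing,
    ]
    ys = [
        y_top + rel_y["nose"] * H, y_top + rel_y["eye"] * H, y_top + rel_y["eye"] * H,
        y_top + rel_y["ear"] * H, y_top + rel_y["ear"] * H,
        y_top + rel_y["shoulder"] * H, y_top + rel_y["shoulder"] * H,
        y_top + rel_y["elbow"] * H, y_top + rel_y["elbow"] * H,
        y_top + rel_y["wrist"] * H + 0.01 * H * osc,
        y_top + rel_y["wrist"] * H - 0.01 * H * osc,
        y_top + rel_y["hip"] * H, y_top + rel_y["hip"] * H,
        y_top + rel_y["knee"] * H, y_top + rel_y["knee"] * H,
        y_top + rel_y["ankle"] * H, y_top + rel_y["ankle"] * H,
    ]
    clean_xs, clean_ys = np.asarray(xs), np.asarray(ys)
    xs = np.clip(clean_xs + noise[:, 1], 0.0, 1.0)
    ys = np.clip(clean_ys + noise[:, 0], 0.0, 1.0)
    kps = tuple(
        Keypoint(y=float(ys[i]), x=float(xs[i]), score=float(kp_scores[i]))
        for i in range(17)
    )
    margin = 0.02 * H
    bn = box_noise if box_noise is not None else np.zeros(4)
    ymin = max(0.0, clean_ys.min() - margin + bn[0])
    xmin = max(0.0, clean_xs.min() - margin + bn[1])
    ymax = min(1.0, clean_ys.max() + margin + bn[2])
    xmax = min(1.0, clean_xs.max() + margin + bn[3])
    box = BoundingBox(
        ymin=min(ymin, ymax), xmin=min(xmin, xmax),
        ymax=max(ymin, ymax), xmax=max(xmin, xmax),
        score=box_score,
    )
    return PersonDetection(keypoints=kps, box=box)


def simulate_walker(cfg: WalkerConfig, seed: int) -> PoseSequence:
    """Generate a single-walker sequence; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    n = cfg.n_frames
    H = _height_profile(cfg)
    cx = _x_profile(cfg)
    facing, travel = _direction_signs(cfg)
    d_s = TORSO_FRAC * H / math.sqrt(cfg.effective_ratio_target)
    phases = 2 * math.pi * STRIDE_HZ * np.arange(n) / cfg.fps
    noise = rng.normal(0.0, cfg.keypoint_noise_sd, size=(n, 17, 2))
    box_noise = rng.normal(0.0, cfg.keypoint_noise_sd / 2.0, size=(n, 4))
    kp_scores = rng.uniform(0.75, 0.95, size=(n, 17))

    frames = []
    for i in range(n):
        person = _build_person(
            cx=float(cx[i]), cy=0.5, H=float(H[i]), d_s=float(d_s[i]),
            facing=float(facing[i]), travel=float(travel[i]),
            phase=float(phases[i]), noise=noise[i], kp_scores=kp_scores[i],
            box_score=0.9, box_noise=box_noise[i],
        )
        frames.append(FrameDetections(frame_index=i, persons=(person,)))
    return PoseSequence(
        frames=tuple(frames),
        fps=cfg.fps,
        frame_width=cfg.frame_width,
        frame_height=cfg.frame_height,
        source_id=f"synthetic-{cfg.plane}-{seed}",
    )


# ---------------------------------------------------------------------------
# artifact injection


def _scale_person(p: PersonDetection, factor: float) -> PersonDetection:
    """Scale a detection about its box centroid (zoom / shrink)."""
    cx = (p.box.xmin + p.box.xmax) / 2.0
    cy = (p.box.ymin + p.box.ymax) / 2.0

    def sx(v: float) -> float:
        return min(1.0, max(0.0, cx + factor * (v - cx)))

    def sy(v: float) -> float:
        return min(1.0, max(0.0, cy + factor * (v - cy)))

    kps = tuple(Keypoint(y=sy(k.y), x=sx(k.x), score=k.score) for k in p.keypoints)
    box = BoundingBox(
        ymin=sy(p.box.ymin), xmin=sx(p.box.xmin),
        ymax=sy(p.box.ymax), xmax=sx(p.box.xmax), score=p.box.score,
    )
    return PersonDetection(keypoints=kps, box=box)


def _zoom_factor_curve(
    n: int, windows: Sequence[ZoomWindow], heights: np.ndarray
) -> np.ndarray:
    """Multiplicative scale per frame: ramps across each window and holds
    after it, as a real camera zoom would."""
    factor = np.ones(n)
    for w in windows:
        if not 0 <= w.start_frame < w.end_frame < n:
            raise ConfigError(f"zoom window {w} out of sequence bounds")
        h0 = heights[w.start_frame]
        sign = 1.0 if w.direction == "zoom_in" else -1.0
        end_factor = max(0.05, (h0 + sign * w.magnitude) / h0)
        span = w.end_frame - w.start_frame
        ramp = 1.0 + (end_factor - 1.0) * np.arange(span + 1) / span
        factor[w.start_frame: w.end_frame + 1] *= ramp
        factor[w.end_frame + 1:] *= end_factor
    return factor


def _lowres_factor_curve(
    n: int,
    windows: Sequence[tuple[int, int]],
    heights: np.ndarray,
    ramp_frames: int,
    target_height: float = 0.05,
) -> np.ndarray:
    """Scale curve that shrinks the subject below the pixel thresholds
    inside each window, with slow ramps so no zoom event is created."""
    factor = np.ones(n)
    for a, b in windows:
        if not 0 <= a <= b < n:
            raise ConfigError(f"lowres window ({a}, {b}) out of sequence bounds")
        low = target_height / np.maximum(heights[a: b + 1], 1e-6)
        factor[a: b + 1] = np.minimum(factor[a: b + 1], low)
        for i in range(max(0, a - ramp_frames), a):
            frac = (i - (a - ramp_frames)) / ramp_frames
            factor[i] = min(factor[i], 1.0 + frac * (low[0] - 1.0))
        for i in range(b + 1, min(n, b + 1 + ramp_frames)):
            frac = (i - b) / ramp_frames
            factor[i] = min(factor[i], low[-1] + frac * (1.0 - low[-1]))
    return factor


def _extra_person_frames(
    seq: PoseSequence, extra: ExtraPersonConfig, rng: np.random.Generator
) -> dict[int, PersonDetection]:
    """A second, smaller walker loitering at the frame edge; during overlap
    windows it shifts horizontally until its box intersects the target's
    while its centroid stays clearly apart (no tracker identity swap)."""
    n = len(seq)
    if not 0 <= extra.entry_frame <= extra.exit_frame < n:
        raise ConfigError("extra-person window out of sequence bounds")
    for a, b in extra.overlap_windows:
        if not extra.entry_frame <= a <= b <= extra.exit_frame:
            raise ConfigError(f"overlap window ({a}, {b}) outside presence window")
    out: dict[int, PersonDetection] = {}
    H2 = 0.45
    noise = rng.normal(0.0, DEFAULT_NOISE_SD, size=(n, 17, 2))
    box_noise = rng.normal(0.0, DEFAULT_NOISE_SD / 2.0, size=(n, 4))
    kp_scores = rng.uniform(0.75, 0.95, size=(n, 17))
    in_overlap = np.zeros(n, dtype=bool)
    for a, b in extra.overlap_windows:
        in_overlap[a: b + 1] = True
    for i in range(extra.entry_frame, extra.exit_frame + 1):
        target = seq.frames[i].persons[0] if seq.frames[i].persons else None
        if in_overlap[i] and target is not None:
            # sit just inside the target's box edge, centroids still apart
            half_w = (target.box.xmax - target.box.xmin) / 2.0
            cx2 = (target.box.xmin + target.box.xmax) / 2.0 + half_w + 0.02
        else:
            cx2 = 0.08
        person = _build_person(
            cx=min(0.95, cx2), cy=0.5, H=H2,
            d_s=TORSO_FRAC * H2 / math.sqrt(1.4),
            facing=1.0, travel=0.0,
            phase=float(i) * 0.1, noise=noise[i], kp_scores=kp_scores[i],
            box_score=extra.confidence, box_noise=box_noise[i],
        )
        out[i] = person
    return out


def _rect_intersects(a: BoundingBox, b: BoundingBox) -> bool:
    # independent of tracking.boxes_overlap: plain interval arithmetic
    return not (
        a.xmax <= b.xmin or b.xmax <= a.xmin or a.ymax <= b.ymin or b.ymax <= a.ymin
    )


def _truth_valid_ranges(
    cfg: Optional[WalkerConfig],
    n: int,
    fps: float,
    zoom_windows: Sequence[ZoomWindow],
    step: int = 8,
    min_duration_s: float = 3.0,
) -> tuple[tuple[int, int], ...]:
    """Frame spans a correct segmenter should keep: schedule legs minus
    zoom windows (padded by the differencing step), pieces above 3 s."""
    legs = (
        [(a, b) for a, b, _ in cfg.leg_frame_ranges()]
        if cfg is not None
        else [(0, n - 1)]
    )
    blocked = np.zeros(n, dtype=bool)
    for w in zoom_windows:
        blocked[max(0, w.start_frame - step): min(n, w.end_frame + step + 1)] = True
    out = []
    for a, b in legs:
        start = None
        for i in range(a, b + 2):
            free = i <= b and not blocked[i]
            if free and start is None:
                start = i
            elif not free and start is not None:
                if (i - start) / fps > min_duration_s:
                    out.append((start, i - 1))
                start = None
    return tuple(out)


def inject_artifacts(
    seq: PoseSequence,
    art: ArtifactConfig,
    seed: int,
    walker_cfg: Optional[WalkerConfig] = None,
    w_min_px: float = 60.0,
    h_min_px: float = 80.0,
) -> LabeledVideo:
    """Apply artifacts to a clean sequence and record exact ground truth.

    The quality label is derived by rule: a video is good when it has no
    zoom events, at least one valid zoom-free span of 8 s or more, no
    low-resolution frames and no overlap frames.
    """
    rng = np.random.default_rng(seed)
    n = len(seq)
    heights = np.array(
        [fr.persons[0].box.height if fr.persons else np.nan for fr in seq.frames]
    )
    if np.any(np.isnan(heights)):
        # carry forward for factor-curve arithmetic only
        last = np.nanmean(heights)
        for i in range(n):
            if np.isnan(heights[i]):
                heights[i] = last
            else:
                last = heights[i]

    factor = _zoom_factor_curve(n, art.zoom_events, heights)
    factor *= _lowres_factor_curve(
        n, art.lowres_windows, heights, art.lowres_ramp_frames
    )

    extra_frames = (
        _extra_person_frames(seq, art.extra_person, rng) if art.extra_person else {}
    )

    new_frames = []
    overlap_frames: set[int] = set()
    multiperson_frames: set[int] = set()
    low_res_frames: set[int] = set()
    for i, fr in enumerate(seq.frames):
        persons = list(fr.persons)
        if persons and factor[i] != 1.0:
            persons[0] = _scale_person(persons[0], float(factor[i]))
        if persons:
            box = persons[0].box
            b_w = box.width * seq.frame_width
            b_h = box.height * seq.frame_height
            if b_w < w_min_px and b_h < h_min_px:
                low_res_frames.add(i)
        extra = extra_frames.get(i)
        if extra is not None:
            if extra.box.score >= 0.5:
                multiperson_frames.add(i)
            if persons and _rect_intersects(persons[0].box, extra.box):
                overlap_frames.add(i)
            persons.append(extra)
        new_frames.append(FrameDetections(frame_index=i, persons=tuple(persons)))

    out_seq = PoseSequence(
        frames=tuple(new_frames),
        fps=seq.fps,
        frame_width=seq.frame_width,
        frame_height=seq.frame_height,
        source_id=seq.source_id,
    )
    valid_ranges = _truth_valid_ranges(walker_cfg, n, seq.fps, art.zoom_events)
    has_8s = any((b - a + 1) / seq.fps >= 8.0 for a, b in valid_ranges)
    good = (
        not art.zoom_events
        and has_8s
        and not low_res_frames
        and not overlap_frames
    )
    truth = GroundTruth(
        plane=walker_cfg.plane if walker_cfg else "unknown",
        multiperson_frames=frozenset(multiperson_frames),
        overlap_frames=frozenset(overlap_frames),
        zoom_events=tuple(art.zoom_events),
        valid_segment_ranges=valid_ranges,
        low_res_frames=frozenset(low_res_frames),
        quality_label="good" if good else "manual_edit_required",
    )
    return LabeledVideo(sequence=out_seq, truth=truth)


# ---------------------------------------------------------------------------
# dataset generation


_DEFECTS = ("zoom", "short_legs", "lowres", "overlap")


def _sample_video(
    plane: Literal["sagittal", "coronal"],
    want_good: bool,
    defect: str,
    rng: np.random.Generator,
) -> tuple[WalkerConfig, ArtifactConfig]:
    pair = ("towards", "away") if plane == "coronal" else ("l2r", "r2l")
    if want_good or defect != "short_legs":
        legs = tuple(
            (pair[k % 2], float(rng.uniform(9.0, 13.0)))
            for k in range(int(rng.integers(1, 3)))
        )
    else:
        legs = tuple(
            (pair[k % 2], float(rng.uniform(4.0, 6.5)))
            for k in range(int(rng.integers(3, 5)))
        )
    height_frac = 0.045 if (not want_good and defect == "lowres") else float(
        rng.uniform(0.5, 0.7)
    )
    cfg = WalkerConfig(
        plane=plane,
        direction_schedule=legs,
        subject_height_frac=height_frac,
    )
    n = cfg.n_frames
    art = ArtifactConfig()
    if want_good:
        # benign distant bystander, coronal only: a sagittal walker traverses
        # the full frame width and would eventually brush the bystander's box
        if plane == "coronal" and rng.random() < 0.3:
            entry = int(rng.integers(30, max(31, n // 3)))
            exit_ = min(n - 1, entry + int(rng.integers(60, 240)))
            art = ArtifactConfig(
                extra_person=ExtraPersonConfig(entry_frame=entry, exit_frame=exit_)
            )
        return cfg, art
    if defect == "zoom":
        start = int(rng.integers(n // 4, n // 2))
        span = int(rng.integers(4, 8))
        art = ArtifactConfig(
            zoom_events=(
                ZoomWindow(
                    start_frame=start,
                    end_frame=start + span,
                    direction="zoom_in" if rng.random() < 0.5 else "zoom_out",
                    magnitude=float(rng.uniform(0.12, 0.25)),
                ),
            )
        )
    elif defect == "overlap":
        entry = int(rng.integers(30, n // 3))
        exit_ = min(n - 31, entry + int(n * 0.6))
        n_windows = int(rng.integers(1, 3))
        windows = []
        lo = entry + 10
        for _ in range(n_windows):
            if lo + 40 >= exit_:
                break
            a = int(rng.integers(lo, exit_ - 40))
            b = min(exit_, a + int(rng.integers(30, 120)))
            windows.append((a, b))
            lo = b + 30
        art = ArtifactConfig(
            extra_person=ExtraPersonConfig(
                entry_frame=entry, exit_frame=exit_, overlap_windows=tuple(windows)
            )
        )
    # short_legs and lowres need no artifact injection beyond the config
    return cfg, art


def generate_dataset(
    n: int,
    mix: float = 0.5,
    seed: int = 0,
    planes: Sequence[Literal["sagittal", "coronal"]] = ("coronal", "sagittal"),
) -> tuple[list[LabeledVideo], pd.DataFrame]:
    """Labelled videos plus the five-feature table for classifier work.

    ``mix`` is the fraction of good videos (label counts are exact:
    ``round(n * mix)`` good).  Defect types cycle over zoom, short clips,
    low resolution and overlap.  Deterministic for a given seed.
    """
    from .pipeline import RunConfig, compute_features
    from .tracking import TargetSelection

    if n < 2:
        raise ConfigError("need n >= 2")
    n_good = int(round(n * mix))
    if n_good < 1 or n - n_good < 1:
        raise ConfigError(f"degenerate mix {mix}: both labels must be represented")
    rng = np.random.default_rng(seed)
    want_good = np.array([True] * n_good + [False] * (n - n_good))
    rng.shuffle(want_good)

    videos: list[LabeledVideo] = []
    rows = []
    run_cfg = RunConfig()
    defect_i = 0
    for i in range(n):
        plane = planes[i % len(planes)]
        defect = _DEFECTS[defect_i % len(_DEFECTS)]
        if not want_good[i]:
            defect_i += 1
        cfg, art = _sample_video(plane, bool(want_good[i]), defect, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        seq = simulate_walker(cfg, seed=sub_seed)
        video = inject_artifacts(seq, art, seed=sub_seed + 1, walker_cfg=cfg)
        videos.append(video)
        result = compute_features(
            video.sequence,
            TargetSelection(frame_index=0, mode="person_index", person_index=0),
            run_cfg,
        )
        fv = result.features
        rows.append(
            {
                "multiple_persons_score": fv.multiple_persons_score,
                "overlap_score": fv.overlap_score,
                "zoom_flag": fv.zoom_flag,
                "best_segment_score": fv.best_segment_score,
                "resolution_score": fv.resolution_score,
                "detected_plane": result.plane.value,
                "label": video.truth.quality_label,
            }
        )
    return videos, pd.DataFrame(rows)
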