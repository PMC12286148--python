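"""Zoom-artifact detection and zoom-free segment extraction/scoring.

The subject's apparent size is the normalized bounding-box height
``h = y2 - y1`` per frame.  The series is smoothed with a Gaussian kernel
(sigma = 2) and differenced at a fixed step ``s`` frames ahead,

    dh_i = S[i+s] - S[i],

so that only changes completed within ~s frames register.  ``dh > tau``
marks zoom-in, ``dh < -tau`` zoom-out (default ``tau = 0.05``; ``s = 8`` at
60 Hz, scaled with the frame rate to keep the lookahead interval constant).

Segments are carved differently per viewing plane:

* coronal — split wherever the sign of ``dh`` changes (the subject's height
  rises while approaching the camera and falls while receding); segments
  whose height trend contradicts the subject's facing direction are zoom
  artifacts and are dropped.
* sagittal — split at walking-direction transitions read from the ear/nose
  x-order; frames inside zoom events are excised.

Surviving segments shorter than 3 s (roughly two strides, the minimum for
gait scoring) are rejected; valid segments separated by fewer than 5 frames
are merged; each is scored 0-100 by duration (>= 8 s earns 100).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .pose_io import PersonDetection
from .tracking import TargetTrack

DEFAULT_TAU = 0.05
DEFAULT_STEP_AT_60HZ = 8
DEFAULT_SIGMA = 2.0
MIN_SEGMENT_S = 3.0
FULL_SCORE_S = 8.0
MERGE_GAP_FRAMES = 5
DIRECTION_SMOOTH_WINDOW = 5

SegmentLabel = Literal[
    "towards_camera", "away_from_camera", "left_to_right", "right_to_left"
]


class EmptySeriesError(Exception):
    """The target was never present, so no height series exists."""


class SeriesTooShortError(Exception):
    """The height series is shorter than the differencing step requires."""


def step_for_fps(fps: float, step_at_60hz: int = DEFAULT_STEP_AT_60HZ) -> int:
    """Differencing step scaled to keep the lookahead interval constant."""
    return max(1, round(step_at_60hz * fps / 60.0))


@dataclass(slots=True)
class HeightSeries:
    """Per-frame normalized box height, raw and smoothed."""

    normalized_height: np.ndarray
    smoothed: np.ndarray
    step: int
    tau: float
    fps: float


@dataclass(frozen=True, slots=True)
class ZoomEvent:
    """A coalesced span of zoom-flagged frames (end includes the lookahead)."""

    start_frame: int
    end_frame: int
    direction: Literal["zoom_in", "zoom_out"]

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("zoom event must span at least one frame step")


@dataclass(frozen=True, slots=True)
class Segment:
    start_frame: int
    end_frame: int  # inclusive
    duration_s: float
    label: SegmentLabel
    score: float
    valid: bool


@dataclass(frozen=True, slots=True)
class SegmentReport:
    """Valid zoom-free segments plus the summary quantities fed downstream.

    ``best_score_dir1``/``best_score_dir2`` are towards/away scores for
    coronal sequences and left-to-right/right-to-left for sagittal ones.
    """

    segments: tuple[Segment, ...]
    best_score_dir1: float
    best_score_dir2: float
    percent_valid_frames: float
    zoom_flag: int
    zoom_events: tuple[ZoomEvent, ...] = ()


def height_series(
    trk: TargetTrack,
    fps: float,
    sigma: float = DEFAULT_SIGMA,
    step: Optional[int] = None,
    tau: float = DEFAULT_TAU,
) -> HeightSeries:
    """Normalized target box height per frame, Gaussian-smoothed.

    Target-absent frames carry the last observed height forward (leading
    gaps take the first observed height); smoothing uses reflected edges.
    """
    heights = np.full(len(trk), np.nan)
    for i, entry in enumerate(trk.entries):
        if entry.present and entry.target is not None:
            heights[i] = entry.target.box.height
    if np.all(np.isnan(heights)):
        raise EmptySeriesError("target never present: no height series")
    # forward-fill, then back-fill the leading gap
    last = np.nan
    for i in range(len(heights)):
        if np.isnan(heights[i]):
            heights[i] = last
        else:
            last = heights[i]
    first_defined = heights[~np.isnan(heights)][0]
    heights[np.isnan(heights)] = first_defined
    smoothed = gaussian_filter1d(heights, sigma=sigma, mode="reflect")
    return HeightSeries(
        normalized_height=heights,
        smoothed=smoothed,
        step=step if step is not None else step_for_fps(fps),
        tau=tau,
        fps=fps,
    )


def height_diffs(hs: HeightSeries) -> np.ndarray:
    """Step differences of the smoothed series; length ``N - s``."""
    s = hs.step
    n = len(hs.smoothed)
    if n <= s:
        raise SeriesTooShortError(
            f"series of {n} frames is too short for step {s}: need at least {s + 1}"
        )
    return hs.smoothed[s:] - hs.smoothed[:-s]


def detect_zoom(hs: HeightSeries) -> tuple[list[ZoomEvent], int]:
    """Threshold the step differences into coalesced zoom events.

    Frame ``i`` with ``dh_i > tau`` opens/extends a zoom-in span (``< -tau``
    zoom-out); an event covers the first flagged frame through the last
    flagged frame plus the lookahead step.  Returns the events and the
    binary zoom flag (1 iff any event).
    """
    dh = height_diffs(hs)
    marks = np.where(dh > hs.tau, 1, np.where(dh < -hs.tau, -1, 0))
    events: list[ZoomEvent] = []
    run_start = None
    run_dir = 0
    for i, m in enumerate(np.append(marks, 0)):  # sentinel closes a trailing run
        if m == run_dir:
            continue
        if run_dir != 0 and run_start is not None:
            events.append(
                ZoomEvent(
                    start_frame=run_start,
                    end_frame=(i - 1) + hs.step,
                    direction="zoom_in" if run_dir > 0 else "zoom_out",
                )
            )
        run_start, run_dir = (i, m) if m != 0 else (None, 0)
    return events, int(bool(events))


def score_segment(
    duration_s: float,
    mode: Literal["piecewise", "proportional_0_8"] = "piecewise",
) -> float:
    """Duration-based 0-100 quality score for one segment.

    A segment of 3 s or less scores 0 (two strides is the floor for gait
    scoring); 8 s or more scores 100 (about five steps at moderate walking
    cadence).  Between the anchors the default mapping is the continuous
    linear ramp ``100 * (d - 3) / 5``; ``proportional_0_8`` instead scales
    on the 0-8 s axis, ``100 * d / 8`` (still 0 at or below 3 s).
    """
    if duration_s < 0:
        raise ValueError(f"negative duration {duration_s}")
    if duration_s <= MIN_SEGMENT_S:
        return 0.0
    if duration_s >= FULL_SCORE_S:
        return 100.0
    if mode == "proportional_0_8":
        return 100.0 * duration_s / FULL_SCORE_S
    return 100.0 * (duration_s - MIN_SEGMENT_S) / (FULL_SCORE_S - MIN_SEGMENT_S)


def walking_direction(
    det: PersonDetection, kp_min_score: float = 0.5
) -> Optional[Literal["left_to_right", "right_to_left"]]:
    """Walking direction for a sagittal view from the ear/nose x-order.

    Ears to the right of the nose mean the subject faces left (walking
    right-to-left) and vice versa.  Returns ``None`` when both ears are
    below the keypoint-confidence floor or the x-coordinates tie exactly;
    callers fall back to the previous frame's direction.
    """
    nose = det.keypoint("nose")
    ears = [
        kp
        for kp in (det.keypoint("left_ear"), det.keypoint("right_ear"))
        if kp.score >= kp_min_score
    ]
    if not ears:
        return None
    ear_x = sum(kp.x for kp in ears) / len(ears)
    if ear_x > nose.x:
        return "right_to_left"
    if ear_x < nose.x:
        return "left_to_right"
    return None


# ---------------------------------------------------------------------------
# internal segmentation machinery


def _segment_signs(dh: np.ndarray, n_frames: int) -> np.ndarray:
    """Per-frame trend sign; zeros continue the previous sign, frames past
    the differenced range continue the final sign."""
    signs = np.sign(dh)
    prev = 0.0
    for i in range(len(signs)):
        if signs[i] == 0.0:
            signs[i] = prev
        else:
            prev = signs[i]
    # leading zeros adopt the first nonzero sign
    nz = np.flatnonzero(signs)
    if nz.size:
        signs[: nz[0]] = signs[nz[0]]
    out = np.zeros(n_frames)
    out[: len(signs)] = signs
    if len(signs) < n_frames and len(signs) > 0:
        out[len(signs):] = signs[-1]
    return out


def _runs(values: Sequence) -> list[tuple[int, int]]:
    """(start, end-inclusive) runs of equal consecutive values."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i - 1))
            start = i
    return runs


def _majority_orientation(
    trk: TargetTrack, start: int, end: int
) -> Optional[Literal["towards_camera", "away_from_camera"]]:
    """Facing direction by shoulder x-order, majority over the span.

    Left shoulder appearing to the right of the right shoulder means the
    subject faces the camera (front -> walking towards it in a coronal walk).
    """
    votes = Counter()
    for i in range(start, end + 1):
        entry = trk.entries[i]
        if not entry.present or entry.target is None:
            continue
        ls = entry.target.keypoint("left_shoulder").x
        rs = entry.target.keypoint("right_shoulder").x
        if ls > rs:
            votes["towards_camera"] += 1
        elif ls < rs:
            votes["away_from_camera"] += 1
    if not votes:
        return None
    return votes.most_common(1)[0][0]


def _merge_segments(
    segments: list[Segment],
    fps: float,
    gap: int = MERGE_GAP_FRAMES,
    score_mode: Literal["piecewise", "proportional_0_8"] = "piecewise",
) -> list[Segment]:
    """Iteratively merge valid segments separated by fewer than ``gap``
    frames, left to right; the merged span keeps the first start and the
    last end.

    Only same-direction segments merge: the rule exists to re-join a walk
    interrupted by eliminated zoom frames, and two adjacent segments born
    from a direction turn (gap of one frame) must stay distinct.
    """
    if not segments:
        return []
    merged = [segments[0]]
    for seg in segments[1:]:
        prev = merged[-1]
        if seg.label == prev.label and seg.start_frame - prev.end_frame < gap:
            start, end = prev.start_frame, seg.end_frame
            duration = (end - start + 1) / fps
            merged[-1] = Segment(
                start_frame=start,
                end_frame=end,
                duration_s=duration,
                label=prev.label,
                score=score_segment(duration, mode=score_mode),
                valid=True,
            )
        else:
            merged.append(seg)
    return merged


def _finalize_report(
    segments: list[Segment],
    dir1: SegmentLabel,
    dir2: SegmentLabel,
    n_frames: int,
    zoom_events: list[ZoomEvent],
    zoom_flag: int,
) -> SegmentReport:
    best1 = max((s.score for s in segments if s.label == dir1), default=0.0)
    best2 = max((s.score for s in segments if s.label == dir2), default=0.0)
    valid_frames = sum(s.end_frame - s.start_frame + 1 for s in segments)
    return SegmentReport(
        segments=tuple(segments),
        best_score_dir1=best1,
        best_score_dir2=best2,
        percent_valid_frames=100.0 * valid_frames / n_frames if n_frames else 0.0,
        zoom_flag=zoom_flag,
        zoom_events=tuple(zoom_events),
    )


def segment_coronal(
    trk: TargetTrack,
    hs: HeightSeries,
    fps: float,
    min_duration_s: float = MIN_SEGMENT_S,
    merge_gap: int = MERGE_GAP_FRAMES,
    score_mode: Literal["piecewise", "proportional_0_8"] = "piecewise",
) -> SegmentReport:
    """Zoom-free segment extraction for a coronal (front/back view) walk.

    Splits at sign changes of the height trend, labels each span by the
    majority facing direction, drops spans whose trend contradicts that
    direction (zoom artifacts: approaching while shrinking, receding while
    growing), rejects spans of ``min_duration_s`` or less, merges
    near-adjacent survivors and scores them by duration.
    """
    n = len(trk)
    dh = height_diffs(hs)
    signs = _segment_signs(dh, n)
    zoom_events, zoom_flag = detect_zoom(hs)

    candidates: list[Segment] = []
    for start, end in _runs(list(signs)):
        orientation = _majority_orientation(trk, start, end)
        if orientation is None:
            continue
        sign = signs[start]
        is_zoom = (orientation == "towards_camera" and sign < 0) or (
            orientation == "away_from_camera" and sign > 0
        )
        if is_zoom:
            continue
        duration = (end - start + 1) / fps
        if duration <= min_duration_s:
            continue
        candidates.append(
            Segment(
                start_frame=start,
                end_frame=end,
                duration_s=duration,
                label=orientation,
                score=score_segment(duration, mode=score_mode),
                valid=True,
            )
        )

    merged = _merge_segments(candidates, fps=fps, gap=merge_gap, score_mode=score_mode)
    return _finalize_report(
        merged, "towards_camera", "away_from_camera", n, zoom_events, zoom_flag
    )


def _direction_per_frame(
    trk: TargetTrack, window: int = DIRECTION_SMOOTH_WINDOW
) -> list[Optional[str]]:
    raw: list[Optional[str]] = []
    prev: Optional[str] = None
    for entry in trk.entries:
        d = None
        if entry.present and entry.target is not None:
            d = walking_direction(entry.target)
        if d is None:
            d = prev  # tie or undefined: carry the previous direction
        else:
            prev = d
        raw.append(d)
    # majority smoothing over a centred window of defined values
    half = window // 2
    smoothed: list[Optional[str]] = []
    for i in range(len(raw)):
        votes = Counter(
            d for d in raw[max(0, i - half): i + half + 1] if d is not None
        )
        smoothed.append(votes.most_common(1)[0][0] if votes else None)
    return smoothed


def segment_sagittal(
    trk: TargetTrack,
    hs: HeightSeries,
    fps: float,
    min_duration_s: float = MIN_SEGMENT_S,
    merge_gap: Optional[int] = MERGE_GAP_FRAMES,
    score_mode: Literal["piecewise", "proportional_0_8"] = "piecewise",
) -> SegmentReport:
    """Zoom-free segment extraction for a sagittal (side view) walk.

    Splits at transitions of the per-frame walking direction (majority-
    smoothed over a 5-frame window), excises frames ``i..i+s`` wherever
    ``|dh_i| > tau`` (zoom of either sign), rejects short spans, merges
    near-adjacent survivors (set ``merge_gap=None`` to disable) and scores
    by duration.
    """
    n = len(trk)
    dh = height_diffs(hs)
    zoom_events, zoom_flag = detect_zoom(hs)

    zoom_mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(np.abs(dh) > hs.tau):
        zoom_mask[i: i + hs.step + 1] = True

    directions = _direction_per_frame(trk)
    candidates: list[Segment] = []
    for start, end in _runs(directions):
        label = directions[start]
        if label is None:
            continue
        # re-split around excised zoom frames
        keep = ~zoom_mask[start: end + 1]
        for rs, re in _runs(list(keep)):
            if not keep[rs]:
                continue
            a, b = start + rs, start + re
            duration = (b - a + 1) / fps
            if duration <= min_duration_s:
                continue
            candidates.append(
                Segment(
                    start_frame=a,
                    end_frame=b,
                    duration_s=duration,
                    label=label,  # type: ignore[arg-type]
                    score=score_segment(duration, mode=score_mode),
                    valid=True,
                )
            )

    if merge_gap is not None:
        candidates = _merge_segments(
            candidates, fps=fps, gap=merge_gap, score_mode=score_mode
        )
    return _finalize_report(
        candidates, "left_to_right", "right_to_left", n, zoom_events, zoom_flag
    )
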