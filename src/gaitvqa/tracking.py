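"""Target-person selection and centroid tracking, plus the multiple-persons
and overlap quality metrics.

The target is followed across frames by nearest-centroid matching: for each
frame the reliable detection whose bounding-box centroid has the smallest
Euclidean distance to the target's centroid in the previous frame is taken
to be the target,

    d = min_i sqrt((x_t - x_i)^2 + (y_t - y_i)^2),   i = 1..n.

Detections whose box confidence falls below ``min_confidence`` (default 0.5)
are eliminated before any matching or counting.  Both quality metrics are
frame percentages: the share of frames without a second reliable person, and
the share of frames where no other reliable box overlaps the target's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .pose_io import BoundingBox, FrameDetections, PersonDetection, PoseSequence

DEFAULT_MIN_CONFIDENCE = 0.5


class SelectionError(Exception):
    """The requested target does not exist among reliable detections."""


class UndefinedMetricError(Exception):
    """A frame-percentage metric was requested on a zero-length sequence."""


@dataclass(frozen=True, slots=True)
class TargetSelection:
    """Non-interactive replacement for click-to-select: pick the target at
    ``frame_index`` either by reliable-detection index or by the reliable
    detection whose centroid is nearest to a given normalized point."""

    frame_index: int
    mode: Literal["person_index", "nearest_point"] = "person_index"
    person_index: Optional[int] = None
    point: Optional[tuple[float, float]] = None  # (x, y) normalized

    def __post_init__(self) -> None:
        if self.mode == "person_index" and self.person_index is None:
            raise ValueError("mode=person_index requires person_index")
        if self.mode == "nearest_point" and self.point is None:
            raise ValueError("mode=nearest_point requires point")


@dataclass(frozen=True, slots=True)
class TrackEntry:
    target: Optional[PersonDetection]
    present: bool
    n_reliable_detections: int
    d_min: Optional[float]


@dataclass(frozen=True, slots=True)
class TargetTrack:
    """Per-frame resolved target detection; one entry per sequence frame."""

    entries: tuple[TrackEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> TrackEntry:
        return self.entries[i]


@dataclass(frozen=True, slots=True)
class TrackMetrics:
    multiple_persons_score: float
    overlap_score: float
    multiperson_frames: int
    overlap_frames: int
    total_frames: int


def filter_reliable(
    frame: FrameDetections, min_confidence: float = DEFAULT_MIN_CONFIDENCE
) -> FrameDetections:
    """Drop detections with box confidence below the minimum (inclusive keep:
    a score exactly at the threshold is retained)."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence={min_confidence} outside [0, 1]")
    kept = tuple(p for p in frame.persons if p.box.score >= min_confidence)
    return FrameDetections(frame_index=frame.frame_index, persons=kept)


def centroid(box: BoundingBox) -> tuple[float, float]:
    """Bounding-box centre as normalized (x, y)."""
    return ((box.xmin + box.xmax) / 2.0, (box.ymin + box.ymax) / 2.0)


def match_target(
    prev_centroid: tuple[float, float], candidates: Sequence[PersonDetection]
) -> tuple[int, float]:
    """Nearest-centroid match; ties resolve to the lowest candidate index.

    Raises :class:`SelectionError` on an empty candidate list, which callers
    treat as "target absent this frame".
    """
    if not candidates:
        raise SelectionError("no candidates: target absent this frame")
    px, py = prev_centroid
    best_i, best_d = 0, math.inf
    for i, person in enumerate(candidates):
        cx, cy = centroid(person.box)
        d = math.hypot(cx - px, cy - py)
        if d < best_d:
            best_i, best_d = i, d
    return best_i, best_d


def _resolve_selection(
    frame: FrameDetections, selection: TargetSelection, min_confidence: float
) -> PersonDetection:
    reliable = filter_reliable(frame, min_confidence).persons
    if selection.mode == "person_index":
        idx = selection.person_index
        if idx is None or not 0 <= idx < len(reliable):
            raise SelectionError(
                f"person_index {idx} not among {len(reliable)} reliable "
                f"detections in frame {frame.frame_index}"
            )
        return reliable[idx]
    if not reliable:
        raise SelectionError(
            f"no reliable detections in selection frame {frame.frame_index}"
        )
    x, y = selection.point  # type: ignore[misc]
    i, _ = match_target((x, y), reliable)
    return reliable[i]


def track(
    seq: PoseSequence,
    selection: TargetSelection,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    forward_only: bool = False,
) -> TargetTrack:
    """Follow the selected person across the whole sequence.

    A forward pass runs from the selection frame to the last frame; unless
    ``forward_only`` is set, a backward pass also covers frames before the
    selection frame so whole-video metrics are defined.  Frames with no
    reliable detections get ``present=False`` and the previous centroid is
    carried unchanged (no extrapolation); re-acquisition after a gap is plain
    nearest-centroid matching with no distance gate.
    """
    n = len(seq)
    if not 0 <= selection.frame_index < n:
        raise SelectionError(
            f"selection frame {selection.frame_index} outside sequence of {n} frames"
        )
    target0 = _resolve_selection(seq.frames[selection.frame_index], selection, min_confidence)

    entries: list[Optional[TrackEntry]] = [None] * n

    def _pass(indices: Sequence[int], start_centroid: tuple[float, float]) -> None:
        prev = start_centroid
        for i in indices:
            frame = seq.frames[i]
            reliable = filter_reliable(frame, min_confidence).persons
            if not reliable:
                entries[i] = TrackEntry(None, False, 0, None)
                continue
            j, d = match_target(prev, reliable)
            chosen = reliable[j]
            prev = centroid(chosen.box)
            entries[i] = TrackEntry(chosen, True, len(reliable), d)

    c0 = centroid(target0.box)
    k = selection.frame_index
    entries[k] = TrackEntry(
        target0, True, len(filter_reliable(seq.frames[k], min_confidence).persons), 0.0
    )
    _pass(range(k + 1, n), c0)
    if forward_only:
        for i in range(k):
            n_rel = len(filter_reliable(seq.frames[i], min_confidence).persons)
            entries[i] = TrackEntry(None, False, n_rel, None)
    else:
        _pass(range(k - 1, -1, -1), c0)
    return TargetTrack(entries=tuple(e for e in entries if e is not None))


def multiple_persons_metric(
    seq: PoseSequence,
    trk: TargetTrack,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> TrackMetrics:
    """Percentage of frames in which only the target's reliable box appears.

    A frame counts as a multi-person frame when it holds two or more
    reliable detections; lower-confidence detections never count.
    """
    total = len(seq)
    if total == 0:
        raise UndefinedMetricError("multiple-persons metric undefined on empty sequence")
    multi = sum(1 for e in trk.entries if e.n_reliable_detections >= 2)
    score = 100.0 * (total - multi) / total
    overlap = _count_overlap_frames(seq, trk, min_confidence)
    return TrackMetrics(
        multiple_persons_score=score,
        overlap_score=100.0 * (total - overlap) / total,
        multiperson_frames=multi,
        overlap_frames=overlap,
        total_frames=total,
    )


def boxes_overlap(
    a: BoundingBox, b: BoundingBox, rule: Literal["and", "or"] = "and"
) -> bool:
    """Whether two boxes overlap.

    ``rule="and"`` (default) is geometric rectangle intersection: the
    x-interval condition and the y-interval condition must both hold.
    ``rule="or"`` flags the frame when either condition alone holds, which
    treats any horizontal or vertical range intersection as overlap.
    """
    x_cond = a.xmin < b.xmax and a.xmax > b.xmin
    y_cond = a.ymin < b.ymax and a.ymax > b.ymin
    return (x_cond and y_cond) if rule == "and" else (x_cond or y_cond)


def _count_overlap_frames(
    seq: PoseSequence,
    trk: TargetTrack,
    min_confidence: float,
    rule: Literal["and", "or"] = "and",
) -> int:
    flagged = 0
    for frame, entry in zip(seq.frames, trk.entries):
        if not entry.present or entry.target is None:
            continue
        reliable = filter_reliable(frame, min_confidence).persons
        others = [p for p in reliable if p is not entry.target]
        if any(boxes_overlap(entry.target.box, p.box, rule=rule) for p in others):
            flagged += 1
    return flagged


def overlap_metric(
    seq: PoseSequence,
    trk: TargetTrack,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    rule: Literal["and", "or"] = "and",
) -> TrackMetrics:
    """Percentage of frames where no other reliable box overlaps the target.

    Target-absent frames are never flagged but stay in the denominator.
    """
    total = len(seq)
    if total == 0:
        raise UndefinedMetricError("overlap metric undefined on empty sequence")
    overlap = _count_overlap_frames(seq, trk, min_confidence, rule=rule)
    multi = sum(1 for e in trk.entries if e.n_reliable_detections >= 2)
    return TrackMetrics(
        multiple_persons_score=100.0 * (total - multi) / total,
        overlap_score=100.0 * (total - overlap) / total,
        multiperson_frames=multi,
        overlap_frames=overlap,
        total_frames=total,
    )


def track_metrics(
    seq: PoseSequence,
    trk: TargetTrack,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    overlap_rule: Literal["and", "or"] = "and",
) -> TrackMetrics:
    """Both tracking metrics in one pass."""
    return overlap_metric(seq, trk, min_confidence, rule=overlap_rule)
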