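"""Canonical data model for multi-person pose detections and file I/O.

The framework consumes per-frame detections in the MoveNet Multipose
Lightning layout: up to six persons per frame, each with 17 named COCO
keypoints (normalized ``y, x, score``) and a bounding box (normalized
``ymin, xmin, ymax, xmax, score``).  Coordinates are normalized to the
frame, origin at the top-left, y increasing downward.  All downstream
geometry works in these normalized units; only the resolution module
converts to pixels.

Two serialisations are supported:

* JSON — ``{"fps", "frame_width", "frame_height", "source_id",
  "frames": [{"frame_index", "persons": [{"keypoints": [[y,x,score]*17],
  "box": [ymin,xmin,ymax,xmax,score]}]}]}``
* CSV — one row per person-frame (UTF-8); empty frames are kept as rows
  with ``person_index == -1`` so sequences round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: COCO / MoveNet keypoint order; index -> anatomical landmark.
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

KEYPOINT_INDEX: dict[str, int] = {n: i for i, n in enumerate(KEYPOINT_NAMES)}

MAX_PERSONS_PER_FRAME = 6


class PoseIOError(Exception):
    """Base error for detection-file problems."""


class ParseError(PoseIOError):
    """Malformed detection file; message names the offending frame."""


class MetadataError(PoseIOError):
    """Missing or invalid sequence metadata (fps, frame size)."""


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if math.isnan(value):
        raise ValueError(f"{name} is NaN")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")
    return value


@dataclass(frozen=True, slots=True)
class Keypoint:
    """One landmark: normalized position and detection confidence."""

    y: float
    x: float
    score: float

    def __post_init__(self) -> None:
        _check_unit(self.y, "y")
        _check_unit(self.x, "x")
        _check_unit(self.score, "score")


@dataclass(frozen=True, slots=True)
class BoundingBox:
    """Axis-aligned person box in normalized coordinates.

    Maps to corner notation as x1=xmin, y1=ymin, x2=xmax, y2=ymax
    (x1 left edge, y1 top edge, x2 right edge, y2 bottom edge).
    """

    ymin: float
    xmin: float
    ymax: float
    xmax: float
    score: float

    def __post_init__(self) -> None:
        for name in ("ymin", "xmin", "ymax", "xmax", "score"):
            _check_unit(getattr(self, name), name)
        if self.ymin > self.ymax:
            raise ValueError(f"ymin={self.ymin} > ymax={self.ymax}")
        if self.xmin > self.xmax:
            raise ValueError(f"xmin={self.xmin} > xmax={self.xmax}")

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def width(self) -> float:
        return self.xmax - self.xmin


@dataclass(frozen=True, slots=True)
class PersonDetection:
    """One person in one frame: 17 keypoints plus the bounding box."""

    keypoints: tuple[Keypoint, ...]
    box: BoundingBox

    def __post_init__(self) -> None:
        if len(self.keypoints) != len(KEYPOINT_NAMES):
            raise ValueError(
                f"expected {len(KEYPOINT_NAMES)} keypoints, got {len(self.keypoints)}"
            )

    def keypoint(self, name: str) -> Keypoint:
        """Look up a keypoint by its COCO name, e.g. ``left_shoulder``."""
        return self.keypoints[KEYPOINT_INDEX[name]]


@dataclass(frozen=True, slots=True)
class FrameDetections:
    """All detections in one frame; zero persons is a legal frame."""

    frame_index: int
    persons: tuple[PersonDetection, ...] = ()

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index={self.frame_index} < 0")
        if len(self.persons) > MAX_PERSONS_PER_FRAME:
            raise ValueError(
                f"frame {self.frame_index}: {len(self.persons)} persons exceeds "
                f"the {MAX_PERSONS_PER_FRAME}-person cap"
            )


@dataclass(frozen=True, slots=True)
class PoseSequence:
    """Ordered frames of detections plus capture metadata.

    Frame indices are contiguous ``0..N-1``; ``fps`` and the pixel frame
    dimensions are required for duration and resolution computations.
    """

    frames: tuple[FrameDetections, ...]
    fps: float
    frame_width: int
    frame_height: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise MetadataError(f"fps={self.fps} must be > 0")
        if self.frame_width < 1 or self.frame_height < 1:
            raise MetadataError(
                f"frame size {self.frame_width}x{self.frame_height} must be >= 1px"
            )
        for i, fr in enumerate(self.frames):
            if fr.frame_index != i:
                raise ValueError(
                    f"frame indices must be contiguous 0..N-1; "
                    f"position {i} holds frame_index {fr.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)


class VideoPoseAdapter:
    """Interface for third-party adapters that run pose estimation on video.

    Not implemented here: decoding video and running a pose model are out
    of scope.  Adapters must return coordinates already normalized to the
    original frame (not to any padded model input).
    """

    def extract(self, video_path: str | Path) -> PoseSequence:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# construction helpers


def person_from_movenet_vector(vec: Sequence[float]) -> PersonDetection:
    """Decode one 56-float MoveNet Multipose person vector.

    Layout: 17 x (y, x, score) followed by (ymin, xmin, ymax, xmax, score).
    """
    if len(vec) != 56:
        raise ValueError(f"MoveNet person vector must have 56 values, got {len(vec)}")
    kps = tuple(
        Keypoint(y=vec[3 * i], x=vec[3 * i + 1], score=vec[3 * i + 2])
        for i in range(17)
    )
    b = vec[51:56]
    box = BoundingBox(ymin=b[0], xmin=b[1], ymax=b[2], xmax=b[3], score=b[4])
    return PersonDetection(keypoints=kps, box=box)


def _clamp_unit(value: float, where: str) -> float:
    if math.isnan(value):
        raise ParseError(f"NaN coordinate at {where}")
    if value < 0.0 or value > 1.0:
        logger.warning("clamping out-of-range value %s at %s", value, where)
        return min(1.0, max(0.0, value))
    return value


def _person_from_json(obj: dict, where: str) -> PersonDetection:
    try:
        raw_kps = obj["keypoints"]
        raw_box = obj["box"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"missing keypoints/box at {where}") from exc
    if len(raw_kps) != 17:
        raise ParseError(f"{where}: expected 17 keypoints, got {len(raw_kps)}")
    kps = tuple(
        Keypoint(
            y=_clamp_unit(kp[0], f"{where} kp{i}.y"),
            x=_clamp_unit(kp[1], f"{where} kp{i}.x"),
            score=_clamp_unit(kp[2], f"{where} kp{i}.score"),
        )
        for i, kp in enumerate(raw_kps)
    )
    if len(raw_box) != 5:
        raise ParseError(f"{where}: box must have 5 values")
    box = BoundingBox(
        ymin=_clamp_unit(raw_box[0], f"{where} box.ymin"),
        xmin=_clamp_unit(raw_box[1], f"{where} box.xmin"),
        ymax=_clamp_unit(raw_box[2], f"{where} box.ymax"),
        xmax=_clamp_unit(raw_box[3], f"{where} box.xmax"),
        score=_clamp_unit(raw_box[4], f"{where} box.score"),
    )
    return PersonDetection(keypoints=kps, box=box)


def _sequence_from_frames(
    frames: list[FrameDetections], fps, frame_width, frame_height, source_id
) -> PoseSequence:
    # never reorder beyond the frame_index sort key; reindex to 0..N-1
    frames = sorted(frames, key=lambda f: f.frame_index)
    seen = [f.frame_index for f in frames]
    if len(set(seen)) != len(seen):
        raise ParseError("duplicate frame_index values in detection file")
    reindexed = tuple(
        FrameDetections(frame_index=i, persons=f.persons) for i, f in enumerate(frames)
    )
    try:
        fps = float(fps)
    except (TypeError, ValueError) as exc:
        raise MetadataError(f"invalid fps: {fps!r}") from exc
    return PoseSequence(
        frames=reindexed,
        fps=fps,
        frame_width=int(frame_width),
        frame_height=int(frame_height),
        source_id=str(source_id or ""),
    )


# ---------------------------------------------------------------------------
# readers / writers


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in {"json", "csv"}:
            raise ValueError(f"unknown format {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in {"json", "csv"} else "json"


def read_detections(path: str | Path, format: str | None = None) -> PoseSequence:
    """Load a detection file into a validated :class:`PoseSequence`.

    Out-of-range coordinates are clamped to [0, 1] with a logged warning;
    frames with an empty ``persons`` array are legal.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if "fps" not in data:
        raise MetadataError(f"{path}: missing fps")
    frames = []
    for raw in data.get("frames", []):
        idx = raw.get("frame_index")
        if idx is None:
            raise ParseError(f"{path}: frame without frame_index")
        where = f"{path} frame {idx}"
        persons = tuple(
            _person_from_json(p, where) for p in (raw.get("persons") or [])
        )
        try:
            frames.append(FrameDetections(frame_index=int(idx), persons=persons))
        except ValueError as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return _sequence_from_frames(
        frames,
        data.get("fps"),
        data.get("frame_width", 0),
        data.get("frame_height", 0),
        data.get("source_id", ""),
    )


def write_detections(
    seq: PoseSequence, path: str | Path, format: str | None = None
) -> Path:
    """Serialise a sequence losslessly; returns the written path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _write_csv(seq, path)
    payload = {
        "fps": seq.fps,
        "frame_width": seq.frame_width,
        "frame_height": seq.frame_height,
        "source_id": seq.source_id,
        "frames": [
            {
                "frame_index": fr.frame_index,
                "persons": [
                    {
                        "keypoints": [[kp.y, kp.x, kp.score] for kp in p.keypoints],
                        "box": [p.box.ymin, p.box.xmin, p.box.ymax, p.box.xmax, p.box.score],
                    }
                    for p in fr.persons
                ],
            }
            for fr in seq.frames
        ],
    }
    path.write_text(json.dumps(payload))
    return path


_CSV_META = ["fps", "frame_width", "frame_height", "source_id"]


def _csv_columns() -> list[str]:
    cols = ["frame_index", "person_index"]
    for name in KEYPOINT_NAMES:
        cols += [f"{name}_y", f"{name}_x", f"{name}_score"]
    cols += ["box_ymin", "box_xmin", "box_ymax", "box_xmax", "box_score"]
    return cols + _CSV_META


def _write_csv(seq: PoseSequence, path: Path) -> Path:
    rows = []
    meta = [seq.fps, seq.frame_width, seq.frame_height, seq.source_id]
    for fr in seq.frames:
        if not fr.persons:
            rows.append([fr.frame_index, -1] + [float("nan")] * 56 + meta)
        for pi, p in enumerate(fr.persons):
            vals: list[float] = []
            for kp in p.keypoints:
                vals += [kp.y, kp.x, kp.score]
            vals += [p.box.ymin, p.box.xmin, p.box.ymax, p.box.xmax, p.box.score]
            rows.append([fr.frame_index, pi] + vals + meta)
    pd.DataFrame(rows, columns=_csv_columns()).to_csv(path, index=False)
    return path


def _read_csv(path: Path) -> PoseSequence:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser types
        raise ParseError(f"{path}: invalid CSV: {exc}") from exc
    missing = set(_csv_columns()) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise MetadataError(f"{path}: empty CSV carries no sequence metadata")
    meta = df.iloc[0]
    frames: list[FrameDetections] = []
    for idx, group in df.groupby("frame_index", sort=True):
        persons = []
        for _, row in group.sort_values("person_index").iterrows():
            if int(row["person_index"]) < 0:
                continue
            where = f"{path} frame {idx}"
            kps = tuple(
                Keypoint(
                    y=_clamp_unit(row[f"{n}_y"], f"{where} {n}.y"),
                    x=_clamp_unit(row[f"{n}_x"], f"{where} {n}.x"),
                    score=_clamp_unit(row[f"{n}_score"], f"{where} {n}.score"),
                )
                for n in KEYPOINT_NAMES
            )
            box = BoundingBox(
                ymin=_clamp_unit(row["box_ymin"], where),
                xmin=_clamp_unit(row["box_xmin"], where),
                ymax=_clamp_unit(row["box_ymax"], where),
                xmax=_clamp_unit(row["box_xmax"], where),
                score=_clamp_unit(row["box_score"], where),
            )
            persons.append(PersonDetection(keypoints=kps, box=box))
        try:
            frames.append(FrameDetections(frame_index=int(idx), persons=tuple(persons)))
        except ValueError as exc:
            raise ParseError(f"{path} frame {idx}: {exc}") from exc
    source = meta["source_id"]
    if isinstance(source, float) and math.isnan(source):
        source = ""
    return _sequence_from_frames(
        frames, meta["fps"], meta["frame_width"], meta["frame_height"], source
    )
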