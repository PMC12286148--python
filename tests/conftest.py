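"""Shared builders for hand-crafted detections and sequences."""

from __future__ import annotations

import numpy as np
import pytest

from gaitvqa.pose_io import (
    BoundingBox,
    FrameDetections,
    KEYPOINT_NAMES,
    Keypoint,
    PersonDetection,
    PoseSequence,
)


def make_person(
    box=(0.2, 0.4, 0.8, 0.6, 0.9),
    kp_overrides: dict[str, tuple[float, float]] | None = None,
    kp_score: float = 0.9,
) -> PersonDetection:
    """A detection with keypoints at the box centre unless overridden.

    ``kp_overrides`` maps keypoint name -> (x, y) normalized position.
    """
    ymin, xmin, ymax, xmax, score = box
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    overrides = kp_overrides or {}
    kps = []
    for name in KEYPOINT_NAMES:
        if name in overrides:
            x, y = overrides[name]
        else:
            x, y = cx, cy
        kps.append(Keypoint(y=y, x=x, score=kp_score))
    return PersonDetection(
        keypoints=tuple(kps),
        box=BoundingBox(ymin=ymin, xmin=xmin, ymax=ymax, xmax=xmax, score=score),
    )


def make_sequence(
    frames_persons: list[list[PersonDetection]],
    fps: float = 60.0,
    frame_width: int = 1920,
    frame_height: int = 1080,
) -> PoseSequence:
    frames = tuple(
        FrameDetections(frame_index=i, persons=tuple(persons))
        for i, persons in enumerate(frames_persons)
    )
    return PoseSequence(
        frames=frames, fps=fps, frame_width=frame_width, frame_height=frame_height
    )


def random_sequence(
    rng: np.random.Generator,
    n_frames: int = 10,
    max_persons: int = 6,
    fps: float = 60.0,
) -> PoseSequence:
    """Random valid sequence for round-trip and tracking-oracle tests."""
    frames = []
    for _ in range(n_frames):
        persons = []
        for _ in range(rng.integers(0, max_persons + 1)):
            y0, x0 = rng.uniform(0.0, 0.7, size=2)
            h, w = rng.uniform(0.05, 0.3, size=2)
            box = (y0, x0, min(1.0, y0 + h), min(1.0, x0 + w), rng.uniform(0.2, 1.0))
            persons.append(make_person(box=box, kp_score=float(rng.uniform(0.3, 1.0))))
        frames.append(persons)
    return make_sequence(frames, fps=fps)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
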