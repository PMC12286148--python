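"""Resolution adequacy of the tracked subject.

The target's normalized box is converted to pixel width/height using the
frame resolution (``b_w = (x2 - x1) * f_w``, ``b_h = (y2 - y1) * f_h``).
Frames where the subject is smaller than the minimum usable size for pose
estimation (default 60 px wide and 80 px tall, below which keypoint
recovery degrades sharply) are flagged low-resolution, and the score is the
percentage of acceptable frames:

    r_s = (1 - t_lrf / t_f) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .pose_io import BoundingBox
from .tracking import TargetTrack, UndefinedMetricError

DEFAULT_MIN_WIDTH_PX = 60
DEFAULT_MIN_HEIGHT_PX = 80


@dataclass(frozen=True, slots=True)
class ResolutionResult:
    box_widths_px: tuple[float, ...]
    box_heights_px: tuple[float, ...]
    low_res_frames: int
    total_frames: int
    resolution_score: float


def box_pixels(box: BoundingBox, f_w: int, f_h: int) -> tuple[float, float]:
    """Pixel (width, height) of a normalized box on an ``f_w x f_h`` frame."""
    if f_w < 1 or f_h < 1:
        raise ValueError(f"frame size {f_w}x{f_h} must be >= 1px")
    return (box.xmax - box.xmin) * f_w, (box.ymax - box.ymin) * f_h


def resolution_score(
    trk: TargetTrack,
    f_w: int,
    f_h: int,
    w_min: float = DEFAULT_MIN_WIDTH_PX,
    h_min: float = DEFAULT_MIN_HEIGHT_PX,
    rule: Literal["and", "or"] = "and",
    absent_is_low_res: bool = True,
) -> ResolutionResult:
    """Score the fraction of frames with an adequately sized subject.

    Under the default ``rule="and"`` a frame is low-resolution when the box
    is both narrower than ``w_min`` and shorter than ``h_min``; ``"or"``
    flags either violation alone.  Target-absent frames count as
    low-resolution by default (an undetectable subject is unusable); their
    pixel sizes are recorded as 0.
    """
    total = len(trk)
    if total == 0:
        raise UndefinedMetricError("resolution score undefined on empty track")
    widths, heights = [], []
    low = 0
    for entry in trk.entries:
        if not entry.present or entry.target is None:
            widths.append(0.0)
            heights.append(0.0)
            if absent_is_low_res:
                low += 1
            continue
        b_w, b_h = box_pixels(entry.target.box, f_w, f_h)
        widths.append(b_w)
        heights.append(b_h)
        narrow, short = b_w < w_min, b_h < h_min
        if (narrow and short) if rule == "and" else (narrow or short):
            low += 1
    return ResolutionResult(
        box_widths_px=tuple(widths),
        box_heights_px=tuple(heights),
        low_res_frames=low,
        total_frames=total,
        resolution_score=(1.0 - low / total) * 100.0,
    )
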