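"""Viewing-plane classification from torso geometry.

Three per-frame ratios are built from the shoulder and hip keypoints of the
tracked target:

    D_s    = |x_ls - x_rs|          horizontal shoulder distance (HSD)
    D_rsh  = |y_rs - y_rh|          right vertical shoulder-to-hip distance
    D_lsh  = |y_ls - y_lh|          left vertical shoulder-to-hip distance
    r1 = D_s / D_rsh,  r2 = D_lsh / D_s,  R = r2 / r1

The per-frame R values are outlier-filtered to the interquartile range
(values outside [P25, P75] excluded, linear-interpolation percentiles); the
mean of the filtered list and the percentage of "low ratios" (filtered
values < 0.7) decide the plane label: sagittal (side view), coronal
(front/back view) or transverse (overhead view).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .pose_io import PersonDetection
from .tracking import TargetTrack

LOW_RATIO_THRESHOLD = 0.7
LOW_RATIO_PERCENT_CUT = 40.0
MEAN_CUTS = (0.5, 1.0, 2.0, 3.0)

PlaneName = Literal["sagittal", "coronal", "transverse"]


class PlaneUndeterminedError(Exception):
    """No frame yielded a defined ratio; the plane cannot be classified."""


@dataclass(frozen=True, slots=True)
class FrameRatios:
    """Torso distances and ratios for one frame; all dimensionless."""

    D_s: float
    D_rsh: float
    D_lsh: float
    r1: float
    r2: float
    R: float


@dataclass(frozen=True, slots=True)
class RatioSummary:
    filtered_ratios: tuple[float, ...]
    mean_filtered: float
    low_ratio_percent: float


@dataclass(frozen=True, slots=True)
class PlaneLabel:
    value: PlaneName


def frame_ratios(det: PersonDetection) -> Optional[FrameRatios]:
    """Ratios for one detection, or ``None`` when a denominator is zero
    (coincident shoulders or right shoulder/hip), marking the frame
    ratio-undefined."""
    ls, rs = det.keypoint("left_shoulder"), det.keypoint("right_shoulder")
    lh, rh = det.keypoint("left_hip"), det.keypoint("right_hip")
    d_s = abs(ls.x - rs.x)
    d_rsh = abs(rs.y - rh.y)
    d_lsh = abs(ls.y - lh.y)
    if d_s == 0.0 or d_rsh == 0.0:
        return None
    r1 = d_s / d_rsh
    r2 = d_lsh / d_s
    return FrameRatios(D_s=d_s, D_rsh=d_rsh, D_lsh=d_lsh, r1=r1, r2=r2, R=r2 / r1)


def ratio_series(trk: TargetTrack) -> list[float]:
    """Defined per-frame R values of the tracked target, in frame order."""
    out = []
    for entry in trk.entries:
        if entry.present and entry.target is not None:
            fr = frame_ratios(entry.target)
            if fr is not None:
                out.append(fr.R)
    return out


def iqr_filter(
    ratios: list[float], low_threshold: float = LOW_RATIO_THRESHOLD
) -> RatioSummary:
    """Keep ratios within [P25, P75] inclusive and summarise them.

    Percentiles use linear interpolation between order statistics.  The
    low-ratio percentage is computed over the filtered list.
    """
    if not ratios:
        raise PlaneUndeterminedError("empty ratio list: plane cannot be determined")
    arr = np.asarray(ratios, dtype=float)
    p25, p75 = np.percentile(arr, [25.0, 75.0])
    kept = arr[(arr >= p25) & (arr <= p75)]
    mean = float(kept.mean())
    low_percent = 100.0 * float(np.mean(kept < low_threshold))
    return RatioSummary(
        filtered_ratios=tuple(float(v) for v in kept),
        mean_filtered=mean,
        low_ratio_percent=low_percent,
    )


def classify_plane(
    summary: RatioSummary,
    rules: Literal["ordered", "mean_ge_2_transverse"] = "ordered",
    mean_cuts: tuple[float, float, float, float] = MEAN_CUTS,
    low_percent_cut: float = LOW_RATIO_PERCENT_CUT,
) -> PlaneLabel:
    """Map (mean filtered ratio, low-ratio percent) to a plane label.

    The ``ordered`` rule set applies, in order: mean < 0.5 -> sagittal;
    mean in [0.5, 1) with low% > 40 -> sagittal, else coronal;
    mean in [1, 2) -> coronal; mean in [2, 3) -> coronal unless low% == 0,
    in which case transverse; mean >= 3 -> transverse.  The alternative
    rule set gives "mean >= 2 -> transverse" precedence over the
    low-ratio clause for means in [2, 3).
    """
    mean, low = summary.mean_filtered, summary.low_ratio_percent
    c1, c2, c3, c4 = mean_cuts
    if rules == "mean_ge_2_transverse" and mean >= c3:
        return PlaneLabel("transverse")
    if mean < c1:
        return PlaneLabel("sagittal")
    if mean < c2:
        return PlaneLabel("sagittal" if low > low_percent_cut else "coronal")
    if mean < c3:
        return PlaneLabel("coronal")
    if mean < c4:
        return PlaneLabel("coronal" if low != 0.0 else "transverse")
    return PlaneLabel("transverse")


def detect_plane(
    trk: TargetTrack,
    rules: Literal["ordered", "mean_ge_2_transverse"] = "ordered",
) -> tuple[PlaneLabel, RatioSummary]:
    """Full plane detection on a tracked sequence."""
    summary = iqr_filter(ratio_series(trk))
    return classify_plane(summary, rules=rules), summary
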