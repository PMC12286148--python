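"""End-to-end assessment pipeline.

Stages run in fixed order: track the target person, classify the viewing
plane (transverse short-circuits: no gait scoring is possible from
overhead), extract and score zoom-free segments with the plane-specific
splitter, score resolution, assemble the five-feature vector and classify
overall quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

from . import plane as plane_mod
from . import resolution as res_mod
from . import tracking
from . import zoom_segments as zs
from .pose_io import PoseSequence
from .quality import (
    FeatureVector,
    QualityModel,
    QualityReport,
    assemble_features,
    classify,
    generate_feedback,
)
from .tracking import TargetSelection, TargetTrack, TrackMetrics

logger = logging.getLogger(__name__)


class StageError(Exception):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True, slots=True)
class RunConfig:
    """All tunable thresholds, defaulting to the framework's values."""

    min_confidence: float = 0.5
    tau: float = 0.05
    step_at_60hz: int = 8
    smoothing_sigma: float = 2.0
    min_segment_s: float = 3.0
    merge_gap_frames: int = 5
    low_ratio_threshold: float = 0.7
    plane_rules: Literal["ordered", "mean_ge_2_transverse"] = "ordered"
    overlap_rule: Literal["and", "or"] = "and"
    lowres_rule: Literal["and", "or"] = "and"
    min_width_px: float = 60.0
    min_height_px: float = 80.0
    feedback_threshold: float = 80.0
    good_threshold: float = 50.0
    score_mode: Literal["piecewise", "proportional_0_8"] = "piecewise"
    sagittal_merge: bool = True
    forward_only_tracking: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True, slots=True)
class PipelineResult:
    """Every intermediate product of one assessment run."""

    track: TargetTrack
    track_metrics: TrackMetrics
    plane: plane_mod.PlaneLabel
    ratio_summary: plane_mod.RatioSummary
    segment_report: zs.SegmentReport
    resolution_result: res_mod.ResolutionResult
    features: FeatureVector


def compute_features(
    seq: PoseSequence,
    selection: TargetSelection,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run every metric stage on a sequence; no classifier involved."""
    try:
        trk = tracking.track(
            seq,
            selection,
            min_confidence=config.min_confidence,
            forward_only=config.forward_only_tracking,
        )
    except Exception as exc:
        raise StageError(f"tracking: {exc}") from exc
    logger.info("tracked %d frames (%d present)", len(trk),
                sum(e.present for e in trk.entries))

    metrics = tracking.track_metrics(
        seq, trk, config.min_confidence, overlap_rule=config.overlap_rule
    )

    try:
        label, summary = plane_mod.detect_plane(trk, rules=config.plane_rules)
    except Exception as exc:
        raise StageError(f"plane detection: {exc}") from exc
    logger.info("plane=%s (mean ratio %.3f, low%% %.1f)",
                label.value, summary.mean_filtered, summary.low_ratio_percent)

    try:
        hs = zs.height_series(
            trk,
            seq.fps,
            sigma=config.smoothing_sigma,
            step=zs.step_for_fps(seq.fps, config.step_at_60hz),
            tau=config.tau,
        )
        if label.value == "sagittal":
            report = zs.segment_sagittal(
                trk, hs, seq.fps,
                min_duration_s=config.min_segment_s,
                merge_gap=config.merge_gap_frames if config.sagittal_merge else None,
                score_mode=config.score_mode,
            )
        else:
            # coronal splitter also serves transverse sequences, whose
            # report is unused downstream (short-circuit) but kept complete
            report = zs.segment_coronal(
                trk, hs, seq.fps,
                min_duration_s=config.min_segment_s,
                merge_gap=config.merge_gap_frames,
                score_mode=config.score_mode,
            )
    except Exception as exc:
        raise StageError(f"segment extraction: {exc}") from exc

    try:
        res = res_mod.resolution_score(
            trk, seq.frame_width, seq.frame_height,
            w_min=config.min_width_px, h_min=config.min_height_px,
            rule=config.lowres_rule,
        )
    except Exception as exc:
        raise StageError(f"resolution: {exc}") from exc

    features = assemble_features(metrics, report, res)
    return PipelineResult(
        track=trk,
        track_metrics=metrics,
        plane=label,
        ratio_summary=summary,
        segment_report=report,
        resolution_result=res,
        features=features,
    )


def assess(
    seq: PoseSequence,
    selection: TargetSelection,
    model: Optional[QualityModel],
    config: RunConfig = RunConfig(),
) -> tuple[QualityReport, PipelineResult]:
    """Full quality assessment of one sequence.

    Returns the quality report (label, overall score, feedback) together
    with every intermediate stage product for inspection.
    """
    result = compute_features(seq, selection, config)
    report = classify(
        result.features, model, result.plane, good_threshold=config.good_threshold
    )
    return report, result
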