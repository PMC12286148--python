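"""Overall quality classification and feedback generation.

Five per-criterion scores — multiple persons, overlap, zoom flag, best
zoom-free clip score, resolution — feed a random-forest classifier that
separates videos good enough for automated gait scoring from those needing
manual editing.  The forest's probability for the "good" class, scaled to
0-100, is the overall quality score:

    o_s = 100 * P(good),

with o_s > 50 labelled good.  Transverse-plane videos bypass the classifier
entirely: overhead footage cannot be gait-scored, so they get their own
label and no score.  When any criterion falls below 80, rule-based feedback
suggests concrete fixes to the person capturing the video.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV

from .plane import PlaneLabel
from .resolution import ResolutionResult
from .tracking import TrackMetrics
from .zoom_segments import SegmentReport

MODEL_FORMAT_VERSION = "gaitvqa-rf-1"

FEATURE_NAMES: tuple[str, ...] = (
    "multiple_persons_score",
    "overlap_score",
    "zoom_flag",
    "best_segment_score",
    "resolution_score",
)

GOOD_SCORE_THRESHOLD = 50.0
FEEDBACK_THRESHOLD = 80.0

LABEL_GOOD = "good"
LABEL_MANUAL_EDIT = "manual_edit_required"
LABEL_TRANSVERSE = "transverse"

# feedback suggestion strings, emitted verbatim
FEEDBACK_SAGITTAL_PLANE = (
    "Ensure the camera is positioned above the pelvis height and parallel to "
    "the walkway (at a 90-degree angle to the side of the body)."
)
FEEDBACK_CORONAL_PLANE = "Ensure the camera is at hip height and in front of the person."
FEEDBACK_MULTIPLE_PERSONS = (
    "Ensure only the person of interest is in the frame during recording"
)
FEEDBACK_OVERLAP = (
    "Ensure only the patient person of interest is in the frame during "
    "recording. Remove additional persons and avoid overlap if more than one "
    "person is required"
)
FEEDBACK_ZOOM = "Keep the camera steady and do not use zoom while recording"
FEEDBACK_CLIP_LENGTH = (
    "Ensure the person walks for at least 2 strides (4 steps). Ideally the "
    "person walks 5–6 strides, with the middle strides captured on video"
)
FEEDBACK_RESOLUTION = (
    "Ensure the person occupies at least 50 percentage of total frame height. "
    "Adjust the camera distance accordingly"
)


class AssemblyError(Exception):
    """An upstream metric needed for the feature vector is missing."""


class TrainingError(Exception):
    """The labelled dataset cannot train a two-class model."""


@dataclass(frozen=True, slots=True)
class FeatureVector:
    """The classifier's five inputs, in the fixed :data:`FEATURE_NAMES` order."""

    multiple_persons_score: float
    overlap_score: float
    zoom_flag: int
    best_segment_score: float
    resolution_score: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.multiple_persons_score,
                self.overlap_score,
                float(self.zoom_flag),
                self.best_segment_score,
                self.resolution_score,
            ]
        )


@dataclass(frozen=True, slots=True)
class ClassifierConfig:
    """Random-forest hyperparameters; defaults are the tuned values."""

    n_estimators: int = 50
    max_depth: Optional[int] = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    bootstrap: bool = False
    random_seed: int = 0

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=self.bootstrap,
            random_state=self.random_seed,
        )


@dataclass(slots=True)
class QualityModel:
    """Fitted forest plus metadata; persisted with joblib."""

    forest: RandomForestClassifier
    config: ClassifierConfig
    version: str = MODEL_FORMAT_VERSION

    def probability_good(self, features: FeatureVector) -> float:
        classes = list(self.forest.classes_)
        if LABEL_GOOD not in classes:
            raise TrainingError("model was not trained with a 'good' class")
        proba = self.forest.predict_proba(features.as_array().reshape(1, -1))[0]
        return float(proba[classes.index(LABEL_GOOD)])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump({"version": self.version, "config": self.config, "forest": self.forest}, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "QualityModel":
        blob = joblib.load(path)
        if blob.get("version") != MODEL_FORMAT_VERSION:
            raise TrainingError(f"unsupported model version {blob.get('version')!r}")
        return cls(forest=blob["forest"], config=blob["config"], version=blob["version"])


@dataclass(frozen=True, slots=True)
class QualityReport:
    plane: PlaneLabel
    features: FeatureVector
    probability_good: Optional[float]
    overall_score: Optional[float]  # o_s, 0-100; None for transverse
    label: str
    feedback: tuple[str, ...]


def assemble_features(
    track_metrics: TrackMetrics,
    segment_report: SegmentReport,
    resolution_result: ResolutionResult,
) -> FeatureVector:
    """Collect the five upstream scores into the classifier's input order."""
    for name, value in (
        ("track metrics", track_metrics),
        ("segment report", segment_report),
        ("resolution result", resolution_result),
    ):
        if value is None:
            raise AssemblyError(f"missing upstream metric: {name}")
    return FeatureVector(
        multiple_persons_score=track_metrics.multiple_persons_score,
        overlap_score=track_metrics.overlap_score,
        zoom_flag=segment_report.zoom_flag,
        best_segment_score=max(
            segment_report.best_score_dir1, segment_report.best_score_dir2
        ),
        resolution_score=resolution_result.resolution_score,
    )


_GRID = {
    "n_estimators": [25, 50, 100],
    "max_depth": [None, 4, 8],
    "min_samples_split": [2, 4],
    "min_samples_leaf": [1, 2],
    "bootstrap": [False, True],
}


def train_classifier(
    dataset: Sequence[tuple[FeatureVector, str]],
    cfg: ClassifierConfig = ClassifierConfig(),
    grid_search: bool = False,
) -> QualityModel:
    """Fit the quality forest on labelled feature vectors.

    Labels are ``good`` / ``manual_edit_required``; both classes must be
    present and the dataset must hold at least 20 examples.  With
    ``grid_search`` the hyperparameters are re-tuned by cross-validated
    search over a small documented grid before the final fit.
    """
    if len(dataset) < 20:
        raise TrainingError(f"need >= 20 labelled examples, got {len(dataset)}")
    X = np.vstack([fv.as_array() for fv, _ in dataset])
    y = np.array([label for _, label in dataset])
    if len(set(y)) < 2:
        raise TrainingError("dataset holds a single class; need both labels")
    if grid_search:
        search = GridSearchCV(
            RandomForestClassifier(random_state=cfg.random_seed), _GRID, cv=5
        )
        search.fit(X, y)
        best = search.best_params_
        cfg = ClassifierConfig(random_seed=cfg.random_seed, **best)
    forest = cfg.build()
    forest.fit(X, y)
    return QualityModel(forest=forest, config=cfg)


def classify(
    features: FeatureVector,
    model: Optional[QualityModel],
    plane: PlaneLabel,
    good_threshold: float = GOOD_SCORE_THRESHOLD,
) -> QualityReport:
    """Label a video from its features; transverse planes skip the model.

    For sagittal/coronal videos ``o_s = 100 * P(good)`` and the label is
    good strictly above the threshold (default 50), otherwise manual edit
    required.  Transverse videos get a null score rather than 0: no quality
    judgment is made on footage the scoring pipeline cannot use.
    """
    if plane.value == "transverse":
        return QualityReport(
            plane=plane,
            features=features,
            probability_good=None,
            overall_score=None,
            label=LABEL_TRANSVERSE,
            feedback=tuple(generate_feedback(features, plane)),
        )
    if model is None:
        raise TrainingError("a trained model is required for non-transverse videos")
    p_good = model.probability_good(features)
    o_s = 100.0 * p_good
    label = LABEL_GOOD if o_s > good_threshold else LABEL_MANUAL_EDIT
    return QualityReport(
        plane=plane,
        features=features,
        probability_good=p_good,
        overall_score=o_s,
        label=label,
        feedback=tuple(generate_feedback(features, plane)),
    )


def generate_feedback(
    features: FeatureVector,
    plane: PlaneLabel,
    threshold: float = FEEDBACK_THRESHOLD,
) -> list[str]:
    """Targeted capture-improvement suggestions for weak criteria.

    Each criterion scoring below the threshold contributes its suggestion;
    the zoom flag (binary) triggers on 1, clip length on the best segment
    score.  When neither a sagittal nor a coronal view was identified, both
    camera-placement suggestions are emitted.  All criteria at or above the
    threshold and no zoom yields an empty list.
    """
    out: list[str] = []
    if plane.value == "transverse":
        out.append(FEEDBACK_SAGITTAL_PLANE)
        out.append(FEEDBACK_CORONAL_PLANE)
    if features.multiple_persons_score < threshold:
        out.append(FEEDBACK_MULTIPLE_PERSONS)
    if features.overlap_score < threshold:
        out.append(FEEDBACK_OVERLAP)
    if features.zoom_flag:
        out.append(FEEDBACK_ZOOM)
    if features.best_segment_score < threshold:
        out.append(FEEDBACK_CLIP_LENGTH)
    if features.resolution_score < threshold:
        out.append(FEEDBACK_RESOLUTION)
    return out
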