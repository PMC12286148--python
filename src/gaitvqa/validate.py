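"""Validation harness: confusion matrices and binary performance metrics.

Each detector (multiple persons, overlap, zoom, overall quality) is scored
against ground-truth labels with accuracy, precision, sensitivity, F1,
specificity and the Matthews correlation coefficient.  The segment
extractor uses a simpler proportion: the fraction of extracted segments
not flagged as containing zoom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    """Binary confusion counts; "positive" is the detected/flagged class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def binary_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, sensitivity, F1, specificity and MCC.

    Undefined ratios (zero denominators) are reported as NaN.  MCC uses the
    standard covariance form
    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn

    def ratio(num: float, den: float) -> float:
        return num / den if den else float("nan")

    accuracy = ratio(tp + tn, cm.total)
    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, denom)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1,
        "specificity": specificity,
        "mcc": mcc,
    }


def confusion_from_labels(
    truth: Sequence[bool], predicted: Sequence[bool]
) -> ConfusionMatrix:
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    tp = sum(1 for t, p in zip(truth, predicted) if t and p)
    fp = sum(1 for t, p in zip(truth, predicted) if not t and p)
    fn = sum(1 for t, p in zip(truth, predicted) if t and not p)
    tn = sum(1 for t, p in zip(truth, predicted) if not t and not p)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def segment_flag_accuracy(n_extracted: int, n_flagged: int) -> float:
    """Share of extracted segments free of zoom: 1 - flagged/extracted."""
    if n_extracted <= 0:
        raise ValueError("no extracted segments")
    if not 0 <= n_flagged <= n_extracted:
        raise ValueError("flagged count outside [0, extracted]")
    return 1.0 - n_flagged / n_extracted


def validate_detectors(
    table: pd.DataFrame, model, good_threshold: float = 50.0
) -> pd.DataFrame:
    """Score each detector and the overall classifier on a labelled feature
    table (columns as produced by :func:`gaitvqa.synthgen.generate_dataset`
    plus per-video truth columns where available).

    Detector predictions are derived from the features themselves
    (multiple persons / overlap: score below 100 means the condition was
    detected; zoom: the flag), so the harness works on any feature table
    with ``truth_*`` boolean columns.  Rows without the needed columns are
    skipped per detector.
    """
    from .quality import FeatureVector, LABEL_GOOD

    rows = []

    def add(name: str, truth_col: str, pred: Sequence[bool]) -> None:
        if truth_col not in table.columns:
            return
        cm = confusion_from_labels(
            [bool(v) for v in table[truth_col]], [bool(v) for v in pred]
        )
        rows.append({
            "detector": name,
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            **binary_metrics(cm),
        })

    add(
        "multiple_persons",
        "truth_multiperson",
        [v < 100.0 for v in table["multiple_persons_score"]],
    )
    add("overlap", "truth_overlap", [v < 100.0 for v in table["overlap_score"]])
    add("zoom", "truth_zoom", [bool(v) for v in table["zoom_flag"]])

    if model is not None and "label" in table.columns:
        preds = []
        for _, r in table.iterrows():
            fv = FeatureVector(
                multiple_persons_score=float(r["multiple_persons_score"]),
                overlap_score=float(r["overlap_score"]),
                zoom_flag=int(r["zoom_flag"]),
                best_segment_score=float(r["best_segment_score"]),
                resolution_score=float(r["resolution_score"]),
            )
            preds.append(100.0 * model.probability_good(fv) > good_threshold)
        cm = confusion_from_labels(
            [lab == LABEL_GOOD for lab in table["label"]], preds
        )
        rows.append({
            "detector": "overall_quality",
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            **binary_metrics(cm),
        })
    if not rows:
        raise ValueError("no validatable columns in table")
    return pd.DataFrame(rows)
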