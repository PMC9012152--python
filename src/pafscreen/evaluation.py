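"""Episode-boundary and beat-level evaluation of PAF detections.

The PAF-score grades each labeled AF episode L against the detections D on a
shared beat axis: a detection matching both boundaries to within three beats
scores 1; otherwise the score is the intersection-over-union |L∩D| / |L∪D|
counted in beats, and a completely missed episode scores 0.  A recording's
score is the mean over its labeled episodes, so short episodes weigh as much
as long ones.  Error segments (detections containing no AF-labeled beat),
missed segments, and per-beat sensitivity/specificity/accuracy complete the
report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rr import RhythmSegment

__all__ = [
    "EvalReport",
    "segment_score",
    "recording_score",
    "count_error_segments",
    "count_missed_segments",
    "beat_metrics",
    "evaluate",
    "BOUNDARY_TOLERANCE_BEATS",
]

#: Onset/offset slack (in beats) under which a detection counts as exact.
BOUNDARY_TOLERANCE_BEATS = 3


@dataclass
class EvalReport:
    """Per-episode PAF-scores plus segment- and beat-level summaries."""

    per_label_scores: list[float]
    average_score: float | None
    error_segments: int
    missed_segments: int
    n_detections: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def to_dict(self) -> dict:
        return {
            "per_label_scores": self.per_label_scores,
            "average_score": self.average_score,
            "error_segments": self.error_segments,
            "missed_segments": self.missed_segments,
            "n_detections": self.n_detections,
            "beat_confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _overlapping(label: RhythmSegment, detections) -> list[RhythmSegment]:
    return [d for d in detections if label.overlap(d) > 0]


def segment_score(label: RhythmSegment, detections) -> float:
    """PAF-score of one labeled episode in [0, 1].

    Only the detections overlapping the label are considered.  A single
    overlapping detection whose onset and offset each differ from the
    label's by fewer than :data:`BOUNDARY_TOLERANCE_BEATS` beats scores 1
    (fragmented detections never take this shortcut); otherwise the score is
    the beat-count intersection over union; no overlap scores 0.
    """
    hits = _overlapping(label, detections)
    if not hits:
        return 0.0
    if len(hits) == 1:
        d = hits[0]
        if (
            abs(d.start_beat - label.start_beat) < BOUNDARY_TOLERANCE_BEATS
            and abs(d.end_beat - label.end_beat) < BOUNDARY_TOLERANCE_BEATS
        ):
            return 1.0
    lo = min([label.start_beat] + [d.start_beat for d in hits])
    hi = max([label.end_beat] + [d.end_beat for d in hits])
    axis = np.zeros(hi - lo, dtype=bool)
    det_mask = axis.copy()
    for d in hits:
        det_mask[d.start_beat - lo : d.end_beat - lo] = True
    lab_mask = axis.copy()
    lab_mask[label.start_beat - lo : label.end_beat - lo] = True
    inter = int(np.count_nonzero(det_mask & lab_mask))
    union = int(np.count_nonzero(det_mask | lab_mask))
    return inter / union


def recording_score(labels, detections) -> float | None:
    """Mean PAF-score over all labeled episodes (missed episodes score 0);
    ``None`` when the recording has no labeled episode."""
    labels = list(labels)
    if not labels:
        return None
    return float(np.mean([segment_score(lab, detections) for lab in labels]))


def count_error_segments(labels, detections) -> int:
    """Detected segments containing zero AF-labeled beats."""
    return sum(1 for d in detections if not _overlapping(d, labels))


def count_missed_segments(labels, detections) -> int:
    """Labeled episodes with zero overlapping detected beats."""
    return sum(1 for lab in labels if not _overlapping(lab, detections))


def _beat_mask(segments, total_beats: int) -> np.ndarray:
    mask = np.zeros(total_beats, dtype=bool)
    for s in segments:
        mask[max(s.start_beat, 0) : min(s.end_beat, total_beats)] = True
    return mask


def beat_metrics(labels, detections, total_beats: int):
    """Per-beat confusion over AF/non-AF.

    Returns ``(tp, fp, tn, fn, sensitivity, specificity, accuracy)``;
    a metric whose class has no beats is ``None`` rather than NaN.
    """
    if total_beats < 1:
        raise ValueError("total_beats must be >= 1")
    lab = _beat_mask(labels, total_beats)
    det = _beat_mask(detections, total_beats)
    tp = int(np.count_nonzero(lab & det))
    fp = int(np.count_nonzero(~lab & det))
    tn = int(np.count_nonzero(~lab & ~det))
    fn = int(np.count_nonzero(lab & ~det))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    acc = (tp + tn) / total_beats
    return tp, fp, tn, fn, sens, spec, acc


def evaluate(labels, detections, total_beats: int) -> EvalReport:
    """Full report: per-episode PAF-scores, error/missed counts, beat metrics."""
    labels = list(labels)
    detections = list(detections)
    scores = [segment_score(lab, detections) for lab in labels]
    tp, fp, tn, fn, sens, spec, acc = beat_metrics(labels, detections, total_beats)
    return EvalReport(
        per_label_scores=scores,
        average_score=float(np.mean(scores)) if scores else None,
        error_segments=count_error_segments(labels, detections),
        missed_segments=count_missed_segments(labels, detections),
        n_detections=len(detections),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
    )
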