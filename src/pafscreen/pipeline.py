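"""End-to-end orchestration: input → screening → rejection cascade → detections.

``detect_paf`` accepts either an RR sequence (with optional contiguity flags
from quality gating) or a raw single-lead waveform; the waveform path runs
baseline removal, quality assessment, QRS detection and refinement first.
Candidates that survive the premature-beat cascade become detected AF
segments; every rejected candidate is kept in the verdict log with its
evidence.

Because the screening threshold is the method's one free parameter,
``calibrate_threshold`` selects it from the statistic's operating curve on
long synthetic sinus and AF sequences: the smallest value whose sinus
false-flag rate stays within a fixed false-alarm budget while nearly every
AF window remains flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .pb_reject import CandidateVerdict, VerdictClass, classify_candidate
from .preprocess import (
    assess_quality,
    detect_qrs,
    refine_qrs,
    remove_baseline,
    rr_from_beats,
)
from .rr import AF_LABEL, RhythmSegment, RRSequence
from .screening import RC_WINDOW, CandidateSegment, candidate_segments, rc_series
from .synth import RhythmClass, RhythmSpec, SyntheticRecording, gen_rr

__all__ = [
    "DetectionResult",
    "detect_paf",
    "detect_paf_waveform",
    "classify_rr_segment",
    "labels_from_recording",
    "calibrate_threshold",
]


@dataclass
class DetectionResult:
    """Detected AF segments plus the full per-candidate verdict log."""

    detections: list[RhythmSegment]
    verdicts: list[tuple[CandidateSegment, CandidateVerdict]]
    n_beats: int
    config: PipelineConfig


def detect_paf(rr: RRSequence, config: PipelineConfig | None = None) -> DetectionResult:
    """Detect AF segments in an RR sequence.

    Candidates come from the rhythm-change screen; each is classified by the
    rejection cascade, and the AF verdicts are returned as beat-indexed
    segments.  A detected segment starts at the candidate's first flagged
    beat and closes six beats after its last flagged beat, since the Rc value
    of a beat describes the six intervals that follow it.
    """
    config = config or PipelineConfig()
    series = rc_series(rr, config.threshold, config.std_mode)
    candidates = candidate_segments(series, config.merge_gap_beats)
    detections: list[RhythmSegment] = []
    verdicts: list[tuple[CandidateSegment, CandidateVerdict]] = []
    for seg in candidates:
        verdict = classify_candidate(
            seg,
            rr,
            config.threshold,
            seed=config.seed,
            single_pb_max_run=config.single_pb_max_run,
            geminy_min_count=config.geminy_min_count,
            reject_order=config.reject_order,
            std_mode=config.std_mode,
        )
        verdicts.append((seg, verdict))
        if verdict.klass is VerdictClass.AF:
            detections.append(
                RhythmSegment(
                    seg.start_beat,
                    min(seg.end_beat + RC_WINDOW, rr.n_beats),
                    AF_LABEL,
                )
            )
    return DetectionResult(detections, verdicts, rr.n_beats, config)


def detect_paf_waveform(
    signal: np.ndarray, fs: float, config: PipelineConfig | None = None
) -> DetectionResult:
    """Waveform entry point: preprocess to an RR sequence, then detect."""
    config = config or PipelineConfig()
    clean = remove_baseline(signal, fs, config.baseline_win1_ms, config.baseline_win2_ms)
    quality = assess_quality(
        clean,
        fs,
        window_s=config.sqa_window_s,
        flatline_uv=config.sqa_flatline_uv,
        rail_fraction=config.sqa_rail_fraction,
        mad_factor=config.sqa_mad_factor,
    )
    beats = detect_qrs(clean, fs)
    beats = refine_qrs(clean, beats, fs, config.refine_radius_ms)
    beats = np.unique(beats)
    rr = rr_from_beats(beats, fs, quality)
    return detect_paf(rr, config)


def classify_rr_segment(rr: RRSequence, config: PipelineConfig) -> bool:
    """Is this (short) RR segment detected as AF?

    Used for segment-level evaluation: a segment counts as AF when any of
    its candidates survives the rejection cascade.
    """
    result = detect_paf(rr, config)
    return len(result.detections) > 0


def labels_from_recording(recording: SyntheticRecording) -> list[RhythmSegment]:
    """Ground-truth AF segments of a synthetic recording (consecutive
    episodes with the same label merge into one segment)."""
    ann = recording.rhythm_annotation
    n = recording.rr.n_beats
    bounds = [s for s, _ in ann] + [n]
    segments: list[RhythmSegment] = []
    for (start, label), end in zip(ann, bounds[1:]):
        if label != AF_LABEL:
            continue
        if segments and segments[-1].end_beat == start:
            segments[-1] = RhythmSegment(segments[-1].start_beat, end, AF_LABEL)
        else:
            segments.append(RhythmSegment(start, end, AF_LABEL))
    return segments


# --------------------------------------------------------------------------
# Threshold calibration

#: Acceptable false-flag rate in sinus rhythm: about one flagged window per
#: 10,000 sinus beats (roughly one per two hours of monitoring at 75 bpm).
NSR_FLAG_BUDGET = 1e-4


def calibrate_threshold(
    seed: int = 0,
    grid=None,
    n_beats: int = 500_000,
    min_af_sensitivity: float = 0.95,
    config: PipelineConfig | None = None,
) -> float:
    """Calibrate the screening threshold on the statistic's operating curve.

    The threshold's job is to separate the low-variability sinus regime from
    the high-variability AF regime.  Both per-window flag rates are measured
    on one long synthetic sequence per rhythm, and the calibrated value is
    the smallest grid threshold whose sinus false-flag rate stays within
    :data:`NSR_FLAG_BUDGET`.  A low sinus false-alarm budget matters beyond
    specificity itself: a stray sinus flag near a true AF run merges into
    its candidate segment and smears the detected episode boundary.  The
    chosen threshold must still flag at least ``min_af_sensitivity`` of AF
    windows (so AF runs stay long enough to survive the single-PB rule);
    violating that raises an error rather than silently degrading.
    """
    if grid is None:
        grid = np.round(np.arange(0.030, 0.1201, 0.005), 4)
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)

    def window_cv(cls: RhythmClass) -> np.ndarray:
        seq = gen_rr(
            RhythmSpec(rhythm_class=cls, n_beats=n_beats, seed=int(rng.integers(0, 2**31 - 1)))
        )
        rc = rc_series(seq, float(grid[0]), config.std_mode).rc
        return rc[~np.isnan(rc)]

    nsr_rc = window_cv(RhythmClass.NSR)
    af_rc = window_cv(RhythmClass.AF)
    for t in grid:
        if float(np.mean(nsr_rc > t)) <= NSR_FLAG_BUDGET:
            af_sens = float(np.mean(af_rc > t))
            if af_sens < min_af_sensitivity:
                raise RuntimeError(
                    f"calibration failed: threshold {t} meets the sinus false-flag "
                    f"budget but AF window sensitivity is {af_sens:.3f} < {min_af_sensitivity}"
                )
            return float(t)
    raise RuntimeError(
        "calibration failed: no grid threshold meets the sinus false-flag budget"
    )
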