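"""Waveform-domain preprocessing: baseline removal, signal-quality gating,
QRS detection and refinement, and RR-interval derivation.

The pipeline can also start directly from RR intervals, in which case none of
these stages run; they exist so that raw single-lead recordings (real or
rendered by :mod:`pafscreen.synth`) can be reduced to the RR sequence the
screening stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .rr import RRSequence

__all__ = [
    "QualityMask",
    "remove_baseline",
    "assess_quality",
    "detect_qrs",
    "refine_qrs",
    "rr_from_beats",
]


@dataclass
class QualityMask:
    """Per-window usability of a recording, in fixed-length windows.

    A beat is usable iff its sample lies in a usable window.
    """

    window_length_s: float
    fs: float
    usable: np.ndarray  # bool per window

    @property
    def n_windows(self) -> int:
        return int(self.usable.shape[0])

    def window_of(self, sample: int) -> int:
        return int(sample // int(round(self.window_length_s * self.fs)))

    def beat_usable(self, beat_samples: np.ndarray) -> np.ndarray:
        if self.n_windows == 0:
            return np.zeros(len(beat_samples), dtype=bool)
        w = np.minimum(
            np.asarray(beat_samples) // int(round(self.window_length_s * self.fs)),
            self.n_windows - 1,
        )
        return self.usable[w]


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def remove_baseline(
    x: np.ndarray, fs: float, win1_ms: float = 200.0, win2_ms: float = 600.0
) -> np.ndarray:
    """Subtract a two-pass sliding-median baseline estimate (zero phase).

    The first (short) median pass removes QRS complexes from the estimate,
    the second (long) pass smooths it to the wander time scale; subtracting
    the result leaves QRS amplitudes essentially intact while flattening
    low-frequency drift.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    x = np.asarray(x, dtype=float)
    k1 = _odd(max(3, int(round(win1_ms / 1000 * fs))))
    k2 = _odd(max(3, int(round(win2_ms / 1000 * fs))))
    if x.shape[0] <= max(k1, k2):
        raise ValueError(
            f"signal of {x.shape[0]} samples is shorter than the {max(k1, k2)}-sample filter window"
        )
    baseline = ndimage.median_filter(x, size=k1, mode="nearest")
    baseline = ndimage.median_filter(baseline, size=k2, mode="nearest")
    return x - baseline


def assess_quality(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    flatline_uv: float = 50.0,
    rail_fraction: float = 0.2,
    mad_factor: float = 6.0,
) -> QualityMask:
    """Flag fixed windows as unusable when they carry no ECG information.

    A window fails when it is (a) flat — peak-to-peak below ``flatline_uv``
    microvolts; (b) saturated — more than ``rail_fraction`` of its samples
    pinned at the recording's min/max rail; or (c) structureless — its
    maximum absolute amplitude below ``mad_factor`` times its median absolute
    deviation, i.e. no QRS-like spike stands out of the noise floor.
    """
    x = np.asarray(x, dtype=float)
    wlen = int(round(window_s * fs))
    n_win = int(np.ceil(x.shape[0] / wlen)) if x.shape[0] else 0
    usable = np.ones(n_win, dtype=bool)
    if n_win == 0:
        return QualityMask(window_s, fs, usable)
    lo_rail, hi_rail = float(np.min(x)), float(np.max(x))
    rail_eps = max(1e-9, 1e-3 * (hi_rail - lo_rail))
    for w in range(n_win):
        seg = x[w * wlen : (w + 1) * wlen]
        ptp = float(np.ptp(seg))
        if ptp < flatline_uv * 1e-3:  # signal is in mV
            usable[w] = False
            continue
        at_rail = np.mean((seg <= lo_rail + rail_eps) | (seg >= hi_rail - rail_eps))
        if at_rail > rail_fraction:
            usable[w] = False
            continue
        mad = float(np.median(np.abs(seg - np.median(seg))))
        if np.max(np.abs(seg)) < mad_factor * mad:
            usable[w] = False
    return QualityMask(window_s, fs, usable)


def detect_qrs(x: np.ndarray, fs: float) -> np.ndarray:
    """Detect QRS complexes on a baseline-removed signal.

    Band-pass (5–15 Hz) energy with a short integration window, peak picking
    under a 200 ms refractory period, and an adaptive amplitude threshold.
    Detections should be refined with :func:`refine_qrs` before deriving RR
    intervals.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < int(0.5 * fs) or not np.any(x):
        return np.zeros(0, dtype=int)
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    energy = filt * filt
    k = max(1, int(round(0.12 * fs)))
    integ = np.convolve(energy, np.ones(k) / k, mode="same")
    refractory = int(round(0.2 * fs))
    peaks, props = sps.find_peaks(integ, distance=refractory, height=0.0)
    if peaks.size == 0:
        return peaks.astype(int)
    heights = props["peak_heights"]
    thr = 0.2 * np.percentile(heights, 75)
    return peaks[heights > thr].astype(int)


def refine_qrs(x: np.ndarray, beats, fs: float, radius_ms: float = 50.0) -> np.ndarray:
    """Move each beat to the maximum absolute amplitude in its neighborhood.

    Idempotent: applying it twice equals applying it once.  Beats close to
    the signal edge search over the clamped valid range.
    """
    x = np.asarray(x, dtype=float)
    beats = np.asarray(beats, dtype=int)
    r = int(round(radius_ms / 1000 * fs))
    out = np.empty_like(beats)
    for i, b in enumerate(beats):
        lo = max(0, b - r)
        hi = min(x.shape[0], b + r + 1)
        out[i] = lo + int(np.argmax(np.abs(x[lo:hi])))
    return out


def rr_from_beats(
    beats, fs: float, quality: QualityMask | None = None
) -> RRSequence:
    """Derive the RR sequence from beat sample indices.

    Beats falling in unusable windows are dropped; intervals that span a
    dropped beat or cross a usable/unusable window boundary are marked
    non-contiguous so that no Rc window straddles the gap.  Fewer than two
    usable beats yield an empty sequence.
    """
    beats = np.asarray(beats, dtype=int)
    if np.any(np.diff(beats) <= 0):
        raise ValueError("beat samples must be strictly increasing")
    if quality is not None:
        keep = quality.beat_usable(beats)
    else:
        keep = np.ones(beats.shape[0], dtype=bool)
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size < 2:
        return RRSequence(np.zeros(0), np.zeros(0), np.zeros(0, dtype=bool))
    kept = beats[kept_idx]
    times = kept / fs
    rr = np.diff(times)
    contiguous = np.ones(rr.shape, dtype=bool)
    for j in range(kept_idx.size - 1):
        if kept_idx[j + 1] != kept_idx[j] + 1:
            contiguous[j] = False  # spans one or more dropped beats
        elif quality is not None:
            wa = quality.window_of(kept[j])
            wb = quality.window_of(kept[j + 1])
            if wa != wb and not np.all(quality.usable[wa : wb + 1]):
                contiguous[j] = False
    return RRSequence(times, rr, contiguous)
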