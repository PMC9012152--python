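"""Suspicious-AF screening: the rhythm-change statistic Rc and candidate segments.

For every beat, the rhythm change over the following six RR intervals is
summarized by

    Rc = std(RR1, ..., RR6) / mean(RR1, ..., RR6)

i.e. the coefficient of variation of a short sliding window.  Beats whose Rc
exceeds a threshold are flagged as showing large rhythm change; maximal runs
of flagged beats (with nearby runs merged) form the candidate AF segments
passed on to the premature-beat rejection cascade.

Rc is scale-invariant — multiplying all six intervals by a constant leaves it
unchanged — so the screen responds to rhythm irregularity, not heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rr import RRSequence

__all__ = [
    "RcSeries",
    "CandidateSegment",
    "compute_rc",
    "rc_series",
    "candidate_segments",
    "RC_WINDOW",
]

#: Number of adjacent RR intervals in one rhythm-change window.
RC_WINDOW = 6


@dataclass
class RcSeries:
    """Per-beat rhythm-change values with above-threshold flags.

    ``rc`` is NaN for beats lacking six subsequent contiguous intervals;
    ``flagged`` is ``False`` there.
    """

    rc: np.ndarray
    threshold: float
    flagged: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rc)


@dataclass(frozen=True)
class CandidateSegment:
    """Half-open run of flagged beats ``[start_beat, end_beat)``.

    ``rc_run_length`` is the longest *pre-merge* run of consecutively flagged
    beats inside the segment; the single-premature-beat rule is applied to it.
    """

    start_beat: int
    end_beat: int
    rc_run_length: int


def _std(x: np.ndarray, mode: str, axis=None) -> np.ndarray:
    if mode == "population":
        return np.std(x, axis=axis, ddof=0)
    if mode == "sample":
        return np.std(x, axis=axis, ddof=1)
    raise ValueError(f"std_mode must be 'population' or 'sample', got {mode!r}")


def compute_rc(window, std_mode: str = "population") -> float:
    """Rhythm change of exactly six strictly positive RR intervals.

    Population standard deviation (divide by 6) over the arithmetic mean by
    default; the sample form (divide by 5) is available via ``std_mode``.
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (RC_WINDOW,):
        raise ValueError(f"Rc window must hold exactly {RC_WINDOW} RR intervals, got shape {w.shape}")
    if np.any(w <= 0):
        raise ValueError("RR intervals must be strictly positive")
    if np.ptp(w) == 0.0:  # identical intervals: exactly zero, not rounding dust
        return 0.0
    return float(_std(w, std_mode) / np.mean(w))


def rc_series(rr: RRSequence, threshold: float, std_mode: str = "population") -> RcSeries:
    """Rc for every beat that has six subsequent contiguous RR intervals.

    The window is attached to its left-edge beat: ``rc[i]`` summarizes
    intervals ``RR_i .. RR_{i+5}`` (the six intervals after beat *i*).  Beats
    whose window would straddle a non-contiguous interval are left undefined.
    Flags use the strict comparison ``rc > threshold``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    n_beats = rr.n_beats
    rc = np.full(n_beats, np.nan)
    if rr.n_rr >= RC_WINDOW:
        wins = np.lib.stride_tricks.sliding_window_view(rr.rr, RC_WINDOW)
        ok = np.all(
            np.lib.stride_tricks.sliding_window_view(rr.contiguous, RC_WINDOW), axis=1
        )
        vals = _std(wins, std_mode, axis=1) / np.mean(wins, axis=1)
        vals[np.ptp(wins, axis=1) == 0.0] = 0.0  # identical intervals
        idx = np.arange(wins.shape[0])
        rc[idx[ok]] = vals[ok]
    flagged = np.zeros(n_beats, dtype=bool)
    defined = ~np.isnan(rc)
    flagged[defined] = rc[defined] > threshold
    return RcSeries(rc=rc, threshold=float(threshold), flagged=flagged)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def candidate_segments(series: RcSeries, merge_gap_beats: int = 6) -> list[CandidateSegment]:
    """Candidate AF segments: merged maximal runs of flagged beats.

    Runs separated by fewer than ``merge_gap_beats`` unflagged beats are
    merged into one segment; each segment keeps its longest pre-merge run
    length for the single-premature-beat rule.
    """
    runs = _runs(series.flagged)
    if not runs:
        return []
    merged: list[list] = []  # [start, end, max_run]
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap_beats:
            merged[-1][1] = e
            merged[-1][2] = max(merged[-1][2], e - s)
        else:
            merged.append([s, e, e - s])
    return [CandidateSegment(s, e, run) for s, e, run in merged]
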