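"""Core in-memory containers shared by every pipeline stage.

The central currency of the package is the :class:`RRSequence`: an ordered
series of inter-beat (RR) intervals in seconds, anchored on beat times, with
optional per-beat labels and a per-interval contiguity flag.  Contiguity marks
RR intervals that connect two beats with no dropped beat or quality gap in
between; the rhythm-change statistic is only evaluated over windows of
contiguous intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RRSequence", "RhythmSegment", "AF_LABEL", "NON_AF_LABEL"]

AF_LABEL = "AFIB"
NON_AF_LABEL = "N"


@dataclass
class RRSequence:
    """Ordered RR intervals with beat times and optional per-beat labels.

    Parameters
    ----------
    beat_times:
        Monotonically increasing beat times in seconds, shape ``(n_beats,)``.
    rr:
        Intervals between consecutive beats in seconds, shape ``(n_beats-1,)``.
    contiguous:
        Boolean per interval; ``False`` marks intervals spanning a dropped
        beat or a signal-quality boundary.  Defaults to all ``True``.
    beat_labels:
        Optional per-beat labels (``"N"`` / ``"PB"``), shape ``(n_beats,)``.
    """

    beat_times: np.ndarray
    rr: np.ndarray
    contiguous: np.ndarray = field(default=None)  # type: ignore[assignment]
    beat_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.contiguous is None:
            self.contiguous = np.ones(self.rr.shape, dtype=bool)
        else:
            self.contiguous = np.asarray(self.contiguous, dtype=bool)
        if self.beat_labels is not None:
            self.beat_labels = np.asarray(self.beat_labels)
        if self.rr.shape[0] != max(self.beat_times.shape[0] - 1, 0):
            raise ValueError(
                f"rr has {self.rr.shape[0]} entries but {self.beat_times.shape[0]} "
                "beats imply n_beats - 1 intervals"
            )
        if self.contiguous.shape != self.rr.shape:
            raise ValueError("contiguous mask must have one flag per RR interval")
        if self.beat_labels is not None and self.beat_labels.shape[0] != self.n_beats:
            raise ValueError("beat_labels must have one label per beat")

    @classmethod
    def from_rr(
        cls,
        rr,
        t0: float = 0.0,
        beat_labels=None,
        contiguous=None,
    ) -> "RRSequence":
        """Build a sequence from intervals alone; beat times are cumulative."""
        rr = np.asarray(rr, dtype=float)
        beat_times = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        return cls(beat_times, rr, contiguous, beat_labels)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.shape[0])

    @property
    def n_rr(self) -> int:
        return int(self.rr.shape[0])

    def __len__(self) -> int:
        return self.n_beats


@dataclass(frozen=True)
class RhythmSegment:
    """Half-open beat-index interval ``[start_beat, end_beat)`` with a rhythm class.

    Segments are anchored on beats (QRS complexes), not on wall-clock time:
    rhythm transitions in annotated recordings fall on a beat, and detections
    are produced in beat coordinates.
    """

    start_beat: int
    end_beat: int
    label: str = AF_LABEL

    def __post_init__(self) -> None:
        if self.end_beat <= self.start_beat:
            raise ValueError(
                f"empty segment: start_beat={self.start_beat} end_beat={self.end_beat}"
            )

    @property
    def n_beats(self) -> int:
        return self.end_beat - self.start_beat

    def overlap(self, other: "RhythmSegment") -> int:
        """Number of beats shared with ``other``."""
        return max(0, min(self.end_beat, other.end_beat) - max(self.start_beat, other.start_beat))
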