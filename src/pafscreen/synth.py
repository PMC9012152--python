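"""Synthetic RR-interval and ECG generator for the six rhythm classes.

Generates annotated RR sequences (and optionally sampled ECG waveforms) with
the statistical structure each rhythm class is assumed to have:

* **NSR** — normal sinus rhythm: mildly autocorrelated, low-variability RRs
  (AR(1) around a base interval).
* **AF** — atrial fibrillation: highly irregular, serially exchangeable RRs
  (i.i.d. truncated-normal draws with a large coefficient of variation), so a
  3-way clustering of the intervals finds no separated groups.
* **SINGLE_PB / MULTI_PB** — one or several premature beats, each producing a
  short coupling interval followed by a longer compensatory pause, both
  proportional to the local mean RR.
* **BIGEMINY** — every other beat premature: alternating short/long RRs.
* **TRIGEMINY** — every third beat premature: repeating normal/short/long RRs.

Every generator is deterministic for a fixed seed, and all RR values are
truncated to the physiologically plausible band [0.2, 2.5] s.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .rr import AF_LABEL, NON_AF_LABEL, RRSequence

__all__ = [
    "RhythmClass",
    "RhythmSpec",
    "SyntheticRecording",
    "gen_rr",
    "gen_recording",
    "render_ecg",
    "write_rr_csv",
    "read_rr_csv",
    "RR_MIN",
    "RR_MAX",
]

RR_MIN = 0.2
RR_MAX = 2.5

#: AR(1) coefficient of the sinus-rhythm model (mild short-range correlation).
NSR_AR_COEF = 0.5


class RhythmClass(str, Enum):
    NSR = "NSR"
    AF = "AF"
    SINGLE_PB = "SINGLE_PB"
    MULTI_PB = "MULTI_PB"
    BIGEMINY = "BIGEMINY"
    TRIGEMINY = "TRIGEMINY"


@dataclass
class RhythmSpec:
    """Parameters of one synthetic rhythm episode.

    ``coupling_fraction`` scales the premature (short) interval and
    ``compensatory_fraction`` the following pause, both relative to the local
    mean RR, so premature beats stay rate-adaptive.
    """

    rhythm_class: RhythmClass
    n_beats: int
    base_rr: float = 0.8
    nsr_cv: float = 0.03
    af_cv: float = 0.20
    coupling_fraction: float = 0.6
    compensatory_fraction: float = 1.4
    n_pb: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.rhythm_class = RhythmClass(self.rhythm_class)
        if self.n_beats < 7:
            raise ValueError(f"n_beats must be >= 7, got {self.n_beats}")
        if self.base_rr <= 0:
            raise ValueError(f"base_rr must be positive, got {self.base_rr}")
        for name in ("nsr_cv", "af_cv"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.coupling_fraction < 1:
            raise ValueError(
                f"coupling_fraction must be in (0, 1), got {self.coupling_fraction}"
            )
        if self.compensatory_fraction <= 1:
            raise ValueError(
                f"compensatory_fraction must be > 1, got {self.compensatory_fraction}"
            )
        if self.n_pb < 1:
            raise ValueError(f"n_pb must be >= 1, got {self.n_pb}")


@dataclass
class SyntheticRecording:
    """Episode-structured recording with exact ground truth.

    ``rhythm_annotation`` lists ``(start_beat_index, rhythm_label)`` pairs,
    one per episode, the first at beat 0; ``beat_labels`` marks every beat as
    normal (``"N"``) or premature (``"PB"``).
    """

    rr: RRSequence
    beat_labels: np.ndarray
    rhythm_annotation: list[tuple[int, str]]
    seed: int = 0

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.rhythm_annotation]
        if not starts or starts[0] != 0:
            raise ValueError("first rhythm annotation must start at beat 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("rhythm annotation indices must be strictly increasing")
        if len(self.beat_labels) != self.rr.n_beats:
            raise ValueError("beat_labels length must equal number of beats")


def _truncate(rr: np.ndarray) -> np.ndarray:
    return np.clip(rr, RR_MIN, RR_MAX)


def _nsr_rr(n_rr: int, spec: RhythmSpec, rng: np.random.Generator) -> np.ndarray:
    """AR(1) around base_rr with stationary sd = nsr_cv * base_rr."""
    sd = spec.nsr_cv * spec.base_rr
    phi = NSR_AR_COEF
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n_rr)
    prev = rng.normal(0.0, sd)
    for i in range(n_rr):
        prev = phi * prev + rng.normal(0.0, innov_sd)
        x[i] = prev
    return _truncate(spec.base_rr + x)


def _local_mean(rr: np.ndarray, i: int, width: int = 6) -> float:
    lo = max(0, i - width)
    if lo == i:
        return float(rr[i]) if len(rr) else 0.8
    return float(np.mean(rr[lo:i]))


def _insert_pb(rr: np.ndarray, beat_idx: int, spec: RhythmSpec) -> None:
    """Overwrite the RR pair around a premature beat at ``beat_idx``.

    The coupling interval precedes the beat (rr[beat_idx-1]) and the
    compensatory pause follows it (rr[beat_idx]); both scale with the local
    mean of the preceding normal intervals.
    """
    m = _local_mean(rr, beat_idx - 1)
    rr[beat_idx - 1] = spec.coupling_fraction * m
    rr[beat_idx] = spec.compensatory_fraction * m


def _pb_positions(spec: RhythmSpec, n_pb: int, rng: np.random.Generator) -> list[int]:
    """Premature-beat indices: >= 3 beats from each end, spacing >= 3 beats."""
    lo, hi = 3, spec.n_beats - 4
    candidates = list(range(lo, hi + 1))
    if n_pb * 3 - 2 > len(candidates):
        raise ValueError(
            f"cannot place {n_pb} premature beats with spacing 3 in {spec.n_beats} beats"
        )
    for _ in range(10_000):
        pick = sorted(rng.choice(candidates, size=n_pb, replace=False).tolist())
        if all(b - a >= 3 for a, b in zip(pick, pick[1:])):
            return pick
    # Fall back to an evenly spaced deterministic layout.
    step = max(3, (hi - lo) // max(n_pb - 1, 1))
    return [lo + k * step for k in range(n_pb)]


def gen_rr(spec: RhythmSpec) -> RRSequence:
    """Generate one annotated RR sequence for the requested rhythm class.

    Returns ``spec.n_beats`` beats, hence ``n_beats - 1`` intervals, with a
    per-beat label (``"N"`` or ``"PB"``).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_rr = spec.n_beats - 1
    labels = np.full(spec.n_beats, "N", dtype="<U2")
    cls = spec.rhythm_class

    if cls is RhythmClass.NSR:
        rr = _nsr_rr(n_rr, spec, rng)

    elif cls is RhythmClass.AF:
        rr = _truncate(rng.normal(spec.base_rr, spec.af_cv * spec.base_rr, size=n_rr))

    elif cls in (RhythmClass.SINGLE_PB, RhythmClass.MULTI_PB):
        rr = _nsr_rr(n_rr, spec, rng)
        n_pb = 1 if cls is RhythmClass.SINGLE_PB else spec.n_pb
        for p in _pb_positions(spec, n_pb, rng):
            _insert_pb(rr, p, spec)
            labels[p] = "PB"
        rr = _truncate(rr)

    elif cls is RhythmClass.BIGEMINY:
        # Beats N, PB, N, PB, ...; RRs alternate coupling / compensatory.
        base = _truncate(
            rng.normal(spec.base_rr, spec.nsr_cv * spec.base_rr, size=n_rr)
        )
        rr = base.copy()
        rr[0::2] = spec.coupling_fraction * base[0::2]
        rr[1::2] = spec.compensatory_fraction * base[1::2]
        labels[1::2] = "PB"
        rr = _truncate(rr)

    elif cls is RhythmClass.TRIGEMINY:
        # Beats N, N, PB repeating; RRs cycle normal / coupling / compensatory.
        base = _truncate(
            rng.normal(spec.base_rr, spec.nsr_cv * spec.base_rr, size=n_rr)
        )
        rr = base.copy()
        rr[1::3] = spec.coupling_fraction * base[1::3]
        rr[2::3] = spec.compensatory_fraction * base[2::3]
        labels[2::3] = "PB"
        rr = _truncate(rr)

    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown rhythm class {cls}")

    return RRSequence.from_rr(rr, beat_labels=labels)


def _junction_rr(spec: RhythmSpec, rng: np.random.Generator) -> float:
    """Interval bridging into an episode, drawn from that episode's model."""
    if spec.rhythm_class is RhythmClass.AF:
        v = rng.normal(spec.base_rr, spec.af_cv * spec.base_rr)
    else:
        v = rng.normal(spec.base_rr, spec.nsr_cv * spec.base_rr)
    return float(np.clip(v, RR_MIN, RR_MAX))


def gen_recording(
    episodes: list[tuple[RhythmSpec, str]], seed: int = 0
) -> SyntheticRecording:
    """Concatenate rhythm episodes into one annotated recording.

    Each element of ``episodes`` is ``(spec, rhythm_label)`` with
    ``rhythm_label`` in ``{"AFIB", "N"}``.  The rhythm annotation marks the
    first beat of every episode; the ground truth is exactly recoverable.
    Episode seeds are derived from ``seed`` so the recording is reproducible
    regardless of the seeds stored in the specs.
    """
    if not episodes:
        raise ValueError("at least one episode is required")
    rng = np.random.default_rng(seed)
    rr_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    annotation: list[tuple[int, str]] = []
    start = 0
    for k, (spec, rhythm_label) in enumerate(episodes):
        if rhythm_label not in (AF_LABEL, NON_AF_LABEL):
            raise ValueError(f"rhythm_label must be 'AFIB' or 'N', got {rhythm_label!r}")
        ep_seed = int(rng.integers(0, 2**31 - 1))
        ep_spec = RhythmSpec(**{**spec.__dict__, "seed": ep_seed})
        seq = gen_rr(ep_spec)
        if k > 0:
            rr_parts.append(np.array([_junction_rr(ep_spec, rng)]))
        rr_parts.append(seq.rr)
        label_parts.append(seq.beat_labels)
        annotation.append((start, rhythm_label))
        start += spec.n_beats
    rr = np.concatenate(rr_parts)
    labels = np.concatenate(label_parts)
    return SyntheticRecording(
        rr=RRSequence.from_rr(rr, beat_labels=labels),
        beat_labels=labels,
        rhythm_annotation=annotation,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Waveform rendering


def _qrs_template(fs: float, width_s: float = 0.080, amplitude: float = 1.0) -> np.ndarray:
    """Narrow biphasic pulse (Mexican-hat shape) with its |max| at the center."""
    half = int(round(width_s / 2 * fs))
    t = np.arange(-half, half + 1) / fs
    sigma = width_s / 8
    u = (t / sigma) ** 2
    shape = (1.0 - u) * np.exp(-u / 2.0)
    return amplitude * shape / np.max(np.abs(shape))


def render_ecg(
    recording: SyntheticRecording,
    fs: float = 250.0,
    qrs_amplitude: float = 1.0,
    baseline_wander_amp: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a sampled single-lead waveform (mV) plus true QRS sample indices.

    One QRS-like template per beat at the cumulative RR times, additive
    low-frequency (0.3 Hz) sinusoidal baseline wander and white noise.  The
    returned indices are the exact positions of each template's absolute
    maximum, so noiseless renderings give a perfect QRS-detection reference.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz to represent the QRS template, got {fs}")
    rng = np.random.default_rng(seed)
    template = _qrs_template(fs, amplitude=qrs_amplitude)
    half = len(template) // 2
    beat_samples = np.round(recording.rr.beat_times * fs).astype(int) + half
    n = int(round(float(np.sum(recording.rr.rr)) * fs)) + 2 * half + 1
    signal = np.zeros(n)
    for s in beat_samples:
        lo, hi = s - half, s + half + 1
        signal[lo:hi] += template
    if baseline_wander_amp > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        signal += baseline_wander_amp * np.sin(2 * np.pi * 0.3 * t + phase)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=n)
    return signal, beat_samples


# --------------------------------------------------------------------------
# Delimited-text output (one row per beat)

_CSV_FIELDS = ["beat_index", "time_s", "rr_s", "beat_label", "rhythm_label"]


def write_rr_csv(path, recording: SyntheticRecording) -> None:
    """Write a recording as delimited text, one row per beat.

    ``rr_s`` on row *i* is the interval preceding beat *i* (empty for the
    first beat); ``rhythm_label`` is the episode label the beat falls in.
    """
    ann = recording.rhythm_annotation
    starts = [s for s, _ in ann]
    seq = recording.rr
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for i in range(seq.n_beats):
            ep = np.searchsorted(starts, i, side="right") - 1
            w.writerow(
                [
                    i,
                    f"{seq.beat_times[i]:.6f}",
                    f"{seq.rr[i - 1]:.6f}" if i > 0 else "",
                    str(recording.beat_labels[i]),
                    ann[ep][1],
                ]
            )


def read_rr_csv(path) -> SyntheticRecording:
    """Read a recording written by :func:`write_rr_csv` (or any file with the
    same columns; ``beat_label``/``rhythm_label`` default to ``N``)."""
    path = Path(path)
    times: list[float] = []
    beat_labels: list[str] = []
    rhythm_labels: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "time_s" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with a 'time_s' column")
        for row in reader:
            times.append(float(row["time_s"]))
            beat_labels.append(row.get("beat_label") or "N")
            rhythm_labels.append(row.get("rhythm_label") or NON_AF_LABEL)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 beats")
    bt = np.asarray(times)
    labels = np.asarray(beat_labels, dtype="<U2")
    annotation: list[tuple[int, str]] = []
    for i, lab in enumerate(rhythm_labels):
        if i == 0 or lab != rhythm_labels[i - 1]:
            annotation.append((i, lab))
    seq = RRSequence(bt, np.diff(bt), beat_labels=labels)
    return SyntheticRecording(seq, labels, annotation)
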