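"""Minimal WFDB (PhysioNet waveform-database) reading and writing, beat-code
mapping, and premature-beat segment extraction.

Supports single-segment records with a ``.hea`` header, a ``.dat`` signal
file in format 16 (read/write) or 212 (read), and MIT-format annotation
files carrying beat codes and rhythm (aux) annotations such as ``(AFIB``.
That covers writing synthetic records, round-tripping them, and reading the
ambulatory-ECG databases this package targets (MIT-BIH arrhythmia and atrial
fibrillation databases) when the user has downloaded them.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .rr import AF_LABEL, RhythmSegment

__all__ = [
    "Annotation",
    "AnnotatedRecord",
    "PBSegment",
    "PBCategory",
    "BeatClass",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "map_beat_codes",
    "extract_pb_segments",
    "rhythm_segments_from_annotations",
    "DEFAULT_PB_CODES",
    "BEAT_SYMBOLS",
    "RHYTHM_LABELS",
]

log = logging.getLogger(__name__)

# MIT annotation code <-> symbol table (the standard WFDB assignment).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

#: Symbols that annotate a heartbeat (as opposed to rhythm/noise/markers).
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnE/fQ?")

#: Premature-beat codes: atrial premature, aberrated atrial premature,
#: nodal (junctional) premature, ventricular premature, ventricular fusion.
DEFAULT_PB_CODES = frozenset("AaJVF")

#: Documented rhythm labels; anything else is preserved but flagged.
RHYTHM_LABELS = frozenset({"AFIB", "AFL", "J", "N"})

_RHYTHM_CODE = 28  # '+'


class BeatClass(str, Enum):
    N = "N"
    PB = "PB"
    OTHER = "OTHER"


class PBCategory(str, Enum):
    SINGLE_PB = "SINGLE_PB"
    MULTI_PB = "MULTI_PB"
    BIGEMINY = "BIGEMINY"
    TRIGEMINY = "TRIGEMINY"


@dataclass
class Annotation:
    sample: int
    symbol: str
    aux: str = ""


@dataclass
class AnnotatedRecord:
    """A WFDB record in physical units with its beat and rhythm annotations."""

    name: str
    fs: float
    signal: np.ndarray  # (n_samples, n_sig), mV
    sig_names: list[str] = field(default_factory=list)
    beat_samples: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    beat_codes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype="<U1"))
    rhythm_intervals: list[tuple[int, str]] = field(default_factory=list)
    unknown_rhythm_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_samples = np.asarray(self.beat_samples, dtype=int)
        self.beat_codes = np.asarray(self.beat_codes)
        if self.beat_samples.size and np.any(np.diff(self.beat_samples) <= 0):
            raise ValueError("beat_samples must be strictly increasing")
        if self.beat_samples.shape[0] != self.beat_codes.shape[0]:
            raise ValueError("beat_samples and beat_codes must have equal length")


@dataclass
class PBSegment:
    """31-beat (30-RR) window centered on a premature beat."""

    rr: np.ndarray
    beat_codes: np.ndarray
    category: PBCategory
    record: str
    first_beat: int

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.beat_codes = np.asarray(self.beat_codes)
        if self.beat_codes.shape[0] != 31 or self.rr.shape[0] != 30:
            raise ValueError("a PB segment has exactly 31 beats and 30 RR intervals")


# --------------------------------------------------------------------------
# Header + signal


def _parse_gain(tok: str) -> tuple[float, int, str]:
    """Parse a 'gain(baseline)/units' token."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = 0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_record(path, annotator: str = "atr") -> AnnotatedRecord:
    """Read a WFDB record (``path`` has no extension); annotations optional.

    Raises ``FileNotFoundError`` naming the missing header or signal file.
    Unknown rhythm labels in the annotation file are retained and listed in
    ``unknown_rhythm_labels`` with a warning.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header file: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    sig_lines = lines[1 : 1 + n_sig]
    files: dict[str, list[tuple[int, int, float, int, str]]] = {}
    order = []
    for ch, ln in enumerate(sig_lines):
        toks = ln.split()
        fname, fmt = toks[0], int(toks[1].split("x")[0])
        gain, baseline, units = _parse_gain(toks[2]) if len(toks) > 2 else (200.0, 0, "mV")
        desc = " ".join(toks[9:]) if len(toks) > 9 else f"ch{ch}"
        files.setdefault(fname, []).append((ch, fmt, gain, baseline, desc))
        order.append(desc)

    signal = np.zeros((n_samples, n_sig))
    for fname, chans in files.items():
        dat = path.parent / fname
        if not dat.exists():
            raise FileNotFoundError(f"missing WFDB signal file: {dat}")
        raw = dat.read_bytes()
        fmt = chans[0][1]
        k = len(chans)
        if fmt == 16:
            d = np.frombuffer(raw, dtype="<i2")
            d = d[: (len(d) // k) * k].reshape(-1, k)
        elif fmt == 212:
            d = _decode_212(raw)
            d = d[: (len(d) // k) * k].reshape(-1, k)
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt} in {dat}")
        m = min(d.shape[0], n_samples) if n_samples else d.shape[0]
        if n_samples == 0:
            n_samples = d.shape[0]
            signal = np.zeros((n_samples, n_sig))
        for col, (ch, _fmt, gain, baseline, _desc) in enumerate(chans):
            signal[:m, ch] = (d[:m, col].astype(float) - baseline) / gain

    record = AnnotatedRecord(name=name, fs=fs, signal=signal, sig_names=order)
    ann_path = path.with_suffix(f".{annotator}")
    if ann_path.exists():
        anns = read_annotations(ann_path)
        _populate_annotations(record, anns)
    return record


def _decode_212(raw: bytes) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit samples per 3 bytes."""
    b = np.frombuffer(raw[: (len(raw) // 3) * 3], dtype=np.uint8).reshape(-1, 3)
    s1 = (b[:, 0].astype(np.int32) | ((b[:, 1].astype(np.int32) & 0x0F) << 8))
    s2 = (b[:, 2].astype(np.int32) | ((b[:, 1].astype(np.int32) & 0xF0) << 4))
    s1[s1 > 2047] -= 4096
    s2[s2 > 2047] -= 4096
    return np.column_stack([s1, s2]).reshape(-1)


def _populate_annotations(record: AnnotatedRecord, anns: list[Annotation]) -> None:
    beats = [(a.sample, a.symbol) for a in anns if a.symbol in BEAT_SYMBOLS]
    if beats:
        samples, codes = zip(*beats)
        samples = np.asarray(samples, dtype=int)
        codes = np.asarray(codes)
        keep = np.concatenate([[True], np.diff(samples) > 0])
        record.beat_samples = samples[keep]
        record.beat_codes = codes[keep]
    rhythms: list[tuple[int, str]] = []
    unknown: list[str] = []
    for a in anns:
        if a.symbol == "+" and a.aux:
            label = a.aux.lstrip("(").rstrip("\x00")
            if label not in RHYTHM_LABELS:
                unknown.append(label)
                log.warning("unknown rhythm label %r at sample %d (retained)", label, a.sample)
            rhythms.append((a.sample, label))
    record.rhythm_intervals = rhythms
    record.unknown_rhythm_labels = unknown


def write_record(
    path,
    record: AnnotatedRecord,
    gain: float = 200.0,
    annotator: str = "atr",
) -> None:
    """Write a record as header + format-16 signal (+ annotations if present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sig = np.atleast_2d(np.asarray(record.signal, dtype=float))
    if sig.shape[0] < sig.shape[1]:  # tolerate (n_sig, n) input
        sig = sig.T
    n_samples, n_sig = sig.shape
    digital = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
    dat_name = f"{path.name}.dat"
    with open(path.with_suffix(".dat"), "wb") as fh:
        fh.write(digital.reshape(-1).tobytes())
    lines = [f"{path.name} {n_sig} {int(record.fs) if record.fs == int(record.fs) else record.fs} {n_samples}"]
    for ch in range(n_sig):
        first = int(digital[0, ch]) if n_samples else 0
        checksum = int(np.sum(digital[:, ch], dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        desc = record.sig_names[ch] if ch < len(record.sig_names) else f"ch{ch}"
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 {desc}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    if record.beat_samples.size or record.rhythm_intervals:
        anns = [
            Annotation(int(s), str(c))
            for s, c in zip(record.beat_samples, record.beat_codes)
        ]
        anns += [
            Annotation(int(s), "+", aux=lab if lab.startswith("(") else f"({lab}")
            for s, lab in record.rhythm_intervals
        ]
        anns.sort(key=lambda a: (a.sample, a.symbol != "+"))
        write_annotations(path.with_suffix(f".{annotator}"), anns)


# --------------------------------------------------------------------------
# MIT annotation format

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_annotations(path) -> list[Annotation]:
    """Parse an MIT-format annotation file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB annotation file: {path}")
    data = path.read_bytes()
    anns: list[Annotation] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            skip = (high << 16) | low
            if skip >= 1 << 31:
                skip -= 1 << 32
            pending_skip += skip
        elif code in (_NUM, _SUB, _CHN):
            pass  # sub/chan/num fields are not used by this package
        elif code == _AUX:
            aux = data[i : i + delta].decode("latin-1").rstrip("\x00")
            i += delta + (delta % 2)
            if anns:
                anns[-1].aux = aux
        else:
            t += delta + pending_skip
            pending_skip = 0
            symbol = _CODE_TO_SYMBOL.get(code)
            if symbol is None:
                log.warning("unknown annotation code %d at sample %d (retained as '?')", code, t)
                symbol = "?"
            anns.append(Annotation(t, symbol))
    return anns


def write_annotations(path, anns: list[Annotation]) -> None:
    """Write annotations in MIT format (sorted by sample)."""
    anns = sorted(anns, key=lambda a: a.sample)
    out = bytearray()
    prev = 0
    for a in anns:
        code = _SYMBOL_TO_CODE.get(a.symbol)
        if code is None:
            raise ValueError(f"cannot encode annotation symbol {a.symbol!r}")
        dt = a.sample - prev
        if dt < 0:
            raise ValueError("annotations must be sorted by sample")
        if dt > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (code << 10) | dt)
        if a.aux:
            raw = a.aux.encode("latin-1")
            out += struct.pack("<H", (_AUX << 10) | len(raw))
            out += raw
            if len(raw) % 2:
                out += b"\x00"
        prev = a.sample
    out += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(out))


# --------------------------------------------------------------------------
# Beat-code mapping and PB segment extraction


def map_beat_codes(beat_codes, pb_codes=DEFAULT_PB_CODES) -> list[BeatClass]:
    """Map annotation symbols to {N, PB, OTHER}.

    Premature codes map to PB; every other recognized beat code maps to N
    (normal beats and non-AF, non-premature rhythms alike); non-beat symbols
    map to OTHER and are logged.
    """
    out = []
    for c in beat_codes:
        c = str(c)
        if c in pb_codes:
            out.append(BeatClass.PB)
        elif c in BEAT_SYMBOLS:
            out.append(BeatClass.N)
        else:
            log.debug("non-beat code %r mapped to OTHER", c)
            out.append(BeatClass.OTHER)
    return out


_BIGEMINY_PATTERNS = ("*N*N*N", "N*N*N*")
_TRIGEMINY_PATTERNS = ("*NN*NN", "N*NN*N", "NN*NN*")


def categorize_pattern(pattern: str) -> PBCategory | None:
    """Classify a '*'/'N' pattern string by the segment-definition rules."""
    if any(p in pattern for p in _BIGEMINY_PATTERNS):
        return PBCategory.BIGEMINY
    if any(p in pattern for p in _TRIGEMINY_PATTERNS):
        return PBCategory.TRIGEMINY
    n_pb = pattern.count("*")
    if n_pb >= 2:
        return PBCategory.MULTI_PB
    if n_pb == 1:
        return PBCategory.SINGLE_PB
    return None


def _af_mask(record: AnnotatedRecord) -> np.ndarray:
    """Per-beat: does the beat fall inside an AFIB rhythm interval?"""
    n = record.beat_samples.shape[0]
    mask = np.zeros(n, dtype=bool)
    if not record.rhythm_intervals:
        return mask
    starts = np.array([s for s, _ in record.rhythm_intervals])
    labels = [lab for _, lab in record.rhythm_intervals]
    idx = np.searchsorted(starts, record.beat_samples, side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)  # beats before the first interval take it
    return np.array([labels[i] == AF_LABEL for i in idx])


def extract_pb_segments(record: AnnotatedRecord, pb_codes=DEFAULT_PB_CODES) -> list[PBSegment]:
    """Extract 31-beat windows centered on premature beats.

    Each premature beat with at least 15 beats on both sides yields one
    window; windows sharing premature beats with an earlier kept window are
    skipped, and windows overlapping AFIB rhythm intervals are discarded.
    """
    classes = map_beat_codes(record.beat_codes, pb_codes)
    pb_idx = [i for i, c in enumerate(classes) if c is BeatClass.PB]
    af = _af_mask(record)
    n = len(classes)
    segments: list[PBSegment] = []
    used_pb: set[int] = set()
    for center in pb_idx:
        if center in used_pb:
            continue
        lo, hi = center - 15, center + 16
        if lo < 0 or hi > n:
            continue
        if af[lo:hi].any():
            log.info("PB window at beat %d overlaps an AFIB interval; discarded", center)
            continue
        window_pb = [i for i in range(lo, hi) if classes[i] is BeatClass.PB]
        pattern = "".join("*" if classes[i] is BeatClass.PB else "N" for i in range(lo, hi))
        category = categorize_pattern(pattern)
        if category is None:  # pragma: no cover - center is always PB
            continue
        used_pb.update(window_pb)
        rr = np.diff(record.beat_samples[lo:hi]) / record.fs
        segments.append(
            PBSegment(
                rr=rr,
                beat_codes=record.beat_codes[lo:hi],
                category=category,
                record=record.name,
                first_beat=lo,
            )
        )
    return segments


def rhythm_segments_from_annotations(record: AnnotatedRecord) -> list[RhythmSegment]:
    """Maximal runs of same-rhythm beats as half-open beat-index segments.

    A beat is AF iff it falls inside an AFIB interval (atrial flutter and
    junctional rhythm count as non-AF); beats before the first rhythm
    annotation take the first interval's label.
    """
    if not record.rhythm_intervals:
        raise ValueError(f"record {record.name} has no rhythm annotations")
    af = _af_mask(record)
    segments: list[RhythmSegment] = []
    start = 0
    for i in range(1, len(af) + 1):
        if i == len(af) or af[i] != af[start]:
            segments.append(
                RhythmSegment(start, i, AF_LABEL if af[start] else "N")
            )
            start = i
    return segments
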