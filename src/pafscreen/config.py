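"""Pipeline configuration: every tunable of the detector in one serializable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the screening pipeline with their defaults.

    The rhythm-change threshold is the single parameter that matters most: it
    separates the low-variability sinus regime from the high-variability AF
    regime and also drives the recheck decisions of the rejection cascade.
    """

    # screening.*
    threshold: float = 0.10            # Rc flag level, dimensionless
    std_mode: str = "population"       # "population" (divide by 6) or "sample"
    merge_gap_beats: int = 6           # flagged runs closer than this merge

    # reject.*
    single_pb_max_run: int = 10        # runs of flagged beats <= this are single-PB
    geminy_min_count: int = 2          # short/long counts per 6-RR window
    reject_order: tuple[str, ...] = ("geminy", "multi")

    # baseline.*
    baseline_win1_ms: float = 200.0
    baseline_win2_ms: float = 600.0

    # sqa.*
    sqa_window_s: float = 2.0
    sqa_flatline_uv: float = 50.0      # peak-to-peak floor, microvolts
    sqa_rail_fraction: float = 0.2     # saturation: fraction of samples at rail
    sqa_mad_factor: float = 6.0        # no-QRS rule: max|x| < factor * MAD

    # qrs.*
    refine_radius_ms: float = 50.0

    input_mode: str = "rr"             # "rr" or "waveform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if self.std_mode not in ("population", "sample"):
            raise ValueError(f"std_mode must be 'population' or 'sample', got {self.std_mode!r}")
        if self.merge_gap_beats < 0:
            raise ValueError("merge_gap_beats must be >= 0")
        if self.single_pb_max_run < 1:
            raise ValueError("single_pb_max_run must be >= 1")
        if self.input_mode not in ("rr", "waveform"):
            raise ValueError(f"input_mode must be 'rr' or 'waveform', got {self.input_mode!r}")
        if isinstance(self.reject_order, list):
            self.reject_order = tuple(self.reject_order)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reject_order"] = list(self.reject_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
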