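"""Analysis configuration: every threshold and constant in one place.

Defaults encode the analysis conventions used throughout: 18-degree
phase bins, 500 time-offset shuffles with 1-3 s offsets, 500-ms
segments, the 200-trough / 300-spike inclusion rules, and the
slow/medium/fast speed bins in cm/s.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    # theta extraction
    theta_band_hz: tuple = (4.0, 12.0)
    theta_min_interval_s: float = 0.065
    theta_prominence_frac: float = 0.25
    # paw trough detection
    paw_min_interval_s: float = 0.06
    paw_prominence_frac: float = 0.25
    # circular statistics
    bin_deg: int = 18
    rayleigh_method: str = "zar"
    min_events: int = 200
    # shuffle test
    n_shuffles: int = 500
    offset_range_s: tuple = (1.0, 3.0)
    # parcellation
    seg_len_s: float = 0.5
    speed_bins_cms: tuple = ((2.0, 7.0), (7.0, 13.0), (13.0, 19.0))
    speed_window_s: float = 1.0
    run_min_speed_cms: float = 2.0
    reward_halfwidth_s: float = 1.0
    # unit analyses
    min_spikes: int = 300
    peth_window_s: float = 0.5
    peth_bin_s: float = 0.01
    n_perm: int = 10_000
    # spectra
    psd_seg_len_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta_band_hz[0] < self.theta_band_hz[1]):
            raise ValueError("invalid theta band")
        if 360 % self.bin_deg != 0:
            raise ValueError("bin_deg must divide 360")
        if self.n_shuffles < 1 or self.min_events < 0 or self.min_spikes < 0:
            raise ValueError("counts must be non-negative")
        if not (0 < self.offset_range_s[0] < self.offset_range_s[1]):
            raise ValueError("invalid shuffle offset range")
        if self.seg_len_s <= 0 or self.speed_window_s <= 0:
            raise ValueError("window lengths must be positive")
        for lo, hi in self.speed_bins_cms:
            if not lo < hi:
                raise ValueError("speed bins must have lo < hi")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("theta_band_hz", "offset_range_s"):
            if key in d:
                d[key] = tuple(d[key])
        if "speed_bins_cms" in d:
            d["speed_bins_cms"] = tuple(tuple(b) for b in d["speed_bins_cms"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
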