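"""Pipeline configuration.

Every numeric threshold used by the five processing stages, the certainty
flags and the simulator lives in :class:`PipelineConfig`.  Defaults encode the
study protocol the pipeline implements: a 10-minute trip-split gap, the
plausible-altitude band for a hilly UK city (19-592 m with error buffers),
the 7 m/s non-vehicular speed ceiling with a 20 m GPS-jump allowance, 10 s
interpolation, a ~5-minute moving-average window with a 50 % inside-boundary
requirement, and the 25 m / 5 m/s / 50 % certainty-flag cut-offs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    #: stage 1 -- split a device's stream into trips at time gaps > gap_s
    gap_s: float = 600.0
    #: stage 2 -- plausible altitude band (min/max of the study area) and
    #: the error buffers applied below/above it
    alt_min_m: float = 19.0
    alt_max_m: float = 592.0
    alt_upper_buffer_m: float = 30.0
    alt_lower_buffer_m: float = 1.0
    #: stage 2 -- trips shorter than this, or with fewer points, are dropped
    min_trip_duration_s: float = 70.0
    min_trip_points: int = 3
    #: stage 2 -- jump criterion: dist3d > vmax_clean_ms * dt + jump_allowance_m
    vmax_clean_ms: float = 7.0
    jump_allowance_m: float = 20.0
    #: stage 3 -- interpolation grid spacing
    interp_interval_s: float = 10.0
    #: stage 4 -- moving-average window and thresholds
    ma_window_s: float = 300.0
    inside_min_frac: float = 0.5
    vmax_filter_ms: float = 7.0
    #: stage 5 -- certainty-flag thresholds
    flag_min_distance_m: float = 25.0
    flag_entrance_max_m: float = 25.0
    flag_vmax_ms: float = 5.0
    flag_building_max_frac: float = 0.5
    flag_inside_min_frac: float = 0.5
    #: geofence radius around greenspace boundaries (simulation only)
    geofence_buffer_m: float = 10.0
    #: user-summary subsetting ("users with >= 5 trips")
    min_user_trips: int = 5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        for name in ("inside_min_frac", "flag_building_max_frac", "flag_inside_min_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if not (self.alt_min_m - self.alt_lower_buffer_m
                < self.alt_max_m + self.alt_upper_buffer_m):
            raise ValueError("altitude band is empty after applying buffers")

    @property
    def alt_lo(self) -> float:
        """Lower altitude bound including the error buffer."""
        return self.alt_min_m - self.alt_lower_buffer_m

    @property
    def alt_hi(self) -> float:
        """Upper altitude bound including the error buffer."""
        return self.alt_max_m + self.alt_upper_buffer_m

    def replace(self, **kwargs) -> "PipelineConfig":
        d = asdict(self)
        d.update(kwargs)
        return PipelineConfig(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat-key YAML file; absent keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
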