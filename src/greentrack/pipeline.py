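"""End-to-end orchestration of the five processing stages.

``run_pipeline`` takes a projected fix frame and a greenspace map and runs
segmentation -> cleaning -> interpolation -> boundary/speed filtering ->
attribute and flag computation, returning the trip records together with
per-stage counts and the cleaning audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cleaning import clean
from .config import PipelineConfig
from .gsmap import GreenspaceMap
from .interpolation import interpolate_trips
from .io import iter_trips
from .metrics import build_records
from .segmentation import segment_frame
from .stage4 import apply_stage4


@dataclass
class PipelineResult:
    records: pd.DataFrame
    paths: list[pd.DataFrame] = field(repr=False)
    clean_audit: pd.DataFrame = field(repr=False)
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    fixes: pd.DataFrame,
    gsmap: GreenspaceMap,
    cfg: PipelineConfig | None = None,
    homes: dict[str, tuple[float, float]] | None = None,
) -> PipelineResult:
    """Run stages 1-5 on a projected fix frame (columns incl. x, y, alt)."""
    cfg = cfg or PipelineConfig()
    segmented = segment_frame(fixes, cfg.gap_s)
    trips = list(iter_trips(segmented))
    cleaned, audit = clean(trips, cfg)
    interp = interpolate_trips(cleaned, cfg.interp_interval_s)
    paths = apply_stage4(interp, gsmap, cfg)
    records = build_records(paths, gsmap, cfg, homes=homes)
    counts = {
        "fixes_in": len(fixes),
        "trips_segmented": len(trips),
        "trips_cleaned": len(cleaned),
        "paths_final": len(paths),
        "trips_zero_flags": int((records["n_flags"] == 0).sum()) if len(records) else 0,
    }
    return PipelineResult(records=records, paths=paths, clean_audit=audit, counts=counts)
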