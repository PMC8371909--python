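"""Analysis configuration: every numeric constant of the pipeline in one place.

Defaults reproduce the published protocol: 20 N contact threshold, 12 ms
drop-off lead, 100 ms pre-contact mark, 150 ms gravity lead, +/-25 ms EMG
windows, 0.3 g gravity-excursion exclusion, 3.09 um reference sarcomere
length, and the human length-tension breakpoints.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_LT_BREAKPOINTS = (
    (1.27, 0.0),
    (1.67, 0.677),
    (2.64, 1.0),
    (2.81, 1.0),
    (4.24, 0.0),
)


@dataclass
class AnalysisConfig:
    # --- phase detection ---
    grf_threshold_n: float = 20.0
    debounce_s: float = 0.005          # GRF must hold past threshold this long
    min_flight_s: float = 0.050        # shortest interval accepted as flight
    do_lead_s: float = 0.012           # DO precedes fall onset by 12 ms
    pre_gc_s: float = 0.100            # PRE100 mark
    unload_fraction: float = 0.2       # platform-load fraction marking fall onset
    per_plate_threshold: bool = False  # gate on summed plates by default
    # --- gravity clustering ---
    gravity_lead_s: float = 0.150
    gravity_dev_limit_g: float = 0.3
    # --- EMG ---
    emg_halfwidth_s: float = 0.025
    # --- ultrasound segmentation ---
    threshold_quantile: float = 0.92
    selem_rows: int = 3
    selem_cols: int = 15
    min_band_area_px: int = 400
    min_band_coverage: float = 0.60    # fraction of image width a band must span
    use_ultrasound: bool = True
    include_braking_frames: bool = False
    # --- sarcomere model ---
    sl_ref_um: float = 3.09
    lt_breakpoints: tuple = DEFAULT_LT_BREAKPOINTS
    # --- reporting ---
    delta_grf_mode: str = "peak"       # "peak" (interval max - GC) or "instant"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["lt_breakpoints"] = [list(bp) for bp in self.lt_breakpoints]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "lt_breakpoints" in d:
            d["lt_breakpoints"] = tuple(tuple(bp) for bp in d["lt_breakpoints"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
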