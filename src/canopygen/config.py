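"""Run configuration: every tunable parameter of the pipeline in one place."""
from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

# (low, high, low_inclusive) legal ranges checked at load time
_RANGES = {
    "ground_cell": (0.0, 100.0, False),
    "ground_k_mad": (0.0, 100.0, True),
    "raster_cell": (0.0, 100.0, False),
    "min_tree_height": (0.0, 1000.0, True),
    "max_crown_radius": (0.0, 1000.0, False),
    "apex_window_radius": (0.0, 1000.0, False),
    "th_seed": (0.0, 1.0, True),
    "th_crown": (0.0, 1.0, True),
    "slice_height": (0.0, 10.0, False),
    "cbh_spread_factor": (0.0, 100.0, False),
    "min_cbh": (0.0, 100.0, True),
    "trunk_radius": (0.0, 10.0, True),
    "maf_min": (0.0, 0.5, True),
    "call_rate_min": (0.0, 1.0, True),
    "h2_coefficient": (0.0, 10.0, False),
    "log10p_sig05": (0.0, 100.0, True),
    "log10p_sig01": (0.0, 100.0, True),
}


@dataclass
class RunConfig:
    """Defaults mirror the pipeline's documented parameter choices.

    Segmentation thresholds (2.6 m minimum height, 2.5 m maximum crown
    radius) follow the study design this pipeline targets; region-growing
    thresholds are the published defaults of the Dalponte CHM algorithm.
    """

    # ground classification / rasters
    ground_cell: float = 1.0
    ground_k_mad: float = 3.0
    raster_cell: float = 0.25
    # segmentation
    min_tree_height: float = 2.6
    max_crown_radius: float = 2.5
    apex_window_radius: float = 1.5
    th_seed: float = 0.45
    th_crown: float = 0.55
    # trait extraction
    slice_height: float = 0.25
    cbh_spread_factor: float = 3.0
    min_cbh: float = 0.3
    trunk_radius: float = 0.25
    # genetics
    maf_min: float = 0.05
    call_rate_min: float = 0.9
    h2_coefficient: float = 2.5
    log10p_sig05: float = 4.0
    log10p_sig01: float = 5.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi, lo_inc) in _RANGES.items():
            v = getattr(self, name)
            ok = (v >= lo if lo_inc else v > lo) and v <= hi
            if not ok:
                raise ValueError(
                    f"RunConfig.{name}={v} outside legal range "
                    f"{'[' if lo_inc else '('}{lo}, {hi}]")
        if self.log10p_sig01 < self.log10p_sig05:
            raise ValueError("log10p_sig01 must be >= log10p_sig05")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
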