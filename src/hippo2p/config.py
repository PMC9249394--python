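"""Run configuration: defaults, TOML loading, validation.

The defaults reproduce every analysis constant of the published pipeline
(72 track bins, 20 mm/s movement threshold with 1 s minimum and 0.5 s
buffer, 180 mm/s lap cutoff, 500 consistency iterations at KS alpha 0.01
and Cohen's D 0.5, Gaussian-fit criteria, 100 speed shuffles gated at the
1st/99th percentiles with >10-frame shifts, 1 um^2 spine inclusion, 10 um
dendrite sections, 50 um histology bins with 1000 bootstrap resamples).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # track
    outer_diameter_mm: float = 250.0
    inner_diameter_mm: float = 140.0
    n_bins: int = 72
    # movement filter
    speed_threshold_mm_s: float = 20.0
    min_move_dur_s: float = 1.0
    move_buffer_s: float = 0.5
    lap_speed_cutoff_mm_s: float = 180.0
    # consistency test
    n_consistency_iter: int = 500
    ks_alpha: float = 0.01
    cohens_d_min: float = 0.5
    # Gaussian-fit criteria
    adj_r2_min: float = 0.375
    fwhm_min_cm: float = 2.5
    fwhm_max_cm: float = 30.6
    amp_ratio_min: float = 0.50
    # speed cells
    n_speed_shuffles: int = 100
    speed_min_shift_frames: int = 10
    speed_pct_hi: float = 99.0
    speed_pct_lo: float = 1.0
    # spines
    spine_min_area_um2: float = 1.0
    density_section_um: float = 10.0
    um_per_px_spines: float = 52.0 / 760.0
    # axis
    axis_n_bins: int = 5
    axis_range_um: float = 600.0
    axis_window_um: float = 200.0
    axis_step_um: float = 50.0
    n_boot: int = 1000
    n_shuffle: int = 1000
    # histology
    histology_bin_um: float = 50.0
    histology_n_boot: int = 1000
    # bookkeeping
    seed: int = 0
    output_dir: str = "hippo2p_out"
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        positive = (
            "outer_diameter_mm",
            "inner_diameter_mm",
            "n_bins",
            "speed_threshold_mm_s",
            "min_move_dur_s",
            "lap_speed_cutoff_mm_s",
            "n_consistency_iter",
            "ks_alpha",
            "cohens_d_min",
            "fwhm_min_cm",
            "fwhm_max_cm",
            "n_speed_shuffles",
            "spine_min_area_um2",
            "density_section_um",
            "histology_bin_um",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.fwhm_max_cm <= self.fwhm_min_cm:
            raise ValueError("fwhm_max_cm must exceed fwhm_min_cm")
        if not (0 < self.ks_alpha < 1):
            raise ValueError("ks_alpha must be in (0, 1)")

    def hash(self) -> str:
        """Stable hash of the configuration, embedded in reports."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a TOML config file, apply keyword overrides, validate."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**data)
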