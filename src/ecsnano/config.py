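"""Run configuration: a single YAML document with per-module sections.

Every constant the analysis depends on (exposure 30 ms, 3-frame averaging,
1 px drift threshold, 40 nm quiet-displacement cutoff, 100 nm exciton
correction, 450 ms MSD window, 90 ms fit span, 25 nm map pixels, 50 nm map
FWHM, 6-point confinement window, width category bounds) lives here so a
run is fully reproducible from its config and seed.  The config is
validated before any stage executes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "ecsnano_run"
    # camera / rendering
    pixel_size_nm: float = 100.0
    exposure_s: float = 0.030
    amplitude: float = 300.0
    background: float = 10.0
    gain: float = 1.0
    read_noise_sd: float = 1.0
    psf_fwhm_nm: float = 400.0
    fov_px: tuple = (64, 64)
    # scene / walker
    n_pools: int = 3
    pool_radius_range_nm: tuple = (80.0, 150.0)
    channel_width_range_nm: tuple = (40.0, 90.0)
    # hindered probe diffusivity ~ 0.026 of the free rod reference
    diffusivity_nm2_s: float = 2.6e5
    n_frames: int = 240
    probe_length_nm: float = 500.0
    drift_px_per_frame: tuple = (0.02, 0.01)
    background_spots: int = 30  # static features for drift tracking
    background_spot_amp_factor: float = 0.15  # dim: tracked by RCC, not fitted
    # localization
    average_window: int = 3
    detect_threshold_sd: float = 20.0
    fit_window_px: int = 15
    # drift correction
    drift_residual_threshold_px: float = 1.0
    drift_smoothing_window: int = 5
    # tracking
    max_step_nm: float = 500.0
    memory_frames: int = 3
    min_track_length: int = 20
    displacement_cutoff_nm: float = 40.0
    exciton_correction_nm: float = 100.0
    # diffusivity / maps
    msd_window_s: float = 0.450
    msd_fit_span_s: float = 0.090
    temperature_K: float = 310.15
    viscosity_Pa_s: float = 0.70e-3
    probe_diameter_nm: float = 1.0
    map_pixel_nm: float = 25.0
    map_fwhm_nm: float = 50.0
    # dimensions
    confinement_points: int = 6
    confinement_quartile: float = 0.25

    def validate(self) -> "RunConfig":
        checks = {
            "pixel_size_nm": self.pixel_size_nm > 0,
            "exposure_s": self.exposure_s > 0,
            "average_window": self.average_window >= 1,
            "n_frames": self.n_frames >= self.average_window,
            "drift_residual_threshold_px":
                self.drift_residual_threshold_px > 0,
            "msd_window_s": self.msd_window_s >= 4 * self.exposure_s,
            "msd_fit_span_s": 0 < self.msd_fit_span_s <= self.msd_window_s,
            "map_pixel_nm": self.map_pixel_nm > 0,
            "map_fwhm_nm": self.map_fwhm_nm > 0,
            "confinement_points": self.confinement_points >= 3,
            "confinement_quartile": 0 < self.confinement_quartile <= 1,
            "temperature_K": self.temperature_K > 0,
            "viscosity_Pa_s": self.viscosity_Pa_s > 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ConfigError(f"invalid or missing fields: {bad}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fov_px", "pool_radius_range_nm",
                    "channel_width_range_nm", "drift_px_per_frame"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        return cfg.validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
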