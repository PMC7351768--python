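"""End-to-end orchestration: simulate -> localize -> drift -> track ->
diffusivity maps -> dimension maps, with a reproducibility manifest.

Every stage writes its intermediates under the configured output directory
and records them (with SHA-256 checksums) in ``manifest.json``; a failure
halts the run with a stage-named error while earlier outputs are kept.
Identical configs and seeds produce checksum-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .diffusivity import (ReferenceMedium, make_map, relative_diffusivity)
from .dimensions import confinement_windows, estimate_local_width, dimension_map
from .drift_correction import apply_drift, pairwise_shifts, solve_drift
from .localization import LocalizeParams, average_frames, localize_movie
from .synthetic_data import (CameraModel, generate_geometry, render_movie,
                             simulate_walker)
from .tracking import classify_immobile, estimate_length, link_trajectories

__all__ = ["run_pipeline", "PipelineError"]

STAGES = ("simulate", "localize", "drift", "track", "diffusivity",
          "dimensions")


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def _background_roi(locs: pd.DataFrame, movie_shape, pixel_size_nm,
                    pad_px: int = 10) -> tuple[int, int]:
    """Row band with static background features only.

    Cross-correlation drift estimation must see a region free of the
    moving probe, so the widest horizontal strip outside the probe's
    explored bounding box (padded for its extended emission profile) is
    selected; falls back to the full frame if the probe covers everything.
    """
    nr = movie_shape[1]
    acc = locs[locs["accepted"]] if "accepted" in locs.columns else locs
    if not len(acc):
        return 0, nr
    y = acc["y_nm"].to_numpy() / pixel_size_nm
    top = int(np.floor(y.min())) - pad_px
    bottom = int(np.ceil(y.max())) + pad_px
    if top >= nr - bottom:
        strip = (0, max(top, 0))
    else:
        strip = (min(bottom, nr), nr)
    if strip[1] - strip[0] < 8:
        return 0, nr
    return strip


def run_pipeline(config: RunConfig) -> dict:
    """Run all six stages on a synthetic scene; return the manifest."""
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ecsnano",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "stages": {},
    }
    files: dict[str, Path] = {}

    def record(stage, **outputs):
        entry = {}
        for name, path in outputs.items():
            files[name] = path
            entry[name] = {
                "path": path.name,
                "sha256": _sha256(path),
            }
        manifest["stages"][stage] = entry

    # --- simulate ---------------------------------------------------------
    try:
        seeds = np.random.SeedSequence(cfg.seed).spawn(3)
        geom = generate_geometry(
            cfg.n_pools, cfg.pool_radius_range_nm,
            cfg.channel_width_range_nm,
            seed=int(seeds[0].generate_state(1)[0] % 2**31),
        )
        track = simulate_walker(
            geom, cfg.diffusivity_nm2_s, cfg.n_frames - 1, cfg.exposure_s,
            seed=int(seeds[1].generate_state(1)[0] % 2**31),
            probe_length_nm=cfg.probe_length_nm,
        )
        cam = CameraModel(cfg.pixel_size_nm, cfg.exposure_s, cfg.amplitude,
                          cfg.background, cfg.gain, cfg.read_noise_sd)
        drift_true = (np.arange(cfg.n_frames)[:, None]
                      * np.asarray(cfg.drift_px_per_frame))
        # keep the emitter in view: centre the geometry in the field
        fov_nm = np.array([cfg.fov_px[1], cfg.fov_px[0]]) * cfg.pixel_size_nm
        shift = fov_nm / 2 - track.positions.mean(axis=0)
        track.positions = track.positions + shift
        movie, truth = render_movie(
            track, cam, drift_true,
            seed=int(seeds[2].generate_state(1)[0] % 2**31),
            fov_px=cfg.fov_px, psf_fwhm_nm=cfg.psf_fwhm_nm,
            exciton_length_nm=cfg.exciton_correction_nm,
            background_spots=cfg.background_spots,
            background_spot_amplitude=cfg.background_spot_amp_factor
            * cfg.amplitude,
        )
        movie_path = out / "movie.tif"
        tifffile.imwrite(movie_path, movie)
        truth_path = out / "truth.csv"
        _write_csv(truth, truth_path)
        record("simulate", movie=movie_path, truth=truth_path)
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError("simulate", e) from e

    # --- localize ---------------------------------------------------------
    try:
        params = LocalizeParams(
            pixel_size_nm=cfg.pixel_size_nm, window=cfg.average_window,
            detect_threshold_sd=cfg.detect_threshold_sd,
            fit_window_px=cfg.fit_window_px,
        )
        locs, log = localize_movie(movie, params)
        locs_path = out / "localizations.csv"
        _write_csv(locs, locs_path)
        record("localize", localizations=locs_path)
    except Exception as e:
        raise PipelineError("localize", e) from e

    # --- drift ------------------------------------------------------------
    try:
        avg = average_frames(movie, cfg.average_window)
        roi = _background_roi(locs, avg.shape, cfg.pixel_size_nm)
        eqs = pairwise_shifts(avg[:, roi[0] : roi[1], :])
        drift = solve_drift(eqs, cfg.drift_residual_threshold_px,
                            cfg.drift_smoothing_window)
        offset = (cfg.average_window - 1) // 2
        corrected = apply_drift(locs, drift, cfg.pixel_size_nm,
                                t_offset=-offset)
        drift_df = pd.DataFrame(
            {
                "frame": np.arange(len(drift.r_px)),
                "rx_px": drift.r_px[:, 0],
                "ry_px": drift.r_px[:, 1],
                "n_eqs": drift.n_equations,
            }
        )
        drift_path = out / "drift.csv"
        _write_csv(drift_df, drift_path)
        corr_path = out / "localizations_corrected.csv"
        _write_csv(corrected, corr_path)
        record("drift", drift=drift_path, corrected=corr_path)
    except Exception as e:
        raise PipelineError("drift", e) from e

    # --- track ------------------------------------------------------------
    try:
        trajs = link_trajectories(
            corrected, cfg.max_step_nm, cfg.memory_frames,
            cfg.min_track_length, dt_s=cfg.exposure_s,
        )
        for t in trajs:
            estimate_length(t, cfg.displacement_cutoff_nm,
                            cfg.exciton_correction_nm, cfg.psf_fwhm_nm)
            classify_immobile(t)
        rows = []
        for t in trajs:
            for k in range(len(t)):
                rows.append(
                    (t.id, t.t_index[k] * cfg.exposure_s, t.xy_nm[k, 0],
                     t.xy_nm[k, 1], t.sigma_major_nm[k], t.length_nm,
                     t.immobile)
                )
        traj_df = pd.DataFrame(
            rows, columns=["traj_id", "t_s", "x_nm", "y_nm", "smaj_nm",
                           "length_nm", "immobile"],
        )
        traj_path = out / "trajectories.csv"
        _write_csv(traj_df, traj_path)
        record("track", trajectories=traj_path)
    except Exception as e:
        raise PipelineError("track", e) from e

    # --- diffusivity ------------------------------------------------------
    try:
        medium = ReferenceMedium(cfg.temperature_K, cfg.viscosity_Pa_s,
                                 cfg.probe_diameter_nm)
        estimates = relative_diffusivity(trajs, medium, cfg.msd_window_s,
                                         cfg.msd_fit_span_s)
        est_df = pd.DataFrame(
            [
                (e.traj_id, e.x_nm, e.y_nm, e.d_inst_nm2_s, e.d_ref_nm2_s,
                 e.ratio, e.length_imputed, e.floored)
                for e in estimates
            ],
            columns=["traj_id", "x_nm", "y_nm", "d_inst_nm2_s",
                     "d_ref_nm2_s", "ratio", "length_imputed", "floored"],
        )
        est_path = out / "diffusivity.csv"
        _write_csv(est_df, est_path)
        outputs = {"estimates": est_path}
        if len(est_df):
            pos = est_df[["x_nm", "y_nm"]].to_numpy()
            ratio_map = make_map(pos, est_df["ratio"].to_numpy(),
                                 cfg.map_pixel_nm, cfg.map_fwhm_nm,
                                 mode="mean_value")
            density = make_map(pos, pixel_size_nm=cfg.map_pixel_nm,
                               fwhm_nm=cfg.map_fwhm_nm, mode="density")
            rmap_path = out / "ratio_map.tif"
            dmap_path = out / "density_map.tif"
            tifffile.imwrite(rmap_path, ratio_map.data.astype(np.float32))
            tifffile.imwrite(dmap_path, density.data.astype(np.float32))
            outputs.update(ratio_map=rmap_path, density_map=dmap_path)
        record("diffusivity", **outputs)
    except Exception as e:
        raise PipelineError("diffusivity", e) from e

    # --- dimensions -------------------------------------------------------
    try:
        windows = []
        for t in trajs:
            if not t.immobile:
                windows.extend(confinement_windows(t, cfg.confinement_points))
        outputs = {}
        if windows:
            pos, widths = estimate_local_width(
                windows, cfg.confinement_quartile
            )
            wdf = pd.DataFrame(
                {"x_nm": pos[:, 0], "y_nm": pos[:, 1], "width_nm": widths}
            )
            w_path = out / "widths.csv"
            _write_csv(wdf, w_path)
            outputs["widths"] = w_path
            if len(widths):
                wmap = dimension_map(pos, widths, cfg.map_pixel_nm,
                                     cfg.map_fwhm_nm)
                wmap_path = out / "dimension_map.tif"
                tifffile.imwrite(wmap_path, wmap.data.astype(np.float32))
                outputs["dimension_map"] = wmap_path
        record("dimensions", **outputs)
    except Exception as e:
        raise PipelineError("dimensions", e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
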