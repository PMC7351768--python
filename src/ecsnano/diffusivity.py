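"""Instantaneous diffusivity and super-resolved map rendering.

For each trajectory the instantaneous mean squared displacement (MSD_inst)
is computed over a sliding 450 ms window and the instantaneous diffusion
coefficient D_inst is the initial slope of a straight-line fit to the
first 90 ms of lags, divided by 4 (2D tracking); the free intercept
absorbs static localization error.  D_inst is normalized by the free
diffusion coefficient of the same rod in a reference fluid of
cerebrospinal-fluid-like viscosity,

    D_ref = 3 k_B T ln(2 phi) / (8 pi eta_ref L),

with phi = L / d the aspect ratio of a rod of length L and diameter d.
The local relative diffusivity D_inst/D_ref is what the super-resolved
maps carry: each value (or localization, for density maps) is rendered as
a 2D Gaussian of 50 nm FWHM and unit amplitude on a 25 nm-pixel raster;
value maps use normalized convolution (value-weighted sum over weight
sum), so map values never overshoot the input range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import _FWHM_PER_SIGMA
from .tracking import Trajectory

__all__ = [
    "MsdCurve",
    "ReferenceMedium",
    "DiffusivityEstimate",
    "SuperResolvedMap",
    "BOLTZMANN_J_PER_K",
    "msd_instantaneous",
    "fit_d_inst",
    "d_reference",
    "relative_diffusivity",
    "make_map",
    "exploration_area",
]

BOLTZMANN_J_PER_K = 1.380649e-23  # exact (SI, 2019 redefinition)


@dataclass
class MsdCurve:
    """Windowed time-averaged MSD around one trajectory instant."""

    lags_s: np.ndarray
    msd_nm2: np.ndarray
    center_time_s: float
    center_xy_nm: np.ndarray
    points_per_lag: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_nm2 < 0):
            raise ValueError("MSD must be nonnegative")


@dataclass(frozen=True)
class ReferenceMedium:
    """Reference fluid and probe geometry for the rod diffusion formula."""

    temperature_K: float = 310.15
    viscosity_Pa_s: float = 0.70e-3  # ~ water at 37 C; CSF-like
    probe_diameter_nm: float = 1.0

    def __post_init__(self):
        if min(self.temperature_K, self.viscosity_Pa_s,
               self.probe_diameter_nm) <= 0:
            raise ValueError("medium parameters must be positive")


@dataclass
class DiffusivityEstimate:
    x_nm: float
    y_nm: float
    d_inst_nm2_s: float
    d_ref_nm2_s: float
    ratio: float
    traj_id: int
    length_imputed: bool = False
    floored: bool = False


def msd_instantaneous(
    traj: Trajectory, window_span_s: float = 0.450
) -> list[MsdCurve]:
    """Sliding-window time-averaged MSD curves along a trajectory.

    The window holds ``round(span/dt)`` samples (15 at 30 ms); within each
    window the MSD is averaged over all index pairs at each realized lag.
    Trajectories shorter than the window yield an empty list.
    """
    dt = traj.dt_s
    n_win = int(round(window_span_s / dt))
    if n_win < 4:
        raise ValueError("window span must cover at least 4 samples")
    n = len(traj)
    out = []
    for start in range(0, n - n_win + 1):
        idx = traj.t_index[start : start + n_win]
        xy = traj.xy_nm[start : start + n_win]
        sums: dict[int, list] = {}
        for i in range(n_win - 1):
            dlag = idx[i + 1 :] - idx[i]
            d2 = ((xy[i + 1 :] - xy[i]) ** 2).sum(axis=1)
            for lag, v in zip(dlag, d2):
                sums.setdefault(int(lag), []).append(v)
        lags = np.array(sorted(sums))
        msd = np.array([np.mean(sums[k]) for k in lags])
        npts = np.array([len(sums[k]) for k in lags])
        out.append(
            MsdCurve(
                lags_s=lags * dt,
                msd_nm2=msd,
                center_time_s=float(np.mean(idx) * dt),
                center_xy_nm=xy.mean(axis=0),
                points_per_lag=npts,
            )
        )
    return out


def fit_d_inst(
    msd: MsdCurve, fit_span_s: float = 0.090, free_intercept: bool = True
) -> tuple[float, bool]:
    """Initial-slope diffusion coefficient from one windowed MSD curve.

    Ordinary least squares on lags <= ``fit_span_s``; D = slope / 4.
    Negative slopes are floored at zero with a flag.  Returns
    (D_inst nm²/s, floored).
    """
    sel = msd.lags_s <= fit_span_s * 1.001
    if sel.sum() < 2:
        raise ValueError("need at least 2 lags within the fit span")
    x = msd.lags_s[sel]
    y = msd.msd_nm2[sel]
    if free_intercept:
        slope = np.polyfit(x, y, 1)[0]
    else:
        slope = float((x @ y) / (x @ x))
    if slope < 0:
        return 0.0, True
    return float(slope) / 4.0, False


def d_reference(length_nm: float, medium: ReferenceMedium | None = None
                ) -> float:
    """Free diffusion coefficient (nm²/s) of a rod in the reference fluid.

    D_ref = 3 k_B T ln(2 phi) / (8 pi eta L), phi = L / diameter.
    """
    if length_nm <= 0:
        raise ValueError("rod length must be positive")
    m = medium or ReferenceMedium()
    phi = length_nm / m.probe_diameter_nm
    if phi <= 1:
        raise ValueError("aspect ratio must exceed 1")
    L_m = length_nm * 1e-9
    d_m2_s = (
        3.0 * BOLTZMANN_J_PER_K * m.temperature_K * np.log(2.0 * phi)
    ) / (8.0 * np.pi * m.viscosity_Pa_s * L_m)
    return d_m2_s * 1e18  # m²/s -> nm²/s


def relative_diffusivity(
    trajectories: list[Trajectory],
    medium: ReferenceMedium | None = None,
    window_span_s: float = 0.450,
    fit_span_s: float = 0.090,
) -> list[DiffusivityEstimate]:
    """One D_inst/D_ref estimate per MSD window, at the window centroid.

    Immobile trajectories are excluded.  Trajectories with undefined
    probe length use the cohort median length (flagged); if no trajectory
    has a defined length, a 500 nm default is used, matching the probe
    population the method is designed around.
    """
    mobile = [t for t in trajectories if not t.immobile]
    defined = [t.length_nm for t in mobile if t.length_defined]
    cohort_L = float(np.median(defined)) if defined else 500.0
    out = []
    for traj in mobile:
        L = traj.length_nm if traj.length_defined else cohort_L
        imputed = not traj.length_defined
        if L <= 0:
            L, imputed = cohort_L if cohort_L > 0 else 500.0, True
        d_ref = d_reference(L, medium)
        for curve in msd_instantaneous(traj, window_span_s):
            try:
                d_inst, floored = fit_d_inst(curve, fit_span_s)
            except ValueError:
                continue
            out.append(
                DiffusivityEstimate(
                    x_nm=float(curve.center_xy_nm[0]),
                    y_nm=float(curve.center_xy_nm[1]),
                    d_inst_nm2_s=d_inst,
                    d_ref_nm2_s=d_ref,
                    ratio=d_inst / d_ref,
                    traj_id=traj.id,
                    length_imputed=imputed,
                    floored=floored,
                )
            )
    return out


@dataclass
class SuperResolvedMap:
    """Raster of density or locally averaged values at 25 nm pixels.

    ``data`` is NaN where a mean-value map has no support.  ``origin_nm``
    is the continuous coordinate of pixel (0, 0)'s centre.
    """

    data: np.ndarray
    weight: np.ndarray
    origin_nm: np.ndarray
    pixel_size_nm: float
    mode: str


def make_map(
    positions_nm: np.ndarray,
    values: np.ndarray | None = None,
    pixel_size_nm: float = 25.0,
    fwhm_nm: float = 50.0,
    mode: str = "density",
    support_eps: float = 1e-3,
) -> SuperResolvedMap:
    """Render points (and optional values) as unit-amplitude Gaussians.

    density: sum of unit-amplitude Gaussians, one per localization.
    mean_value: normalized convolution — sum(value_i g_i) / sum(g_i) where
    the total weight exceeds ``support_eps``, NaN elsewhere; map values
    are convex combinations of the inputs.
    """
    pts = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    if len(pts) == 0:
        raise ValueError("need at least one position")
    if mode not in ("density", "mean_value"):
        raise ValueError(f"unknown map mode {mode!r}")
    if mode == "mean_value":
        values = np.asarray(values, dtype=float)
        if values.shape[0] != len(pts):
            raise ValueError("one value per position required")
    sigma = fwhm_nm / _FWHM_PER_SIGMA
    pad = 3 * fwhm_nm
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    origin = np.floor(lo / pixel_size_nm) * pixel_size_nm
    nc = int(np.ceil((hi[0] - origin[0]) / pixel_size_nm)) + 1
    nr = int(np.ceil((hi[1] - origin[1]) / pixel_size_nm)) + 1
    weight = np.zeros((nr, nc))
    num = np.zeros((nr, nc))
    cut = int(np.ceil(4 * sigma / pixel_size_nm))
    for k, (x, y) in enumerate(pts):
        cc = (x - origin[0]) / pixel_size_nm
        rc = (y - origin[1]) / pixel_size_nm
        c0 = max(int(np.floor(cc)) - cut, 0)
        r0 = max(int(np.floor(rc)) - cut, 0)
        c1 = min(int(np.ceil(cc)) + cut + 1, nc)
        r1 = min(int(np.ceil(rc)) + cut + 1, nr)
        rows, cols = np.meshgrid(
            np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
        )
        g = np.exp(
            -0.5 * (((cols - cc) ** 2 + (rows - rc) ** 2)
                    * (pixel_size_nm / sigma) ** 2)
        )
        weight[r0:r1, c0:c1] += g
        if mode == "mean_value":
            num[r0:r1, c0:c1] += values[k] * g
    if mode == "density":
        return SuperResolvedMap(weight.copy(), weight, origin,
                                pixel_size_nm, mode)
    data = np.full_like(weight, np.nan)
    sup = weight > support_eps
    data[sup] = num[sup] / weight[sup]
    return SuperResolvedMap(data, weight, origin, pixel_size_nm, mode)


def exploration_area(
    density_map: SuperResolvedMap, amplitude_threshold: float = 0.5
) -> float:
    """Explored area (µm²): pixels of a density map above threshold."""
    if density_map.mode != "density":
        raise ValueError("exploration area requires a density map")
    n = int(np.count_nonzero(density_map.data >= amplitude_threshold))
    return n * density_map.pixel_size_nm**2 / 1e6
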