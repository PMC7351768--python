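"""Trajectory linking, probe-length estimation and mobility classification.

Drift-corrected localizations are linked into trajectories by greedy
nearest-neighbour assignment under a maximum-step cap, with a short memory
for missed detections.  The rod probe's length is estimated from the
fitted major-axis width in frames where the probe is effectively static
(inter-frame displacement below a cutoff, default 40 nm): the apparent
major-axis FWHM is deconvolved from the optical FWHM in quadrature and the
exciton diffusion length (~100 nm apparent elongation of the emission
profile) is subtracted.  Probes whose global MSD shows a plateau are
classified immobile and excluded from diffusivity analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import _FWHM_PER_SIGMA

__all__ = [
    "Trajectory",
    "link_trajectories",
    "estimate_length",
    "classify_immobile",
    "global_msd",
]


@dataclass
class Trajectory:
    """Time-ordered drift-corrected localizations of one probe."""

    id: int
    t_index: np.ndarray  # frame indices (strictly increasing)
    xy_nm: np.ndarray  # (n, 2)
    sigma_major_nm: np.ndarray
    dt_s: float = 0.030
    length_nm: float = np.nan  # nan = undefined, see length_defined
    length_defined: bool = False
    immobile: bool = False

    def __post_init__(self):
        self.t_index = np.asarray(self.t_index, dtype=int)
        self.xy_nm = np.asarray(self.xy_nm, dtype=float)
        self.sigma_major_nm = np.asarray(self.sigma_major_nm, dtype=float)
        if np.any(np.diff(self.t_index) <= 0):
            raise ValueError("time indices must be strictly increasing")

    def __len__(self):
        return len(self.t_index)

    @property
    def times_s(self) -> np.ndarray:
        return self.t_index * self.dt_s


def link_trajectories(
    localizations: pd.DataFrame,
    max_step_nm: float = 500.0,
    memory_frames: int = 3,
    min_length: int = 20,
    dt_s: float = 0.030,
) -> list[Trajectory]:
    """Greedy nearest-neighbour linking under a step cap.

    Candidate (track, detection) pairs are assigned in ascending order of
    distance (ties broken by lowest track id); each detection and each
    track is used at most once per frame.  Unmatched tracks survive up to
    ``memory_frames`` skipped frames.  Tracks shorter than ``min_length``
    are dropped.  The input row order is irrelevant (sorted internally).
    """
    df = localizations
    if "accepted" in df.columns:
        df = df[df["accepted"]]
    df = df.sort_values("t_index", kind="stable")
    active: list[dict] = []
    closed: list[dict] = []
    next_id = 0
    for t, grp in df.groupby("t_index", sort=True):
        t = int(t)
        pts = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        smaj = grp["smaj_nm"].to_numpy(dtype=float)
        # drop tracks that have been silent too long
        still = []
        for tr in active:
            if t - tr["t"][-1] > memory_frames + 1:
                closed.append(tr)
            else:
                still.append(tr)
        active = still
        assigned_det = set()
        assigned_trk = set()
        if active and len(pts):
            last = np.array([tr["xy"][-1] for tr in active])
            dist = np.hypot(
                last[:, 0:1] - pts[None, :, 0], last[:, 1:2] - pts[None, :, 1]
            )
            order = np.argsort(dist, axis=None, kind="stable")
            for flat in order:
                i, j = np.unravel_index(flat, dist.shape)
                if dist[i, j] > max_step_nm:
                    break
                if i in assigned_trk or j in assigned_det:
                    continue
                tr = active[i]
                tr["t"].append(t)
                tr["xy"].append(pts[j])
                tr["smaj"].append(smaj[j])
                assigned_trk.add(i)
                assigned_det.add(j)
        for j in range(len(pts)):
            if j not in assigned_det:
                active.append(
                    dict(id=next_id, t=[t], xy=[pts[j]], smaj=[smaj[j]])
                )
                next_id += 1
    closed.extend(active)
    out = []
    for tr in sorted(closed, key=lambda d: d["id"]):
        if len(tr["t"]) < min_length:
            continue
        out.append(
            Trajectory(
                id=tr["id"],
                t_index=np.array(tr["t"]),
                xy_nm=np.array(tr["xy"]),
                sigma_major_nm=np.array(tr["smaj"]),
                dt_s=dt_s,
            )
        )
    return out


def estimate_length(
    traj: Trajectory,
    displacement_cutoff_nm: float = 40.0,
    exciton_correction_nm: float = 100.0,
    psf_fwhm_nm: float = 400.0,
    min_quiet_intervals: int = 5,
) -> float:
    """Rod length from the major-axis width during quiet intervals.

    Frames whose displacement to the next frame is below the cutoff
    qualify; the apparent major-axis FWHM is deconvolved from the optical
    FWHM by quadrature subtraction and reduced by the exciton diffusion
    length, floored at zero.  With fewer than ``min_quiet_intervals``
    qualifying frames the length is undefined (NaN, flag unset) and the
    cohort median is substituted downstream.
    """
    disp = np.hypot(*np.diff(traj.xy_nm, axis=0).T)
    quiet = np.flatnonzero(disp < displacement_cutoff_nm)
    if len(quiet) < min_quiet_intervals:
        traj.length_nm = np.nan
        traj.length_defined = False
        return np.nan
    fwhm_app = _FWHM_PER_SIGMA * traj.sigma_major_nm[quiet]
    emission = np.sqrt(np.clip(fwhm_app**2 - psf_fwhm_nm**2, 0.0, None))
    L = max(float(np.median(emission)) - exciton_correction_nm, 0.0)
    traj.length_nm = L
    traj.length_defined = True
    return L


def global_msd(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over the whole trajectory (lags in s, MSD nm²).

    Uses consecutive-index lags; frames missing through gap memory
    contribute to whichever lags their index differences realize.
    """
    t = traj.t_index
    xy = traj.xy_nm
    n = len(t)
    span = t[-1] - t[0]
    sums: dict[int, list] = {}
    for i in range(n - 1):
        dlag = t[i + 1 :] - t[i]
        d2 = ((xy[i + 1 :] - xy[i]) ** 2).sum(axis=1)
        for lag, v in zip(dlag, d2):
            sums.setdefault(int(lag), []).append(v)
    lags = np.array(sorted(sums))
    msd = np.array([np.mean(sums[k]) for k in lags])
    return lags * traj.dt_s, msd


def classify_immobile(
    traj: Trajectory,
    slope_threshold: float = 0.2,
    plateau_ratio_threshold: float = 2.0,
) -> bool:
    """Plateau test on the global MSD.

    Immobile iff the log-log slope of the global MSD over lags in
    [4 dt, span/4] is below ``slope_threshold`` or the plateau ratio
    MSD(span/2) / MSD(4 dt) is below ``plateau_ratio_threshold``.
    """
    lags, msd = global_msd(traj)
    dt = traj.dt_s
    span = traj.times_s[-1] - traj.times_s[0]
    if span < 16 * dt:
        raise ValueError("trajectory too short for the global-MSD test")
    lo, hi = 4 * dt, span / 4
    sel = (lags >= lo * 0.999) & (lags <= hi * 1.001) & (msd > 0)
    immobile = False
    if sel.sum() >= 2:
        slope = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)[0]
        if slope < slope_threshold:
            immobile = True
    m_lo = _msd_at(lags, msd, 4 * dt)
    m_hi = _msd_at(lags, msd, span / 2)
    if m_lo > 0 and m_hi / m_lo < plateau_ratio_threshold:
        immobile = True
    if m_lo == 0 and m_hi == 0:
        immobile = True  # strictly stationary
    traj.immobile = immobile
    return immobile


def _msd_at(lags, msd, target):
    i = int(np.argmin(np.abs(lags - target)))
    return msd[i]
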