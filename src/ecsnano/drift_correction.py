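"""Redundant cross-correlation (RCC) drift estimation and removal.

Slow stage drift r_t is estimated from static background features: for
every ordered frame pair (t, u) the image cross-correlation peak measures
the relative shift Delta_{t,u} = r_u - r_t with sub-pixel accuracy
(separable three-point quadratic interpolation around the integer peak).
The T(T-1)/2 pairwise equations form an overdetermined linear system for
the T unknowns r_1..r_T (gauge fixed at r_1 = 0), solved in a least-squares
sense; equations whose residual exceeds a threshold (default 1 px) are
flagged as outliers and the solve is repeated until the equation set
stabilizes.  The solution is finally smoothed with a moving average
weighted by each frame's count of non-outlier equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DriftEquation",
    "DriftSeries",
    "DisconnectedFramesError",
    "pairwise_shifts",
    "solve_drift",
    "apply_drift",
]


@dataclass
class DriftEquation:
    """Measured shift between one frame pair: Delta = r_u - r_t (px)."""

    t: int  # 1-based, t < u
    u: int
    dx_px: float
    dy_px: float
    outlier: bool = False

    def __post_init__(self):
        if not 1 <= self.t < self.u:
            raise ValueError("require 1 <= t < u")


@dataclass
class DriftSeries:
    """Per-frame drift estimate, gauge r_1 = (0, 0)."""

    r_px: np.ndarray  # (T, 2) columns (x, y)
    n_equations: np.ndarray  # per-frame non-outlier equation counts
    smoothing_window: int


class DisconnectedFramesError(RuntimeError):
    def __init__(self, components):
        self.components = components
        super().__init__(
            "non-outlier equation graph is disconnected; frame groups: "
            + "; ".join(str(sorted(c)) for c in components)
        )


def _subpixel_peak(cc: np.ndarray) -> tuple[float, float]:
    """Argmax of a correlation map with per-axis 3-point parabola."""
    nr, nc = cc.shape
    idx = np.unravel_index(np.argmax(cc), cc.shape)
    out = []
    for axis, n in ((0, nr), (1, nc)):
        i = idx[axis]
        im = list(idx)
        ip = list(idx)
        im[axis] = (i - 1) % n
        ip[axis] = (i + 1) % n
        c0, cm, cp = cc[idx], cc[tuple(im)], cc[tuple(ip)]
        denom = cm - 2 * c0 + cp
        delta = 0.5 * (cm - cp) / denom if denom != 0 else 0.0
        # wrap to signed lag
        lag = i if i <= n // 2 else i - n
        out.append(lag + delta)
    return out[1], out[0]  # (dx, dy) = (col lag, row lag)


def pairwise_shifts(region_series: np.ndarray) -> list[DriftEquation]:
    """Cross-correlate every frame pair of a (T, H, W) region series.

    Returns exactly T(T-1)/2 equations.  Raises on a flat (zero-variance)
    region, where correlation carries no shift information.
    """
    frames = np.asarray(region_series, dtype=float)
    T = len(frames)
    if T < 2:
        raise ValueError("need at least two frames")
    if np.any(frames.std(axis=(1, 2)) == 0):
        raise ValueError("flat region: zero variance frame")
    f = frames - frames.mean(axis=(1, 2), keepdims=True)
    F = np.fft.rfft2(f)
    eqs = []
    for t in range(T - 1):
        for u in range(t + 1, T):
            cc = np.fft.irfft2(np.conj(F[t]) * F[u], s=f.shape[1:])
            dx, dy = _subpixel_peak(cc)
            eqs.append(DriftEquation(t + 1, u + 1, dx, dy))
    return eqs


def solve_drift(
    equations: list[DriftEquation],
    residual_threshold_px: float = 1.0,
    smoothing_window: int = 5,
    max_iterations: int = 100,
) -> DriftSeries:
    """Iteratively re-weighted least squares over the pairwise equations.

    Outliers (2D residual above the threshold) are removed cumulatively —
    the non-outlier set is non-increasing, so iteration terminates — until
    the set stabilizes or the iteration cap is reached.  The gauge is fixed
    by r_1 = 0.  The result is smoothed with a moving average weighted by
    each frame's non-outlier equation count, re-pinned at r_1 = 0.
    """
    if not equations:
        raise ValueError("no equations")
    T = max(e.u for e in equations)
    if T < 2:
        raise ValueError("equations must span at least 2 frames")
    eqs = list(equations)
    active = np.array([not e.outlier for e in eqs])

    r = np.zeros((T, 2))
    for _ in range(max_iterations):
        _check_connected(eqs, active, T)
        idx = np.flatnonzero(active)
        # unknowns r_2..r_T (frame 1 pinned at zero)
        A = np.zeros((len(idx), T - 1))
        bx = np.empty(len(idx))
        by = np.empty(len(idx))
        for row, k in enumerate(idx):
            e = eqs[k]
            if e.u >= 2:
                A[row, e.u - 2] = 1.0
            if e.t >= 2:
                A[row, e.t - 2] = -1.0
            bx[row] = e.dx_px
            by[row] = e.dy_px
        sol_x, *_ = np.linalg.lstsq(A, bx, rcond=None)
        sol_y, *_ = np.linalg.lstsq(A, by, rcond=None)
        r = np.column_stack(
            [np.concatenate([[0.0], sol_x]), np.concatenate([[0.0], sol_y])]
        )
        resid = np.hypot(A @ sol_x - bx, A @ sol_y - by)
        new_out = idx[resid > residual_threshold_px]
        if len(new_out) == 0:
            break
        active[new_out] = False
    for k, e in enumerate(eqs):
        e.outlier = not active[k]

    counts = np.zeros(T, dtype=int)
    for e in eqs:
        if not e.outlier:
            counts[e.t - 1] += 1
            counts[e.u - 1] += 1

    smoothed = _weighted_moving_average(r, counts, smoothing_window)
    smoothed -= smoothed[0]  # re-pin the gauge
    return DriftSeries(smoothed, counts, smoothing_window)


def _check_connected(eqs, active, T):
    g = nx.Graph()
    g.add_nodes_from(range(1, T + 1))
    for k, e in enumerate(eqs):
        if active[k]:
            g.add_edge(e.t, e.u)
    if not nx.is_connected(g):
        raise DisconnectedFramesError(list(nx.connected_components(g)))


def _weighted_moving_average(r, weights, window):
    if window <= 1:
        return r.copy()
    T = len(r)
    half = window // 2
    out = np.empty_like(r)
    w = np.asarray(weights, dtype=float)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        ww = w[lo:hi]
        if ww.sum() == 0:
            ww = np.ones_like(ww)
        out[t] = (r[lo:hi] * ww[:, None]).sum(axis=0) / ww.sum()
    return out


def apply_drift(
    localizations: pd.DataFrame,
    drift: DriftSeries,
    pixel_size_nm: float,
    t_offset: int = 0,
) -> pd.DataFrame:
    """Subtract the per-frame drift from localization positions.

    ``t_index`` values (plus ``t_offset``) index into the drift series
    (0-based).  Raises if any index falls outside the series.
    """
    out = localizations.copy()
    t = out["t_index"].to_numpy(dtype=int) + t_offset
    if t.min() < 0 or t.max() >= len(drift.r_px):
        raise IndexError("localization time index outside drift range")
    out["x_nm"] = out["x_nm"] - drift.r_px[t, 0] * pixel_size_nm
    out["y_nm"] = out["y_nm"] - drift.r_px[t, 1] * pixel_size_nm
    return out
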