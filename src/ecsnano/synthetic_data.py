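"""Ground-truth scene, movie, mask and network generators.

Everything downstream of this module (localization, drift correction,
tracking, diffusivity/dimension mapping, EM morphometry, network
morphometry) is validated against data produced here, where the truth is
known by construction:

* channels-and-pools extracellular-space geometries — wide circular pools
  (widths ~100-300 nm) connected by narrow channels (<100 nm);
* reflected Brownian motion of rod-shaped probes with a locally varying
  diffusion coefficient;
* near-infrared movies of a single elongated emitter rendered as an
  asymmetric 2D Gaussian on an EM-CCD camera (Poisson shot noise, Gaussian
  read noise, gain), with injectable global drift;
* binary EM-like masks with a prescribed foreground (ECS) fraction and
  known width field;
* rasters of sets with known box-counting dimension.

Coordinate convention shared by all modules: continuous positions are in
nm with the origin at the field corner; raster index (row, col) maps to
continuous coordinates so that (0, 0) is the centre of the top-left pixel,
i.e. x_nm = col * pixel_size, y_nm = row * pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneGeometry",
    "TruthTrack",
    "CameraModel",
    "MaskTruth",
    "GeometryError",
    "generate_geometry",
    "simulate_walker",
    "render_movie",
    "generate_ecs_mask",
    "generate_reference_fractal",
]

# Expected range (peak-to-peak) of n iid standard-normal samples, n=6.
# Used by the renderer's documentation only; kept here for reference.
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class GeometryError(RuntimeError):
    """Raised when rejection sampling cannot place a requested geometry."""


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneGeometry:
    """Channels-and-pools planar geometry.

    pools: array (n, 3) of (cx_nm, cy_nm, radius_nm)
    channels: array (m, 5) of (x1, y1, x2, y2, width_nm); each endpoint
        lies inside a pool, so the union is connected by construction.
    domain_size: (width_nm, height_nm) bounding box.
    resolution_nm: raster resolution used for inside tests / reflection.
    """

    pools: np.ndarray
    channels: np.ndarray
    domain_size: tuple[float, float]
    resolution_nm: float = 5.0

    def __post_init__(self):
        pools = np.atleast_2d(np.asarray(self.pools, dtype=float))
        if pools.size == 0:
            pools = pools.reshape(0, 3)
        channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if channels.size == 0:
            channels = channels.reshape(0, 5)
        object.__setattr__(self, "pools", pools)
        object.__setattr__(self, "channels", channels)
        if np.any(pools[:, 2] <= 0) or np.any(channels[:, 4] <= 0):
            raise ValueError("all pool radii and channel widths must be > 0")

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for continuous points (nm).

        A point is inside if it lies in any pool disc or within half a
        channel width of a channel's centre segment.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.zeros(len(pts), dtype=bool)
        for cx, cy, r in self.pools:
            d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
            ok |= d2 <= r * r
        for x1, y1, x2, y2, w in self.channels:
            ok |= _segment_distance(pts, (x1, y1), (x2, y2)) <= w / 2.0
        if np.isscalar(points[0]) and np.ndim(points) == 1:
            return ok[0]
        return ok

    def channel_axis(self, point: np.ndarray) -> float | None:
        """Orientation (rad) of the channel containing ``point``, if any
        and if the point is not also inside a pool."""
        p = np.asarray(point, dtype=float)[None, :]
        for cx, cy, r in self.pools:
            if (p[0, 0] - cx) ** 2 + (p[0, 1] - cy) ** 2 <= r * r:
                return None
        for x1, y1, x2, y2, w in self.channels:
            if _segment_distance(p, (x1, y1), (x2, y2))[0] <= w / 2.0:
                return float(np.arctan2(y2 - y1, x2 - x1) % np.pi)
        return None

    def rasterize(self, resolution_nm: float | None = None) -> np.ndarray:
        """Binary raster of the inside region (row = y, col = x)."""
        res = resolution_nm or self.resolution_nm
        w, h = self.domain_size
        nc = max(int(np.ceil(w / res)) + 1, 2)
        nr = max(int(np.ceil(h / res)) + 1, 2)
        cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
        pts = np.column_stack([cols.ravel() * res, rows.ravel() * res])
        return self.inside(pts).reshape(nr, nc)


def _segment_distance(pts: np.ndarray, a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
    t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])


def generate_geometry(
    n_pools: int,
    pool_radius_range_nm: tuple[float, float] = (50.0, 150.0),
    channel_width_range_nm: tuple[float, float] = (30.0, 90.0),
    seed: int = 0,
    channel_length_range_nm: tuple[float, float] = (200.0, 600.0),
    max_attempts: int = 10_000,
) -> SceneGeometry:
    """Place ``n_pools`` pools and chain-connect consecutive pools with
    channels, guaranteeing a connected geometry.

    Pool widths (diameters) default to 100-300 nm and channel widths to
    <100 nm, the regime reported for brain extracellular space.
    """
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    if min(pool_radius_range_nm) <= 0 or min(channel_width_range_nm) <= 0:
        raise ValueError("ranges must be positive")
    rng = np.random.default_rng(seed)
    r_lo, r_hi = pool_radius_range_nm
    pools = []
    channels = []
    x, y = r_hi * 2.0, r_hi * 2.0
    pools.append((x, y, rng.uniform(r_lo, r_hi)))
    for _ in range(1, n_pools):
        placed = False
        for _attempt in range(max_attempts):
            r = rng.uniform(r_lo, r_hi)
            gap = rng.uniform(*channel_length_range_nm)
            ang = rng.uniform(0, 2 * np.pi)
            px, py, pr = pools[-1]
            cx = px + np.cos(ang) * (pr + gap + r)
            cy = py + np.sin(ang) * (pr + gap + r)
            # avoid overlap with earlier pools so channel widths stay true
            if all(
                np.hypot(cx - qx, cy - qy) > r + qr + 20.0
                for qx, qy, qr in pools
            ):
                w = rng.uniform(*channel_width_range_nm)
                pools.append((cx, cy, r))
                channels.append((px, py, cx, cy, w))
                placed = True
                break
        if not placed:
            raise GeometryError(
                f"could not place pool after {max_attempts} attempts"
            )
    arr = np.asarray(pools)
    margin = r_hi * 2.0
    # shift everything into the positive quadrant with a margin
    x0 = arr[:, 0].min() - arr[:, 2].max() - margin
    y0 = arr[:, 1].min() - arr[:, 2].max() - margin
    arr[:, 0] -= x0
    arr[:, 1] -= y0
    ch = np.asarray(channels, dtype=float).reshape(-1, 5)
    if len(ch):
        ch[:, [0, 2]] -= x0
        ch[:, [1, 3]] -= y0
    width = float(arr[:, 0].max() + arr[:, 2].max() + margin)
    height = float(arr[:, 1].max() + arr[:, 2].max() + margin)
    return SceneGeometry(arr, ch, (width, height))


# ---------------------------------------------------------------------------
# Confined Brownian walker
# ---------------------------------------------------------------------------


@dataclass
class TruthTrack:
    """Ground-truth trajectory of one probe.

    positions: (n, 2) nm; dt_s: constant sampling interval;
    d_true: (n,) local true diffusion coefficient nm²/s at each position;
    probe_length_nm: rod length; orientations: (n,) rad in [0, pi).
    """

    positions: np.ndarray
    dt_s: float
    d_true: np.ndarray
    probe_length_nm: float
    orientations: np.ndarray


def simulate_walker(
    geom: SceneGeometry | None,
    D,
    n_steps: int,
    dt: float,
    seed: int = 0,
    start_nm: np.ndarray | None = None,
    probe_length_nm: float = 500.0,
    rot_diffusion_rad2_s: float = 1.0,
    max_reflections: int = 8,
) -> TruthTrack:
    """Reflected Brownian motion with locally varying diffusivity.

    ``D`` is a scalar (nm²/s) or a callable mapping an (n, 2) position
    array to per-point diffusivities.  Per-axis increments are drawn
    Normal(0, 2·D_local·dt) and reflected specularly against the
    geometry boundary (normal estimated from the signed distance field of
    the rasterized geometry).  A step still outside after
    ``max_reflections`` is rejected (the walker stays put), which
    preserves the uniform equilibrium density.

    Probe orientation follows the channel axis inside channels and
    diffuses rotationally inside pools — a declared stand-in model, since
    the rotational behaviour of rod probes in tissue is not characterised.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d_fun = D if callable(D) else (lambda p, _d=float(D): np.full(len(p), _d))
    rng = np.random.default_rng(seed)

    if geom is None and not callable(D):
        # unconfined, uniform D: closed-form vectorized path
        if D < 0:
            raise ValueError("D must be > 0 everywhere reachable")
        start = (np.zeros(2) if start_nm is None
                 else np.asarray(start_nm, dtype=float))
        steps = rng.normal(0.0, np.sqrt(2.0 * float(D) * dt), (n_steps, 2))
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        ori0 = rng.uniform(0, np.pi)
        dori = rng.normal(0.0, np.sqrt(2.0 * rot_diffusion_rad2_s * dt),
                          n_steps)
        ori = (ori0 + np.concatenate([[0.0], np.cumsum(dori)])) % np.pi
        return TruthTrack(pos, float(dt), np.full(n_steps + 1, float(D)),
                          float(probe_length_nm), ori)

    sdf = _SignedDistance(geom) if geom is not None else None
    if start_nm is None:
        if geom is not None:
            start_nm = geom.pools[0, :2].copy()
        else:
            start_nm = np.zeros(2)
    start_nm = np.asarray(start_nm, dtype=float)
    if geom is not None and not geom.inside(start_nm[None, :])[0]:
        raise ValueError("start point outside geometry")

    pos = np.empty((n_steps + 1, 2))
    ori = np.empty(n_steps + 1)
    pos[0] = start_nm
    ori[0] = rng.uniform(0, np.pi)
    d_here = float(d_fun(pos[:1])[0])
    dvals = np.empty(n_steps + 1)
    dvals[0] = d_here
    for i in range(n_steps):
        p = pos[i]
        d_here = float(d_fun(p[None, :])[0])
        if d_here < 0:
            raise ValueError("D must be > 0 everywhere reachable")
        step = rng.normal(0.0, np.sqrt(2.0 * d_here * dt), 2)
        q = p + step
        if geom is not None and not geom.inside(q[None, :])[0]:
            q = _reflect(p, q, geom, sdf, max_reflections)
        pos[i + 1] = q
        dvals[i + 1] = float(d_fun(q[None, :])[0])
        axis = geom.channel_axis(q) if geom is not None else None
        if axis is not None:
            ori[i + 1] = axis
        else:
            ori[i + 1] = (
                ori[i] + rng.normal(0.0, np.sqrt(2.0 * rot_diffusion_rad2_s * dt))
            ) % np.pi
    return TruthTrack(pos, float(dt), dvals, float(probe_length_nm), ori)


class _SignedDistance:
    """Bilinear-interpolated signed distance to the geometry boundary
    (positive inside), built from the rasterized inside mask."""

    def __init__(self, geom: SceneGeometry):
        self.res = geom.resolution_nm
        mask = geom.rasterize()
        din = ndimage.distance_transform_edt(mask)
        dout = ndimage.distance_transform_edt(~mask)
        self.phi = (din - dout) * self.res

    def __call__(self, p: np.ndarray) -> float:
        r = p[1] / self.res
        c = p[0] / self.res
        nr, nc = self.phi.shape
        r = min(max(r, 0.0), nr - 1.001)
        c = min(max(c, 0.0), nc - 1.001)
        r0, c0 = int(r), int(c)
        fr, fc = r - r0, c - c0
        z = self.phi
        return float(
            z[r0, c0] * (1 - fr) * (1 - fc)
            + z[r0 + 1, c0] * fr * (1 - fc)
            + z[r0, c0 + 1] * (1 - fr) * fc
            + z[r0 + 1, c0 + 1] * fr * fc
        )

    def normal(self, p: np.ndarray) -> np.ndarray:
        h = self.res * 0.5
        gx = self(p + [h, 0]) - self(p - [h, 0])
        gy = self(p + [0, h]) - self(p - [0, h])
        n = np.array([gx, gy])
        nn = np.hypot(*n)
        return n / nn if nn > 0 else np.array([1.0, 0.0])


def _reflect(p, q, geom, sdf, max_reflections):
    """Specular reflection of the sub-step p->q against the boundary,
    re-applied until inside (bounded); rejection fallback keeps p."""
    for _ in range(max_reflections):
        # bisect for the boundary crossing along p -> q
        lo, hi = 0.0, 1.0
        for _b in range(24):
            mid = 0.5 * (lo + hi)
            if geom.inside((p + mid * (q - p))[None, :])[0]:
                lo = mid
            else:
                hi = mid
        hit = p + lo * (q - p)
        n = sdf.normal(hit)
        rem = q - hit
        q = hit + rem - 2.0 * float(rem @ n) * n
        # nudge the pivot just inside to avoid re-hitting the same spot
        p = hit + 1e-6 * n
        if geom.inside(q[None, :])[0]:
            return q
    return p  # reject the move


# ---------------------------------------------------------------------------
# Camera / movie rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """EM-CCD forward model (expected photons -> counts)."""

    pixel_size_nm: float = 100.0
    exposure_s: float = 0.030
    amplitude: float = 200.0  # peak expected photons of the emitter
    background: float = 10.0  # expected photons per pixel
    gain: float = 1.0
    read_noise_sd: float = 1.0

    def __post_init__(self):
        if self.pixel_size_nm <= 0 or self.exposure_s <= 0:
            raise ValueError("pixel size and exposure must be > 0")


def asymmetric_gaussian(shape, x0_px, y0_px, sigma_major_px, sigma_minor_px,
                        theta, amplitude, background=0.0):
    """Rotated asymmetric 2D Gaussian on a pixel grid (unit = peak amp).

    theta is the major-axis orientation measured from the +x (col) axis.
    """
    rows, cols = np.indices(shape)
    dx = cols - x0_px
    dy = rows - y0_px
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return background + amplitude * np.exp(
        -0.5 * (u / sigma_major_px) ** 2 - 0.5 * (v / sigma_minor_px) ** 2
    )


def render_movie(
    track: TruthTrack,
    cam: CameraModel,
    drift_px: np.ndarray,
    seed: int = 0,
    fov_px: tuple[int, int] = (64, 64),
    psf_fwhm_nm: float = 400.0,
    exciton_length_nm: float = 100.0,
    noise: bool = True,
    background_spots: int = 0,
    background_spot_amplitude: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 16-bit movie of the probe plus a ground-truth table.

    The emitter is an asymmetric Gaussian: minor-axis FWHM equals the
    optical PSF FWHM; major-axis FWHM is the quadrature sum of the PSF and
    the probe's apparent emission extent (rod length + exciton diffusion
    length ~100 nm).  Noise order: Poisson on expected photons, additive
    Gaussian read noise, then gain.

    ``background_spots`` adds that many static point features (symmetric
    Gaussians at fixed positions, moving only with the injected drift) —
    the stationary tissue background that drift correction tracks.
    """
    drift_px = np.atleast_2d(np.asarray(drift_px, dtype=float))
    n_frames = len(track.positions)
    if len(drift_px) != n_frames:
        raise ValueError("drift length must equal frame count")
    rng = np.random.default_rng(seed)
    px = cam.pixel_size_nm
    sig_minor = (psf_fwhm_nm / _FWHM_PER_SIGMA) / px
    app_major = np.sqrt(
        psf_fwhm_nm**2 + (track.probe_length_nm + exciton_length_nm) ** 2
    )
    sig_major = (app_major / _FWHM_PER_SIGMA) / px
    nr, nc = fov_px
    spot_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB6]))
    spots = spot_rng.uniform([2, 2], [nc - 3, nr - 3],
                             size=(background_spots, 2))
    spot_amp = (background_spot_amplitude
                if background_spot_amplitude is not None
                else cam.amplitude * 0.5)
    sig_spot = (psf_fwhm_nm / _FWHM_PER_SIGMA) / px
    movie = np.empty((n_frames, nr, nc), dtype=np.uint16)
    rows = []
    for t in range(n_frames):
        x_px = track.positions[t, 0] / px + drift_px[t, 0]
        y_px = track.positions[t, 1] / px + drift_px[t, 1]
        visible = (0 <= x_px < nc) and (0 <= y_px < nr)
        expected = np.full((nr, nc), cam.background, dtype=float)
        for sx, sy in spots:
            expected += asymmetric_gaussian(
                (nr, nc), sx + drift_px[t, 0], sy + drift_px[t, 1],
                sig_spot, sig_spot, 0.0, spot_amp,
            )
        if visible:
            expected += asymmetric_gaussian(
                (nr, nc), x_px, y_px, sig_major, sig_minor,
                track.orientations[t], cam.amplitude,
            )
        if noise:
            img = rng.poisson(expected).astype(float)
            img += rng.normal(0.0, cam.read_noise_sd, img.shape)
            img *= cam.gain
        else:
            img = expected * cam.gain
        movie[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        rows.append(
            dict(
                frame=t,
                x_nm=track.positions[t, 0],
                y_nm=track.positions[t, 1],
                D_true=track.d_true[t],
                length_nm=track.probe_length_nm,
                drift_x_px=drift_px[t, 0],
                drift_y_px=drift_px[t, 1],
                visible=visible,
            )
        )
    return movie, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EM-like masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskTruth:
    """Ground truth attached to a generated binary mask."""

    volume_fraction: float
    width_field_nm: np.ndarray  # nominal structure width per foreground px
    pixel_size_nm: float


def generate_ecs_mask(
    target_volume_fraction: float,
    width_spec: dict | None = None,
    pixel_size_nm: float = 1.42,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    tolerance: float = 0.005,
) -> tuple[np.ndarray, MaskTruth]:
    """Binary ECS-like mask with a prescribed foreground fraction.

    Modes (``width_spec['mode']``):

    * ``'voronoi'`` (default): cell-packing mask where the foreground is a
      boundary gap of uniform nominal width between Voronoi cells — the
      gap width (px) is bisected until the achieved fraction is within
      ``tolerance`` (0.5 percentage points) of the target.
    * ``'pools'``: rasterized channels-and-pools geometry; all structure
      widths are scaled globally by bisection to hit the target fraction.
    """
    if not 0.0 < target_volume_fraction < 1.0:
        raise ValueError("target fraction must be in (0, 1)")
    spec = dict(width_spec or {})
    mode = spec.get("mode", "voronoi")
    rng = np.random.default_rng(seed)

    if mode == "voronoi":
        n_sites = spec.get("n_sites", max(4, int(shape[0] * shape[1] / 1800)))
        sites = rng.uniform(
            [0, 0], [shape[0] - 1, shape[1] - 1], size=(n_sites, 2)
        )
        rows, cols = np.indices(shape)
        pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        d = np.sqrt(
            ((pts[:, None, :] - sites[None, :, :]) ** 2).sum(-1)
        )
        d.sort(axis=1)
        margin = d[:, 1] - d[:, 0]  # gap half... == 2*distance to midline

        def build(w_px):
            return (margin < w_px).reshape(shape)

        w = _bisect_fraction(build, target_volume_fraction, tolerance,
                             lo=0.0, hi=float(margin.max()))
        mask = build(w)
        width_field = np.where(mask, w * pixel_size_nm, 0.0)
    elif mode == "pools":
        geom = generate_geometry(
            spec.get("n_pools", 4),
            spec.get("pool_radius_range_nm", (80.0, 150.0)),
            spec.get("channel_width_range_nm", (30.0, 90.0)),
            seed=seed,
        )
        scale_nm = spec.get(
            "pixel_size_nm_raster",
            max(geom.domain_size) / max(shape),
        )

        def build(s):
            g = SceneGeometry(
                np.column_stack([geom.pools[:, :2], geom.pools[:, 2] * s]),
                np.column_stack([geom.channels[:, :4], geom.channels[:, 4] * s])
                if len(geom.channels)
                else geom.channels,
                geom.domain_size,
                resolution_nm=scale_nm,
            )
            m = g.rasterize()[: shape[0], : shape[1]]
            out = np.zeros(shape, bool)
            out[: m.shape[0], : m.shape[1]] = m
            return out

        s = _bisect_fraction(build, target_volume_fraction, tolerance,
                             lo=0.05, hi=4.0)
        mask = build(s)
        # nominal width: paint pool diameters then channel widths (scaled)
        width_field = np.zeros(shape)
        rowg, colg = np.indices(shape)
        pnm = np.column_stack([colg.ravel() * scale_nm,
                               rowg.ravel() * scale_nm])
        for cx, cy, r in geom.pools:
            sel = (pnm[:, 0] - cx) ** 2 + (pnm[:, 1] - cy) ** 2 <= (r * s) ** 2
            width_field.ravel()[sel] = 2 * r * s
        for x1, y1, x2, y2, w0 in geom.channels:
            sel = (
                _segment_distance(pnm, (x1, y1), (x2, y2)) <= w0 * s / 2.0
            ) & (width_field.ravel() == 0)
            width_field.ravel()[sel] = w0 * s
        width_field[~mask] = 0.0
        # re-express truth in the requested pixel size for bookkeeping
        width_field = width_field
    else:
        raise ValueError(f"unknown mask mode {mode!r}")

    achieved = float(mask.mean())
    if abs(achieved - target_volume_fraction) > tolerance:
        raise GeometryError(
            f"could not reach fraction {target_volume_fraction} "
            f"(achieved {achieved:.4f})"
        )
    return mask, MaskTruth(achieved, width_field, pixel_size_nm)


def _bisect_fraction(build, target, tol, lo, hi, max_iter=60):
    f_hi = build(hi).mean()
    if f_hi < target - tol:
        raise GeometryError("target fraction unachievable for this spec")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = build(mid).mean()
        if abs(f - target) <= tol * 0.8:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Reference fractals
# ---------------------------------------------------------------------------


def generate_reference_fractal(kind: str, levels: int = 6) -> np.ndarray:
    """Deterministic rasters with known box-counting dimension.

    line -> 1.0; filled_square -> 2.0; sierpinski (triangle) -> log3/log2.
    """
    n = 2**levels
    if kind == "line":
        img = np.zeros((n, n), dtype=bool)
        img[n // 2, :] = True
        return img
    if kind == "filled_square":
        return np.ones((n, n), dtype=bool)
    if kind == "sierpinski":
        if levels < 3:
            raise ValueError("sierpinski needs levels >= 3")
        i, j = np.indices((n, n))
        return (i & j) == 0
    raise ValueError(f"unknown fractal kind {kind!r}")
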