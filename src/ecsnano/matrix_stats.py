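"""Matrix-network morphometry, stereology arithmetic and study statistics.

Covers the image statistics used for extracellular-matrix (hyaluronan)
staining — automatically thresholded area fraction with optional ROI mask
and background reference, box-counting fractal dimension of the binarized
network, skeleton cable lengths — plus the optical-fractionator stereology
estimate, the two-sample Kolmogorov–Smirnov test on cumulative
distributions, and frequency/cumulative distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce
from skimage.morphology import skeletonize

from .em_morphometry import compartment_lengths

__all__ = [
    "NetworkMetrics",
    "FractionatorParams",
    "area_fraction",
    "box_counting_dimension",
    "skeleton_length_distribution",
    "fractionator_estimate",
    "ks_two_sample",
    "summarize_distribution",
    "network_metrics",
]


@dataclass
class NetworkMetrics:
    area_fraction_percent: float
    box_counting_dimension: float
    skeleton_lengths_um: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.area_fraction_percent <= 100.0:
            raise ValueError("area fraction must be a percentage")


@dataclass(frozen=True)
class FractionatorParams:
    """Optical fractionator inputs: N = sum_Q / ssf / asf * t / h."""

    sum_q: float  # objects counted
    ssf: float  # section sampling fraction
    asf: float  # area sampling fraction
    t_um: float  # actual section thickness
    h_um: float  # dissector height

    def __post_init__(self):
        if min(self.sum_q, self.ssf, self.asf, self.t_um, self.h_um) <= 0:
            raise ValueError("all fractionator parameters must be positive")
        if not (self.ssf <= 1 and self.asf <= 1):
            raise ValueError("sampling fractions must lie in (0, 1]")
        if self.h_um > self.t_um:
            raise ValueError("dissector height cannot exceed thickness")


def area_fraction(
    image: np.ndarray,
    threshold_method: str = "otsu",
    roi: np.ndarray | None = None,
    background_reference: float | None = None,
) -> float:
    """% of (ROI) pixels above an automatic threshold.

    ``background_reference`` (e.g. the mean grey value of an unstained
    contralateral region) is subtracted first, clipping at zero.  A
    constant image yields 100% if the constant is positive, else 0%.
    """
    img = np.asarray(image, dtype=float)
    if background_reference is not None:
        img = np.clip(img - background_reference, 0.0, None)
    if roi is not None:
        roi = np.asarray(roi, bool)
        if not roi.any():
            raise ValueError("empty ROI")
        vals = img[roi]
    else:
        vals = img.ravel()
    if vals.max() == vals.min():
        return 100.0 if vals.max() > 0 else 0.0
    if threshold_method == "otsu":
        thr = threshold_otsu(vals)
    elif threshold_method == "mean":
        thr = vals.mean()
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    return 100.0 * float(np.count_nonzero(vals > thr)) / vals.size


def box_counting_dimension(
    image: np.ndarray, box_sizes: np.ndarray | None = None
) -> float:
    """Box-counting dimension D_b of a binary image.

    Box sizes default to the powers of two from 2 px up to a quarter of
    the smaller image side, on a single grid origin (top-left corner);
    D_b is the least-squares slope of log N(s) against log(1/s).
    """
    img = np.asarray(image).astype(bool)
    if not img.any():
        raise ValueError("empty foreground")
    if box_sizes is None:
        top = min(img.shape) // 4
        box_sizes = []
        s = 2
        while s <= top:
            box_sizes.append(s)
            s *= 2
    box_sizes = np.asarray(box_sizes, dtype=int)
    if len(box_sizes) < 4:
        raise ValueError("need at least 4 box sizes")
    counts = []
    for s in box_sizes:
        occupied = block_reduce(img, (s, s), np.max)
        counts.append(int(occupied.sum()))
    counts = np.asarray(counts, dtype=float)
    if np.all(counts == 1):
        raise ValueError("foreground fits in one box at all sizes")
    slope = np.polyfit(np.log(1.0 / box_sizes), np.log(counts), 1)[0]
    return float(slope)


def skeleton_length_distribution(
    image: np.ndarray,
    pixel_size_nm: float,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Cable lengths (µm): longest shortest path per skeleton component.

    The binary image is skeletonized and each 8-connected component's
    graph diameter measured (orthogonal steps 1 px, diagonal sqrt(2) px).
    An optional ROI restricts the analysis before skeletonization.
    """
    img = np.asarray(image).astype(bool)
    if roi is not None:
        img = img & np.asarray(roi, bool)
    skel = skeletonize(img)
    return compartment_lengths(skel, pixel_size_nm=pixel_size_nm)


def fractionator_estimate(p: FractionatorParams) -> tuple[float, int]:
    """Optical fractionator cell-count estimate.

    Returns (raw float, nearest-integer report value) of
    N = sum_Q x 1/ssf x 1/asf x t/h.
    """
    n = p.sum_q / p.ssf / p.asf * (p.t_um / p.h_um)
    return float(n), int(round(n))


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on cumulative distributions.

    D = sup |ECDF_a - ECDF_b|; the p-value is exact for small samples
    (n*m <= 10000) and asymptotic for large ones.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    method = "exact" if len(a) * len(b) <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def summarize_distribution(
    values, kind: str = "frequency", bins: int = 10
) -> dict:
    """Relative frequency or cumulative distribution table plus
    median/IQR (linear-interpolation quartile convention)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    if kind == "frequency":
        hist, edges = np.histogram(v, bins=bins)
        table = pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "relative_frequency": hist / v.size,
            }
        )
    elif kind == "cumulative":
        table = pd.DataFrame(
            {"value": v, "ecdf": np.arange(1, v.size + 1) / v.size}
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return {
        "table": table,
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "n": int(v.size),
    }


def network_metrics(
    image: np.ndarray,
    pixel_size_nm: float,
    roi: np.ndarray | None = None,
) -> NetworkMetrics:
    """Area fraction, fractal dimension and cable lengths of one stained
    network image (grayscale input is Otsu-binarized first)."""
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        raise ValueError("constant image has no network")
    thr = threshold_otsu(img.ravel() if roi is None else img[roi])
    binary = img > thr
    if roi is not None:
        binary &= np.asarray(roi, bool)
    return NetworkMetrics(
        area_fraction_percent=area_fraction(img, roi=roi),
        box_counting_dimension=box_counting_dimension(binary),
        skeleton_lengths_um=skeleton_length_distribution(binary,
                                                         pixel_size_nm),
    )
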