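"""Turning drawings into comparable series and scoring reconstruction.

A drawing is an ordered list of dots on a canvas.  To compare it with the
100-point original, the dots are connected with an interpolating cubic
spline (forced through every dot) and evaluated on the original's input
grid, so both series have the same length.  Two dissimilarity measures are
provided:

* absolute error — the mean absolute pointwise difference;
* wavelet distance — Euclidean distance between Haar approximation
  coefficients of the standardized series, which is robust to scaling and
  shifting of the patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

__all__ = [
    "Drawing",
    "DistanceReport",
    "spline_resample",
    "absolute_error",
    "wavelet_distance",
]

MIN_DOTS = 5


@dataclass
class Drawing:
    """An ordered dot list on the canvas plus an optional resampled series."""

    dots: np.ndarray  # shape (n, 2): (x, y)
    drawer_id: str = "w0"
    pattern_id: str = "p0"
    resampled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dots = np.asarray(self.dots, float).reshape(-1, 2)
        if len(self.dots) < MIN_DOTS:
            raise ValueError(f"a drawing needs at least {MIN_DOTS} dots, got {len(self.dots)}")


@dataclass
class DistanceReport:
    """Reconstruction fidelity of one drawing against one pattern."""

    absolute_error: float
    wavelet_distance: float
    pattern_id: str = "p0"
    drawer_id: str = "w0"


def _dedupe_sorted(x: np.ndarray, y: np.ndarray):
    """Sort dots by x; average y over duplicate x positions (logged)."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size != x.size:
        uy = np.zeros_like(ux)
        counts = np.zeros_like(ux)
        np.add.at(uy, inverse, y)
        np.add.at(counts, inverse, 1.0)
        uy /= counts
        warnings.warn(
            f"{x.size - ux.size} duplicate dot x-position(s) resolved by averaging",
            RuntimeWarning,
            stacklevel=3,
        )
        return ux, uy
    return ux, y


def spline_resample(drawing, x_grid) -> np.ndarray:
    """Resample a drawing onto a grid via an interpolating cubic spline.

    The spline (natural end conditions) passes through every dot exactly;
    outside the outermost dots the series is extended at a constant value.
    Accepts a :class:`Drawing` or an ``(n, 2)`` dot array.
    """
    dots = drawing.dots if isinstance(drawing, Drawing) else np.asarray(drawing, float).reshape(-1, 2)
    if len(dots) < MIN_DOTS:
        raise ValueError(f"a drawing needs at least {MIN_DOTS} dots, got {len(dots)}")
    x, y = _dedupe_sorted(dots[:, 0], dots[:, 1])
    x_grid = np.asarray(x_grid, float).ravel()
    if x.size == 1:
        return np.full_like(x_grid, y[0])
    spline = CubicSpline(x, y, bc_type="natural")
    series = spline(np.clip(x_grid, x[0], x[-1]))
    if isinstance(drawing, Drawing):
        drawing.resampled = series
    return series


def absolute_error(a, b, aggregate: str = "mean") -> float:
    """Mean (or, by flag, summed) absolute pointwise difference."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise ValueError(f"series length mismatch: {a.size} != {b.size}")
    d = np.abs(a - b)
    if aggregate == "mean":
        return float(d.mean())
    if aggregate == "sum":
        return float(d.sum())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        warnings.warn(
            "constant series: standardization fallback to zero vector",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def _pad_pow2(a: np.ndarray) -> np.ndarray:
    n = a.size
    target = 1 << (n - 1).bit_length()
    if target == n:
        return a
    return np.pad(a, (0, target - n), mode="edge")


def _select_level(a: np.ndarray) -> int:
    """Deepest Haar level whose approximation keeps >= 90% of total energy.

    The Haar filters are orthonormal, so coefficient energy partitions the
    series energy exactly; deeper levels keep fewer coefficients.  Falls back
    to level 1 when even the first approximation drops below the threshold.
    """
    total = float(np.sum(a**2))
    if total == 0:
        return 1
    max_level = pywt.dwt_max_level(a.size, "haar")
    level = 1
    for lv in range(1, max_level + 1):
        ca = pywt.downcoef("a", a, "haar", level=lv)
        if float(np.sum(ca**2)) >= 0.9 * total:
            level = lv
        else:
            break
    return level


def wavelet_distance(a, b, level: int | None = None) -> float:
    """Haar-wavelet dissimilarity between two equal-length series.

    Both series are standardized (zero mean, unit variance), padded to a
    power of two by edge replication, Haar-transformed, and compared by the
    Euclidean distance between approximation coefficients at a shared level.
    The shared level is the smaller of the two series' 90%-energy levels
    (a symmetric choice, overridable via ``level``), so the measure is a
    true metric on coefficient space.  Standardization makes it invariant to
    affine transforms ``y -> c1 * y + c2`` with ``c1 > 0``.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise ValueError(f"series length mismatch: {a.size} != {b.size}")
    if a.size < 8:
        raise ValueError(f"series too short for wavelet distance: {a.size} < 8")
    a = _pad_pow2(_standardize(a))
    b = _pad_pow2(_standardize(b))
    if level is None:
        level = min(_select_level(a), _select_level(b))
    ca = pywt.downcoef("a", a, "haar", level=level)
    cb = pywt.downcoef("a", b, "haar", level=level)
    return float(np.linalg.norm(ca - cb))
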