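"""Midline estimation and in-plane head alignment.

The facial midline is near-vertical in an upright portrait, so it is fit
as ``x = a + b*y`` by ordinary least squares over the registry's midline
landmarks (regressing x on y keeps the problem well-posed for head tilts
up to ~25 degrees, where y-on-x would be near-degenerate). The whole
landmark set is then rigidly rotated about the image centre so that the
fitted midline becomes exactly vertical; the applied rotation angle is
``alpha = atan(b)``, inserted into

    x' = cx + (x - cx)*cos(a) - (y - cy)*sin(a)
    y' = cy + (x - cx)*sin(a) + (y - cy)*cos(a)

with pivot ``(cx, cy) = ((w-1)/2, (h-1)/2)``. Rotation is applied to the
landmark coordinates directly (no pixel resampling), keeping the metrology
path free of interpolation noise; any fixed pivot gives identical angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError
from .landmarks import LandmarkSet

__all__ = ["MidlineFit", "AlignmentResult", "fit_midline", "align", "rotate_landmark_set"]


@dataclass(frozen=True)
class MidlineFit:
    """OLS fit of the midline model x = a + b*y."""

    intercept_a: float
    slope_b: float
    n_points: int
    rss: float


@dataclass(frozen=True)
class AlignmentResult:
    rotation_deg: float
    pivot: tuple[float, float]
    aligned: LandmarkSet
    fit: MidlineFit


def fit_midline(ls: LandmarkSet, midline_indices: Sequence[int]) -> MidlineFit:
    """Least-squares midline estimate from the given landmark indices.

    Raises :class:`DegenerateGeometryError` when all midline y values
    coincide (a horizontal point row cannot define a near-vertical line).
    """
    idx = np.asarray(midline_indices, dtype=int)
    if idx.size < 2:
        raise DegenerateGeometryError("midline fit needs at least 2 points")
    pts = ls.xy[idx]
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) == 0.0:
        raise DegenerateGeometryError(
            "all midline landmarks share one y value; midline is not near-vertical"
        )
    # centered normal equations; exactly zero slope for an exactly
    # vertical midline (x constant), unlike an SVD solve
    xbar, ybar = x.mean(), y.mean()
    b = float(np.sum((y - ybar) * (x - xbar)) / np.sum((y - ybar) ** 2))
    a = float(xbar - b * ybar)
    rss = float(np.sum((x - a - b * y) ** 2))
    return MidlineFit(intercept_a=a, slope_b=b, n_points=int(idx.size), rss=rss)


def _rotate_xy(xy: np.ndarray, angle_rad: float, pivot: tuple[float, float]) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    dx = xy[:, 0] - pivot[0]
    dy = xy[:, 1] - pivot[1]
    return np.column_stack(
        [pivot[0] + dx * c - dy * s, pivot[1] + dx * s + dy * c]
    )


def rotate_landmark_set(ls: LandmarkSet, angle_deg: float) -> LandmarkSet:
    """Rigidly rotate all landmarks about the image centre (degrees)."""
    pivot = ((ls.image_width - 1) / 2.0, (ls.image_height - 1) / 2.0)
    return ls.replace(_rotate_xy(ls.xy, np.deg2rad(angle_deg), pivot))


def align(ls: LandmarkSet, midline_indices: Sequence[int]) -> AlignmentResult:
    """Fit the midline and rotate the set so the midline becomes vertical."""
    fit = fit_midline(ls, midline_indices)
    alpha = float(np.arctan(fit.slope_b))
    pivot = ((ls.image_width - 1) / 2.0, (ls.image_height - 1) / 2.0)
    aligned = ls.replace(_rotate_xy(ls.xy, alpha, pivot))
    return AlignmentResult(
        rotation_deg=float(np.rad2deg(alpha)),
        pivot=pivot,
        aligned=aligned,
        fit=fit,
    )
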