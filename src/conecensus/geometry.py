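"""Retinal outline fitting and the central half-radius counting region.

A flat-mounted retina appears as a roughly circular bright disk. The
outline is summarized by a circle (the "outer circle"); cones are counted
only inside the concentric disk of half that radius, because centrally
located cones degenerate first. The half-radius boundary uses a strict
``<`` convention: a point at exactly half the radius is outside the ROI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["RetinaGeometry", "fit_retina_outline", "manual_geometry", "half_radius_mask"]


@dataclass(frozen=True)
class RetinaGeometry:
    """Circle summarizing the retinal outline.

    ``center`` is (x, y) in 0-based pixel coordinates, ``radius`` the
    equivalent-area radius in pixels, ``source`` records whether the
    circle came from the automatic fit or was supplied by an operator.
    """

    center: tuple[float, float]
    radius: float
    source: str = "automatic"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.source not in ("manual", "automatic"):
            raise ValueError(f"source must be 'manual' or 'automatic', got {self.source!r}")


def manual_geometry(center: tuple[float, float], radius: float) -> RetinaGeometry:
    """Operator-supplied outline circle (e.g. drawn in an image viewer)."""
    return RetinaGeometry(center=(float(center[0]), float(center[1])), radius=float(radius), source="manual")


def fit_retina_outline(image: np.ndarray, min_area: int = 64) -> RetinaGeometry:
    """Fit the outer circle of the retina from the image itself.

    Otsu threshold -> largest connected foreground component -> center at
    the component centroid and radius the equivalent-area radius
    ``sqrt(area / pi)``. The equivalent-area radius is robust to the
    ragged, petal-like outlines produced by flat-mount relaxing cuts.

    Raises
    ------
    ValueError
        If the image is empty, constant, or has no foreground component
        of at least ``min_area`` pixels.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if np.ptp(image) == 0:
        raise ValueError("all-background image: constant intensity, no outline to fit")
    thresh = threshold_otsu(image)
    fg = image > thresh
    lab = label(fg)
    props = regionprops(lab)
    props = [p for p in props if p.area >= min_area]
    if not props:
        raise ValueError(f"no foreground component of area >= {min_area} px found")
    largest = max(props, key=lambda p: p.area)
    cy, cx = largest.centroid
    radius = math.sqrt(largest.area / math.pi)
    return RetinaGeometry(center=(cx, cy), radius=radius, source="automatic")


def half_radius_mask(geom: RetinaGeometry, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the central half-radius disk.

    True exactly where the Euclidean distance from ``geom.center`` is
    strictly less than ``geom.radius / 2``. If the disk extends past the
    image bounds the mask is clipped and a warning is emitted.
    """
    h, w = image_shape
    cx, cy = geom.center
    half = geom.radius / 2.0
    if cx - half < -0.5 or cy - half < -0.5 or cx + half > w - 0.5 or cy + half > h - 0.5:
        warnings.warn(
            "half-radius disk extends beyond the image bounds; mask is clipped",
            stacklevel=2,
        )
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(xx - cx, yy - cy) < half
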