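"""Calibrated-image color quantification.

Converts gray-standard-calibrated photographs to an opponent color space
built from a red-green channel x = (R-G)/(R+G) and a blue-green channel
y = (G-B)/(G+B), with luminance taken as the (untransformed) R reflectance.
Chroma is the Euclidean norm of (x, y) and hue the counterclockwise angle
from the +x axis.  Dorsal coloration of a set of individuals is summarized
as a Euclidean distance matrix over the two chromatic axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibratedImage",
    "ColorPoint",
    "UndefinedColorError",
    "normalize_image",
    "roi_mean_rgb",
    "rgb_to_colorpoint",
    "color_distance_matrix",
]


class UndefinedColorError(ValueError):
    """Raised when an opponent channel is undefined (zero channel sum)."""


@dataclass
class CalibratedImage:
    """Linear-reflectance RGB image with ROI masks and physical scale.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Linear reflectance values, nominally in [0, 1] (a small overshoot
        above 1 is tolerated for specular highlights).
    px_per_mm : float
        Physical resolution; must be positive.
    roi_masks : dict of str -> ndarray of bool, shape (H, W)
        Named regions of interest (e.g. ``dorsal_square``, ``dorsal_rect``,
        ``side``, ``ventral``).
    """

    pixels: np.ndarray
    px_per_mm: float
    roi_masks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.pixels.shape[:2]:
                raise ValueError(f"ROI mask {name!r} shape mismatch")
            self.roi_masks[name] = mask


@dataclass(frozen=True)
class ColorPoint:
    """A point in the two-dimensional opponent color space.

    ``hue`` is in degrees in [0, 360), measured counterclockwise from the
    +x (red-green) axis; it is ``None`` for achromatic points (chroma 0),
    where the angle is undefined.
    """

    x: float
    y: float
    luminance: float
    chroma: float
    hue: float | None


def normalize_image(
    raw: np.ndarray,
    gray_patch: tuple[int, int, int, int],
    gray_reflectance: float = 0.18,
    px_per_mm: float = 1.0,
    roi_masks: dict | None = None,
    ceiling: float = 1.5,
    saturation_value: float = 1.0,
) -> CalibratedImage:
    """Linearly rescale each channel so the gray standard reads correctly.

    The single-point calibration divides each channel by the mean value of
    the gray patch and multiplies by the patch's known reflectance
    (18% for the standard used in the field protocol).

    Parameters
    ----------
    raw : ndarray (H, W, 3)
        Linear camera values (any positive scale).
    gray_patch : (row0, row1, col0, col1)
        Half-open pixel bounds of the gray-standard patch.
    gray_reflectance : float
        Known reflectance of the standard, default 0.18.
    ceiling : float
        Values above this are clipped after scaling.
    saturation_value : float
        Raw value treated as sensor saturation; a clipped standard cannot
        be used for calibration.

    Raises
    ------
    ValueError
        If the patch is out of bounds, saturated, or has a non-positive mean.
    """
    raw = np.asarray(raw, dtype=float)
    r0, r1, c0, c1 = gray_patch
    h, w = raw.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("gray patch out of image bounds")
    patch = raw[r0:r1, c0:c1, :]
    if np.any(patch >= saturation_value):
        raise ValueError("standard unusable: gray patch contains saturated pixels")
    means = patch.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("gray patch mean must be positive in every channel")
    scaled = raw * (gray_reflectance / means)
    scaled = np.clip(scaled, 0.0, ceiling)
    return CalibratedImage(scaled, px_per_mm=px_per_mm, roi_masks=roi_masks or {})


def roi_mean_rgb(image: CalibratedImage, roi) -> tuple[float, float, float]:
    """Per-channel arithmetic mean of reflectance over one or more ROIs.

    ``roi`` is a boolean mask, an ROI name, or a sequence of names; named
    regions are pooled into a single mask before averaging (the two dorsal
    regions are measured as one pooled sample of pixels).
    """
    if isinstance(roi, str):
        roi = image.roi_masks[roi]
    elif isinstance(roi, (list, tuple)) and roi and isinstance(roi[0], str):
        pooled = np.zeros(image.pixels.shape[:2], dtype=bool)
        for name in roi:
            pooled |= image.roi_masks[name]
        roi = pooled
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI mask")
    vals = image.pixels[roi]
    r, g, b = vals.mean(axis=0)
    return float(r), float(g), float(b)


def rgb_to_colorpoint(r: float, g: float, b: float) -> ColorPoint:
    """Map mean (R, G, B) reflectances to the opponent color space.

    x = (R-G)/(R+G), y = (G-B)/(G+B); luminance is the untransformed R;
    chroma = sqrt(x^2 + y^2); hue = atan2(y, x) in degrees mapped to
    [0, 360).  Hue is undefined (``None``) at chroma 0.
    """
    if r + g <= 0:
        raise UndefinedColorError("R+G is zero: red-green channel undefined")
    if g + b <= 0:
        raise UndefinedColorError("G+B is zero: blue-green channel undefined")
    x = (r - g) / (r + g)
    y = (g - b) / (g + b)
    chroma = math.hypot(x, y)
    if chroma == 0.0:
        hue = None
    else:
        hue = math.degrees(math.atan2(y, x)) % 360.0
    return ColorPoint(x=x, y=y, luminance=float(r), chroma=chroma, hue=hue)


def color_distance_matrix(points, ids=None) -> np.ndarray:
    """Pairwise Euclidean distance over the two chromatic axes (x, y).

    Luminance is excluded: the color space is two-dimensional because
    luminance is processed separately in vertebrate vision.  ``points``
    holds :class:`ColorPoint` instances; ``None`` entries or non-finite
    coordinates raise with the offending individual ids listed.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least two color points")
    if ids is None:
        ids = [str(i) for i in range(len(points))]
    bad = [
        str(i)
        for i, p in zip(ids, points)
        if p is None or not (np.isfinite(p.x) and np.isfinite(p.y))
    ]
    if bad:
        raise ValueError(f"undefined color points for individuals: {', '.join(bad)}")
    xy = np.array([[p.x, p.y] for p in points])
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
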