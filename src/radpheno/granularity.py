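"""FFT-bandpass granularity analysis and luminance-distribution pattern metrics.

Pattern on a body surface is decomposed into spatial-frequency bands on a
geometric series of scales (2 px, x sqrt(2) per step).  Each band's "energy"
is the standard deviation of the bandpass-filtered luminance image inside
the surface mask; the energy spectrum summarizes marking size and contrast.
Pairwise pattern difference between individuals is the total-variation
distance between their 95-bin luminance histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .imagecal import CalibratedImage

__all__ = [
    "ScaleSeries",
    "GranularitySpectrum",
    "LuminanceHistogram",
    "build_scale_series",
    "rescale_image",
    "bandpass_energy",
    "luminance_histogram",
    "luminance_distribution_difference",
    "pattern_distance_matrix",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class ScaleSeries:
    """Geometric series of filter scales (in pixels)."""

    scales: tuple
    start: float
    factor: float
    max_scale: float

    def __len__(self):
        return len(self.scales)


@dataclass(frozen=True)
class GranularitySpectrum:
    """Per-scale bandpass energies with summary statistics.

    energies[k] is the s.d. of the band-k filtered luminance inside the
    mask.  pattern_contrast is the total spectral energy (sum of band
    energies), pattern_diversity the normalized Shannon entropy of the
    energy proportions (0 = single-scale pattern, 1 = even spread across
    scales), luminance_contrast the s.d. of the unfiltered masked
    luminance, and dominant_scale the scale (px) of the argmax band.
    """

    scales: tuple
    energies: tuple
    pattern_contrast: float
    pattern_diversity: float
    luminance_contrast: float
    dominant_scale: float


@dataclass(frozen=True)
class LuminanceHistogram:
    """Pixel counts over equal-width reflectance bins spanning [0, 1]."""

    counts: np.ndarray
    surface: str | None = None

    @property
    def n_bins(self):
        return len(self.counts)


def build_scale_series(max_scale: float, start: float = 2.0, factor: float = SQRT2) -> ScaleSeries:
    """Maximal geometric scale series within ``max_scale``.

    Starting at ``start`` px and multiplying by ``factor`` until the next
    scale would exceed ``max_scale``.  A 430 px cap yields 16 levels, a
    193 px cap 14 levels.
    """
    if not start > 0:
        raise ValueError("start must be positive")
    if not factor > 1:
        raise ValueError("factor must exceed 1")
    if max_scale < start:
        raise ValueError("max_scale must be at least start")
    scales = []
    k = 0
    while True:
        s = start * factor**k
        if abs(s - round(s)) < 1e-9:  # snap float drift at exact pixel sizes
            s = float(round(s))
        if s > max_scale * (1 + 1e-12):
            break
        scales.append(s)
        k += 1
    return ScaleSeries(tuple(scales), start=start, factor=factor, max_scale=max_scale)


def rescale_image(image: CalibratedImage, target_px_per_mm: float) -> CalibratedImage:
    """Resample an image (bilinear) and its masks (nearest) to a target resolution.

    Pattern statistics are only comparable across individuals when all
    images share the same px/mm, so surfaces are standardized (e.g. side
    19 px/mm, ventral 18.6 px/mm) before filtering.
    """
    if not np.isfinite(image.px_per_mm) or image.px_per_mm <= 0:
        raise ValueError("image px_per_mm unknown or invalid")
    if not target_px_per_mm > 0:
        raise ValueError("target_px_per_mm must be positive")
    zoom = target_px_per_mm / image.px_per_mm
    h, w = image.pixels.shape[:2]
    if zoom == 1.0:
        return image
    new_shape = (max(1, round(h * zoom)), max(1, round(w * zoom)))
    pixels = resize(
        image.pixels, new_shape + (3,), order=1, anti_aliasing=zoom < 1.0, preserve_range=True
    )
    masks = {
        name: resize(mask.astype(float), new_shape, order=0, anti_aliasing=False) > 0.5
        for name, mask in image.roi_masks.items()
    }
    return CalibratedImage(pixels, px_per_mm=target_px_per_mm, roi_masks=masks)


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1)).bit_length()


def bandpass_energy(
    luminance: np.ndarray,
    mask: np.ndarray,
    series: ScaleSeries,
    edge: str = "hard",
    gaussian_width_octaves: float = 0.5,
) -> GranularitySpectrum:
    """Granularity spectrum of a masked luminance image.

    The masked region is embedded in a mean-padded square power-of-two
    canvas and Fourier transformed once.  Band k passes wavelengths in
    [s_k, s_k * factor); adjacent bands tile the spectrum without overlap,
    so for content wholly inside the covered band the squared energies sum
    to the masked variance (a Parseval identity).  Bands are labeled by
    their lower wavelength edge because a marking element of size s (half
    a spatial period) carries its energy at wavelengths just above s; a
    field of spots of diameter d therefore peaks in the band labeled
    near d.  ``edge='gaussian'`` substitutes smooth log-spaced Gaussian
    band edges (non-tiling).
    """
    luminance = np.asarray(luminance, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if luminance.shape != mask.shape:
        raise ValueError("luminance and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")

    mean_val = luminance[mask].mean()
    h, w = luminance.shape
    n = _next_pow2(max(h, w))
    canvas = np.full((n, n), mean_val)
    work = luminance.copy()
    work[~mask] = mean_val
    canvas[:h, :w] = work
    pad_mask = np.zeros((n, n), dtype=bool)
    pad_mask[:h, :w] = mask

    spectrum = np.fft.fft2(canvas)
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    freq = np.hypot(fy, fx)  # cycles per pixel

    energies = []
    for s in series.scales:
        f_hi = 1.0 / s  # wavelength s (inclusive)
        f_lo = 1.0 / (s * series.factor)  # wavelength s*factor (exclusive)
        if edge == "hard":
            band = (freq > f_lo * (1 + 1e-9)) & (freq <= f_hi * (1 + 1e-9))
            filtered = np.fft.ifft2(spectrum * band).real
        elif edge == "gaussian":
            center = math.sqrt(f_lo * f_hi)
            with np.errstate(divide="ignore"):
                logratio = np.where(freq > 0, np.log2(freq / center), -np.inf)
            weight = np.exp(-0.5 * (logratio / gaussian_width_octaves) ** 2)
            weight[freq == 0] = 0.0
            filtered = np.fft.ifft2(spectrum * weight).real
        else:
            raise ValueError(f"unknown edge mode {edge!r}")
        energies.append(float(filtered[pad_mask].std()))

    energies = np.array(energies)
    total = energies.sum()
    if total > 0:
        props = energies / total
        nz = props[props > 0]
        entropy = -(nz * np.log(nz)).sum()
        diversity = float(entropy / math.log(len(energies))) if len(energies) > 1 else 0.0
        dominant = float(series.scales[int(np.argmax(energies))])
    else:
        diversity = 0.0
        dominant = float(series.scales[0])
    return GranularitySpectrum(
        scales=tuple(series.scales),
        energies=tuple(energies),
        pattern_contrast=float(total),
        pattern_diversity=diversity,
        luminance_contrast=float(luminance[mask].std()),
        dominant_scale=dominant,
    )


def luminance_histogram(
    luminance: np.ndarray, mask: np.ndarray, n_bins: int = 95, surface: str | None = None
) -> LuminanceHistogram:
    """Histogram of masked reflectance into ``n_bins`` equal bins over [0, 1].

    Values are clipped into [0, 1] first; the final bin is right-closed so
    counts always sum to the mask's pixel count.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.clip(np.asarray(luminance, dtype=float)[mask], 0.0, 1.0)
    counts, _ = np.histogram(vals, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return LuminanceHistogram(counts=counts.astype(int), surface=surface)


def luminance_distribution_difference(h1: LuminanceHistogram, h2: LuminanceHistogram) -> float:
    """Total-variation distance between two luminance histograms.

    d = 0.5 * sum_k |p1_k - p2_k| on frequency-normalized histograms;
    bounded in [0, 1] (0 identical, 1 disjoint support) and a metric.
    """
    c1 = np.asarray(h1.counts, dtype=float)
    c2 = np.asarray(h2.counts, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("histogram bin counts differ")
    if c1.sum() <= 0 or c2.sum() <= 0:
        raise ValueError("histogram with zero total count")
    return float(0.5 * np.abs(c1 / c1.sum() - c2 / c2.sum()).sum())


def pattern_distance_matrix(histograms, ids=None) -> np.ndarray:
    """Pairwise luminance-distribution differences for one body surface."""
    histograms = list(histograms)
    if len(histograms) < 2:
        raise ValueError("need at least two individuals")
    surfaces = {h.surface for h in histograms if h.surface is not None}
    if len(surfaces) > 1:
        raise ValueError(f"mixed surfaces in one matrix: {sorted(surfaces)}")
    n = len(histograms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = luminance_distribution_difference(histograms[i], histograms[j])
    return d
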