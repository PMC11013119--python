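"""Domain segmentation and surface-coverage estimation.

Two estimators of the area fraction occupied by the higher (gel-phase,
DPPC-rich) domains of a phase-separated film:

* **histogram method** — the pixel-value histogram of a two-phase image
  is bimodal; the threshold is the minimum between the two dominant
  peaks and the coverage is the fraction of pixels above it.
* **particle method** — connected-component labelling of the
  thresholded mask; components below a minimum area are discarded as
  noise and the retained areas are summed.

A "model average" combines the two point estimates (mean) with margins
added in quadrature.  Raw topography must be levelled first
(least-squares plane plus optional per-scan-line median correction) to
remove sample tilt and deposition streaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage import measure

from .scan_io import ScanImage

__all__ = [
    "SegmentationResult",
    "NotBimodalError",
    "level_image",
    "histogram_threshold",
    "coverage_histogram",
    "coverage_particle",
    "model_average",
]


class NotBimodalError(ValueError):
    """The value histogram has fewer than two peaks (single-phase image)."""


@dataclass
class SegmentationResult:
    """Outcome of one coverage estimate.

    ``coverage`` is an area fraction in [0, 1]; ``particles`` (particle
    method only) lists ``(label, area_nm2, centroid)`` per retained
    component.
    """

    method: str
    threshold: float
    mask: np.ndarray
    coverage: float
    particles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if abs(self.coverage - self.mask.mean()) > 1e-12:
            raise ValueError("coverage inconsistent with mask")

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.coverage


def level_image(image: ScanImage, order: int = 1, per_line: bool = False,
                exclude_mask: np.ndarray | None = None) -> ScanImage:
    """Remove background: constant (order 0) or least-squares plane (order 1).

    ``per_line`` additionally subtracts each scan line's median, the
    standard correction for line-to-line offsets and deposition
    streaks.  ``exclude_mask`` marks pixels (e.g. the higher domains
    from a first-pass segmentation) excluded from the background
    estimate — masked flattening avoids the bias that protruding
    domains impose on the plane fit and the line medians.  The output
    has (near-)zero mean.  A constant input image is degenerate: a zero
    image is returned with a warning.
    """
    if order not in (0, 1):
        raise ValueError(f"order must be 0 or 1, got {order}")
    z = image.values
    if np.ptp(z) == 0:
        warnings.warn("constant image: levelling returns a zero image", stacklevel=2)
        return image.with_values(np.zeros_like(z))
    include = None
    if exclude_mask is not None:
        include = ~np.asarray(exclude_mask, dtype=bool)
        if include.shape != z.shape:
            raise ValueError("exclude_mask shape must match image shape")
        if include.sum() < 8:
            raise ValueError("exclude_mask leaves too few background pixels")
    if order == 0:
        out = z - (z.mean() if include is None else z[include].mean())
    else:
        nrow, ncol = z.shape
        rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
        design = np.column_stack([np.ones(z.size), rows.ravel(), cols.ravel()])
        sel = slice(None) if include is None else include.ravel()
        coef, *_ = np.linalg.lstsq(design[sel], z.ravel()[sel], rcond=None)
        out = z - (design @ coef).reshape(z.shape)
    if per_line:
        if include is None:
            offsets = np.median(out, axis=1)
        else:
            # line median over background pixels only; lines almost fully
            # covered by domains keep their plane-only level (offset 0)
            offsets = np.zeros(out.shape[0])
            for i in range(out.shape[0]):
                bg = out[i, include[i]]
                offsets[i] = np.median(bg) if bg.size >= 8 else 0.0
        out = out - offsets[:, None]
        out = out - (out.mean() if include is None else out[include].mean())
    return image.with_values(out)


def histogram_threshold(image: ScanImage, n_bins: int = 256,
                        smooth_bandwidth: int = 5,
                        min_peak_separation: int = 10) -> float:
    """Threshold at the histogram minimum between the two phase peaks.

    Builds an ``n_bins`` histogram of pixel values, smooths it with a
    moving average of ``smooth_bandwidth`` bins, locates the two
    highest local maxima at least ``min_peak_separation`` bins apart,
    and returns the value at the deepest bin strictly between them.

    Raises :class:`NotBimodalError` when fewer than two peaks survive
    smoothing, or when the valley between the best peak pair is not
    clearly below both peaks (shallower than half the lower peak) —
    either way the image is effectively single-phase.
    """
    z = image.values.ravel()
    if min(image.shape) < 8:
        raise ValueError(f"image too small for histogram analysis: {image.shape}")
    lo, hi = float(z.min()), float(z.max())
    if lo == hi:
        raise NotBimodalError("constant image has no bimodal histogram")
    hist, edges = np.histogram(z, bins=n_bins, range=(lo, hi))
    smoothed = uniform_filter1d(hist.astype(float), size=max(1, smooth_bandwidth),
                                mode="constant")
    # pad so peaks in the first/last bin are detectable
    padded = np.concatenate([[-1.0], smoothed, [-1.0]])
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
    peak_idx = np.flatnonzero(is_peak)
    if len(peak_idx) < 2:
        raise NotBimodalError("fewer than two histogram peaks after smoothing")
    # candidate pairs ordered by combined height (ties -> wider separation);
    # the phase peaks are the first pair whose valley dips clearly below
    # both — noise wiggles inside a single mode never have a deep valley
    order = peak_idx[np.argsort(smoothed[peak_idx])[::-1]][:12]
    pairs = []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a, b = sorted((int(order[i]), int(order[j])))
            if b - a >= min_peak_separation:
                pairs.append((smoothed[a] + smoothed[b], b - a, a, b))
    for _, _, a, b in sorted(pairs, key=lambda p: (p[0], p[1]), reverse=True):
        valley = a + 1 + int(np.argmin(smoothed[a + 1:b]))
        if smoothed[valley] < 0.5 * min(smoothed[a], smoothed[b]):
            centers = 0.5 * (edges[:-1] + edges[1:])
            return float(centers[valley])
    raise NotBimodalError(
        "no peak pair with a clear separating valley: image looks single-phase")


def coverage_histogram(image: ScanImage, n_bins: int = 256,
                       smooth_bandwidth: int = 5) -> SegmentationResult:
    """Coverage of the higher phase by histogram thresholding."""
    thr = histogram_threshold(image, n_bins=n_bins, smooth_bandwidth=smooth_bandwidth)
    mask = image.values > thr
    return SegmentationResult(method="histogram", threshold=thr, mask=mask,
                              coverage=float(mask.mean()))


def coverage_particle(image: ScanImage, threshold: float | None = None,
                      min_area: float | None = None,
                      connectivity: int = 8) -> SegmentationResult:
    """Coverage of the higher phase by particle (connected-shape) detection.

    ``min_area`` is in nm²; the default keeps components of at least 4
    pixels.  ``connectivity`` is 4 or 8 (pixel neighbourhood).
    Propagates :class:`NotBimodalError` if automatic thresholding fails.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if threshold is None:
        threshold = histogram_threshold(image)
    px_area = image.pixel_size ** 2
    if min_area is None:
        min_area = 4 * px_area
    mask = image.values > threshold
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    particles = []
    keep = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        area_nm2 = region.area * px_area
        if area_nm2 < min_area:
            continue
        particles.append((region.label, area_nm2, tuple(region.centroid)))
        keep[labels == region.label] = True
    return SegmentationResult(method="particle", threshold=float(threshold),
                              mask=keep, coverage=float(keep.mean()),
                              particles=particles)


def model_average(a: tuple[float, float], b: tuple[float, float],
                  ndigits: int | None = 0) -> tuple[float, float]:
    """Combine two (estimate, margin) pairs in percent.

    Point estimate: the mean of the two estimates.  Margin: quadrature
    sum of the two margins.  Both rounded to ``ndigits`` decimals
    (default integer percent, the printed precision); pass
    ``ndigits=None`` for full precision.
    """
    (va, ma), (vb, mb) = a, b
    if ma < 0 or mb < 0:
        raise ValueError("margins must be >= 0")
    value = 0.5 * (va + vb)
    margin = float(np.hypot(ma, mb))
    if ndigits is not None:
        value, margin = round(value, ndigits), round(margin, ndigits)
        if ndigits == 0:
            value, margin = float(value), float(margin)
    return value, margin
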