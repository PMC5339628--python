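"""PET preprocessing chain: upsampling, median filtering, DTD.

The PET slices are brought to CT resolution with cubic B-spline
interpolation, median-filtered to suppress single-pixel noise, then
denoised with dynamic threshold denoising (DTD): a binarization threshold
set just above the gray-histogram peak (the background mode in
background-dominated PET), followed by the same contour
selection/rasterization machinery used for CT.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .ct_preprocess import (
    SelectionPolicy,
    extract_external_contours,
    rasterize_feature_and_mask,
    select_effective_contours,
    slice_region,
)

__all__ = [
    "HistogramPeak",
    "ThresholdSpec",
    "RegionOffsets",
    "bspline_upsample",
    "median_filter",
    "dynamic_threshold",
    "dtd_segment",
]


@dataclass
class HistogramPeak:
    """256-bin gray histogram of a [0,255] slice and its peak location."""

    histogram: np.ndarray
    peak_loc: int


@dataclass
class ThresholdSpec:
    """A binarization threshold and the resulting binary image."""

    threshold: float
    thresholded: np.ndarray  # boolean; pixel is foreground iff value > threshold


@dataclass
class RegionOffsets:
    """Per-region offsets added to the histogram peak to form the threshold.

    In whole-body PET the histogram peak sits on the background mode; a
    small positive offset above it separates body counts from background.
    The offset may differ between head, trunk and leg slices.
    """

    head: float = 2.0
    trunk: float = 2.0
    legs: float = 2.0

    def offset_for(self, region: str) -> float:
        return getattr(self, region)

    def to_dict(self) -> dict:
        return asdict(self)


def bspline_upsample(slice_: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Cubic B-spline upsampling of one slice to ``target_shape``.

    Pixel centers are treated as cell centers (the geometry used when a
    coarse grid covers the same field of view as a fine one), edges are
    replicated, and interpolation overshoot is clipped back to [0, 255].
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    rows, cols = slice_.shape
    tr, tc = target_shape
    if tr < rows or tc < cols:
        raise ValueError("downsampling not supported here")
    if (tr, tc) == (rows, cols):
        return slice_.copy()
    out = ndimage.zoom(
        slice_, (tr / rows, tc / cols), order=3, grid_mode=True, mode="nearest"
    )
    return np.clip(out, 0.0, 255.0)


def median_filter(slice_: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with an odd ``kernel`` x ``kernel`` window, edge-replicated."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    return ndimage.median_filter(
        np.asarray(slice_, dtype=np.float64), size=kernel, mode="nearest"
    )


def gray_histogram_peak(slice_: np.ndarray) -> HistogramPeak:
    """256-bin histogram over [0, 255] and the gray value of its peak."""
    vals = np.clip(np.asarray(slice_, dtype=np.float64).ravel(), 0, 255)
    hist, _ = np.histogram(vals, bins=256, range=(-0.5, 255.5))
    return HistogramPeak(histogram=hist, peak_loc=int(np.argmax(hist)))


def dynamic_threshold(
    slice_: np.ndarray,
    slice_id: int,
    n_slices: int,
    offsets: RegionOffsets | None = None,
    policy: SelectionPolicy | None = None,
) -> ThresholdSpec:
    """Threshold = histogram peak + region offset; binarize above it."""
    offsets = offsets or RegionOffsets()
    policy = policy or SelectionPolicy()
    region = slice_region(slice_id, n_slices, policy)  # validates n_slices
    peak = gray_histogram_peak(slice_)
    threshold = peak.peak_loc + offsets.offset_for(region)
    return ThresholdSpec(
        threshold=threshold, thresholded=np.asarray(slice_, dtype=np.float64) > threshold
    )


def dtd_segment(
    slice_: np.ndarray,
    slice_id: int,
    n_slices: int,
    policy: SelectionPolicy | None = None,
    offsets: RegionOffsets | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic threshold denoising of one (median-filtered) PET slice.

    Contour extraction/selection runs on the thresholded image; the
    segmented output keeps the original, pre-threshold intensities inside
    the selected body mask and is 0 elsewhere.  Returns
    (segmented, feature).
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    spec = dynamic_threshold(slice_, slice_id, n_slices, offsets, policy)
    contours = extract_external_contours(spec.thresholded.astype(np.float64), threshold=0.0)
    selection = select_effective_contours(
        contours, slice_id, n_slices, policy, shape=slice_.shape
    )
    feature, mask = rasterize_feature_and_mask(selection, slice_.shape)
    # never create foreground where the thresholded image is background
    mask = mask * spec.thresholded
    feature = mask.astype(np.float64) * 255.0
    segmented = slice_ * mask
    return segmented, feature
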