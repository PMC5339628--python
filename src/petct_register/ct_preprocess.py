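"""Geometric feature-based segmentation (GFS) of CT slices.

Removes the scanning-bed shadow and all other background from normalized CT
slices.  The stages are: external-contour extraction on the thresholded
slice, an area filter plus a slice-position-aware contour selection, and
rasterization of the selected contours into a binary feature image and a
{0,1} mask that multiplies the input.

Areas are polygon (shoelace) areas over boundary-pixel center coordinates,
so a filled 50x50 square has contour area 49*49 = 2401.  The minimum-area
filter of 1000 px is defined at 512x512 resolution and scaled by
(rows*cols)/512^2 for other slice sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

__all__ = [
    "Contour",
    "ContourSelection",
    "SelectionPolicy",
    "extract_external_contours",
    "select_effective_contours",
    "rasterize_feature_and_mask",
    "gfs_segment",
    "scaled_min_area",
    "slice_region",
]

# clockwise 8-neighborhood offsets (row, col), starting at north
_NBR = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_EIGHT = np.ones((3, 3), dtype=int)

#: reference slice size at which the default minimum contour area is defined
_REFERENCE_PIXELS = 512 * 512


@dataclass
class Contour:
    """Ordered external boundary of one connected foreground region."""

    points: np.ndarray  # (n, 2) of (x, y) pixel-center coordinates
    area: float  # shoelace polygon area, >= 0

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Contour":
        pts = np.asarray(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be (n, 2)")
        return cls(points=pts, area=shoelace_area(pts))


def shoelace_area(points: np.ndarray) -> float:
    """Absolute polygon area of an (n, 2) point loop (Green's theorem)."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class SelectionPolicy:
    """Slice-position-aware contour selection rules.

    The slice sequence is partitioned by relative slice position into head
    (< ``head_frac``), trunk, and legs (> ``leg_frac``).  In head and trunk
    the largest candidate plus any candidate whose area is at least
    ``beta`` times the largest are kept (admitting e.g. arms resting by the
    body while rejecting the small bed-shadow arc); in the leg region up to
    ``max_regions`` candidates passing the same ratio test are kept (two
    legs, possibly arms).  ``min_area`` is the candidate area filter at
    512x512 resolution.
    """

    min_area: float = 1000.0
    beta: float = 0.1
    head_frac: float = 0.2
    leg_frac: float = 0.7
    max_regions: int = 4

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ContourSelection:
    """Area-filtered candidates and the selected effective contour list."""

    candidates: list[Contour]
    effective: list[Contour]

    @property
    def h(self) -> int:
        return len(self.candidates)

    @property
    def size(self) -> int:
        return len(self.effective)


def scaled_min_area(min_area: float, shape: tuple[int, int]) -> float:
    """Minimum contour area rescaled from 512x512 to the given slice shape."""
    rows, cols = shape
    return min_area * (rows * cols) / _REFERENCE_PIXELS


def slice_region(slice_id: int, n_slices: int, policy: SelectionPolicy) -> str:
    """Classify a slice as 'head', 'trunk' or 'legs' by relative position."""
    if n_slices <= 0:
        raise ValueError("invalid sequence length")
    frac = slice_id / n_slices
    if frac < policy.head_frac:
        return "head"
    if frac > policy.leg_frac:
        return "legs"
    return "trunk"


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixels of one connected component.

    Moore-neighbor tracing; terminates when the (pixel, backtrack) state
    repeats, so the boundary is traversed exactly once.  Returns an (n, 2)
    array of (row, col) coordinates.
    """
    rows, cols = np.nonzero(mask)
    sr = int(rows.min())
    sc = int(cols[rows == sr].min())
    start = (sr, sc)
    if len(rows) == 1:
        return np.array([start])
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    contour = [start]
    cur, bdir = start, 6  # backtrack pixel lies west of the start pixel
    seen = {(cur, bdir)}
    while True:
        for k in range(1, 9):
            d = (bdir + k) % 8
            r, c = cur[0] + _NBR[d][0], cur[1] + _NBR[d][1]
            if fg(r, c):
                nxt = (r, c)
                # backtrack = background neighbor examined just before d
                pb = (cur[0] + _NBR[(d - 1) % 8][0], cur[1] + _NBR[(d - 1) % 8][1])
                nbdir = next(
                    j for j in range(8)
                    if (nxt[0] + _NBR[j][0], nxt[1] + _NBR[j][1]) == pb
                )
                if (nxt, nbdir) in seen:
                    return np.array(contour)
                seen.add((nxt, nbdir))
                contour.append(nxt)
                cur, bdir = nxt, nbdir
                break
        else:  # isolated pixel cluster fully traversed
            return np.array(contour)


def extract_external_contours(grid: np.ndarray, threshold: float = 0.0) -> list[Contour]:
    """External contours of all foreground regions, largest area first.

    Foreground is ``grid > threshold``.  Only outermost boundaries are
    returned: interior holes and nested structures are ignored, matching
    the body-silhouette semantics of the feature image.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("expected a 2D grid")
    binary = grid > threshold
    if not binary.any():
        return []
    labels, n = ndimage.label(binary, structure=_EIGHT)
    contours = []
    for obj_slice, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        sub = labels[obj_slice] == lab
        rc = _moore_trace(sub)
        r0, c0 = obj_slice[0].start, obj_slice[1].start
        pts_xy = np.stack([rc[:, 1] + c0, rc[:, 0] + r0], axis=1).astype(np.float64)
        contours.append(Contour.from_points(pts_xy))
    contours.sort(key=lambda c: -c.area)
    return contours


def select_effective_contours(
    contours: Sequence[Contour],
    slice_id: int,
    n_slices: int,
    policy: SelectionPolicy | None = None,
    shape: tuple[int, int] | None = None,
) -> ContourSelection:
    """Area filter plus position-aware selection of body contours.

    ``shape`` (rows, cols), when given, rescales ``policy.min_area`` from
    its 512x512 reference; otherwise ``min_area`` is used as-is.
    """
    policy = policy or SelectionPolicy()
    if n_slices <= 0:
        raise ValueError("invalid sequence length")
    min_area = (
        scaled_min_area(policy.min_area, shape) if shape is not None else policy.min_area
    )
    candidates = sorted(
        (c for c in contours if c.area >= min_area), key=lambda c: -c.area
    )
    if not candidates:
        return ContourSelection(candidates=[], effective=[])

    region = slice_region(slice_id, n_slices, policy)
    largest = candidates[0].area
    keep = [c for c in candidates if c.area >= policy.beta * largest]
    if region in ("head", "trunk"):
        effective = keep
    else:
        effective = keep[: policy.max_regions]
    return ContourSelection(candidates=candidates, effective=effective)


def rasterize_feature_and_mask(
    selection: ContourSelection, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Fill the effective contours: feature image ({0,255}) and mask ({0,1}).

    The interior of each effective contour, boundary pixels included, is
    set; interior holes are filled solid.
    """
    rows, cols = shape
    mask = np.zeros(shape, dtype=np.uint8)
    for contour in selection.effective:
        pts = contour.points
        if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                or pts[:, 0].max() >= cols or pts[:, 1].max() >= rows):
            raise ValueError("contour outside image")
        r = pts[:, 1]
        c = pts[:, 0]
        if len(pts) >= 3:
            rr, cc = draw_polygon(r, c, shape)
            mask[rr, cc] = 1
            rr, cc = polygon_perimeter(r, c, shape, clip=False)
            ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
            mask[rr[ok], cc[ok]] = 1
        else:
            mask[r.astype(int), c.astype(int)] = 1
    feature = mask.astype(np.float64) * 255.0
    return feature, mask


def gfs_segment(
    slice_: np.ndarray,
    slice_id: int,
    n_slices: int,
    policy: SelectionPolicy | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment one normalized CT slice: returns (segmented, feature).

    The segmented slice equals the input inside the selected body contours
    and 0 elsewhere; the feature image is the binary body silhouette.
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    contours = extract_external_contours(slice_, threshold=0.0)
    selection = select_effective_contours(
        contours, slice_id, n_slices, policy, shape=slice_.shape
    )
    feature, mask = rasterize_feature_and_mask(selection, slice_.shape)
    segmented = slice_ * mask
    return segmented, feature
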