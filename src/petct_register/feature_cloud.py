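"""Trunk-slice detection, feature-point extraction, PCD round-trip,
and the averaging downsampler.

A *trunk slice* is a slice whose binary feature image contains exactly one
connected foreground region.  The trunk range runs from the first to the
last such slice; every slice in between is registered, whatever its own
region count.  Feature points are the boundary pixels of a feature image
(foreground pixels with at least one background 4-neighbor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "TrunkRange",
    "PointCloud",
    "DownsampleSpec",
    "count_connected_regions",
    "extract_trunk_range",
    "extract_feature_points",
    "downsample_cloud",
    "build_point_cloud_sequences",
    "write_pcd",
    "read_pcd",
]

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class TrunkRange:
    """Per-slice connected-region counts and the [m1, m2] trunk interval."""

    ncr: list[int]
    m1: int
    m2: int

    def to_dict(self) -> dict:
        return {"ncr": self.ncr, "m1": self.m1, "m2": self.m2}


@dataclass
class PointCloud:
    """A set of feature points (x, y, z) in pixel/slice coordinates."""

    points: np.ndarray  # (n, 3) float
    source_slice: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class DownsampleSpec:
    """Averaging downsampler settings.

    ``ordering`` selects what "adjacent" means: ``"contour"`` (default)
    groups runs of alpha consecutive points along the traced outline, which
    preserves the contour shape (group means are sub-pixel samples of the
    underlying curve); ``"axis"`` sorts lexicographically along
    ``direction`` first, which interleaves the two branches of a closed
    contour and is kept only as an explicit option.
    """

    alpha: int = 50
    direction: Literal["x", "y"] = "x"
    ordering: Literal["contour", "axis"] = "contour"

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("invalid sample ratio")
        if self.direction not in ("x", "y"):
            raise ValueError("direction must be 'x' or 'y'")
        if self.ordering not in ("contour", "axis"):
            raise ValueError("ordering must be 'contour' or 'axis'")


def count_connected_regions(feature: np.ndarray, connectivity: int = 8) -> int:
    """Number of foreground connected regions in a binary feature image."""
    feature = np.asarray(feature)
    vals = np.unique(feature)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError("not a feature image")
    structure = _EIGHT if connectivity == 8 else _FOUR
    _, n = ndimage.label(feature > 0, structure=structure)
    return int(n)


def extract_trunk_range(
    features: Sequence[np.ndarray], connectivity: int = 8
) -> TrunkRange:
    """First/last slice with exactly one connected region.

    All slices between m1 and m2 are registered downstream even if their
    own region count differs from one.
    """
    if len(features) == 0:
        raise ValueError("empty feature sequence")
    ncr = [count_connected_regions(f, connectivity) for f in features]
    ones = [i for i, n in enumerate(ncr) if n == 1]
    if not ones:
        raise ValueError("no trunk slices found")
    return TrunkRange(ncr=ncr, m1=ones[0], m2=ones[-1])


def extract_feature_points(feature: np.ndarray, slice_id: int = 0,
                           z: float | None = None) -> PointCloud:
    """Boundary pixels of a feature image as a point cloud.

    A feature point is a foreground pixel with at least one background
    4-neighbor (image-border foreground pixels count as boundary).  Each
    point is emitted once as (x, y, z), ordered along the traced outline of
    its connected region (components in scan order; any boundary pixels the
    outer trace does not reach, e.g. hole rims, follow in scan order).
    z defaults to the slice index.
    """
    from .ct_preprocess import _moore_trace  # local import avoids a cycle

    fg = np.asarray(feature) > 0
    if not fg.any():
        return PointCloud(points=np.empty((0, 3)), source_slice=slice_id)
    interior = ndimage.binary_erosion(fg, structure=_FOUR, border_value=0)
    boundary = fg & ~interior
    labels, nlab = ndimage.label(fg, structure=_EIGHT)
    ordered: list[tuple[int, int]] = []
    emitted = np.zeros_like(boundary)
    for obj, lab in zip(ndimage.find_objects(labels), range(1, nlab + 1)):
        sub = labels[obj] == lab
        r0, c0 = obj[0].start, obj[1].start
        for rr, cc in _moore_trace(sub):
            r, c = rr + r0, cc + c0
            if boundary[r, c] and not emitted[r, c]:
                emitted[r, c] = True
                ordered.append((r, c))
    rest = np.argwhere(boundary & ~emitted)
    ordered.extend((int(r), int(c)) for r, c in rest)
    zval = float(slice_id) if z is None else float(z)
    pts = np.array(
        [(c, r, zval) for r, c in ordered], dtype=np.float64
    ).reshape(-1, 3)
    return PointCloud(points=pts, source_slice=slice_id)


def downsample_cloud(cloud: PointCloud, spec: DownsampleSpec) -> PointCloud:
    """Replace each run of ``alpha`` adjacent points by their mean.

    In contour ordering the stored point order (outline traversal) is
    grouped directly; in axis ordering points are first sorted along the
    chosen direction (ties broken by the other in-plane coordinate, then
    z).  Each original point is used exactly once, a final short group is
    averaged as well, so the output has ceil(n / alpha) points.
    """
    pts = cloud.points
    n = len(pts)
    if n == 0:
        return PointCloud(points=pts.copy(), source_slice=cloud.source_slice)
    if spec.ordering == "axis":
        pts = pts[_sort_order(pts, spec.direction)]
    if spec.alpha == 1:
        return PointCloud(points=pts.copy(), source_slice=cloud.source_slice)
    out = []
    for start in range(0, n, spec.alpha):
        out.append(pts[start:start + spec.alpha].mean(axis=0))
    return PointCloud(points=np.array(out), source_slice=cloud.source_slice)


def _sort_order(pts: np.ndarray, direction: str) -> np.ndarray:
    primary, secondary = (0, 1) if direction == "x" else (1, 0)
    return np.lexsort((pts[:, 2], pts[:, secondary], pts[:, primary]))


def build_point_cloud_sequences(
    ct_features: Sequence[np.ndarray],
    pet_features: Sequence[np.ndarray],
    connectivity: int = 8,
    z_spacing: float = 1.0,
    out_dir: str | Path | None = None,
) -> tuple[list[PointCloud], list[PointCloud], TrunkRange]:
    """Per-slice fixed (CT) and moving (PET) clouds over the CT trunk range.

    The trunk range is determined from the CT features only; the PET and CT
    series are in one-to-one slice correspondence, so the same slice ids
    select the PET trunk.  When ``out_dir`` is given, one ASCII PCD file per
    slice and modality is written plus a JSON sidecar with the trunk range.
    """
    if len(ct_features) != len(pet_features):
        raise ValueError("sequences not in correspondence")
    trunk = extract_trunk_range(ct_features, connectivity)
    fixed, moving = [], []
    for sid in range(trunk.m1, trunk.m2 + 1):
        z = sid * z_spacing
        fixed.append(extract_feature_points(ct_features[sid], sid, z=z))
        moving.append(extract_feature_points(pet_features[sid], sid, z=z))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pc in fixed:
            write_pcd(pc, out_dir / f"ct_{pc.source_slice:04d}.pcd")
        for pc in moving:
            write_pcd(pc, out_dir / f"pet_{pc.source_slice:04d}.pcd")
        (out_dir / "trunk_range.json").write_text(
            json.dumps(trunk.to_dict(), indent=1) + "\n"
        )
    return fixed, moving, trunk


_PCD_HEADER = """\
# .PCD v0.7 - Point Cloud Data file format
VERSION 0.7
FIELDS x y z
SIZE 8 8 8
TYPE F F F
COUNT 1 1 1
WIDTH {n}
HEIGHT 1
VIEWPOINT 0 0 0 1 0 0 0
POINTS {n}
DATA ascii
"""


def write_pcd(cloud: PointCloud, path: str | Path) -> Path:
    """Write a cloud as ASCII PCD with full-precision decimal coordinates."""
    path = Path(path)
    lines = [_PCD_HEADER.format(n=len(cloud))]
    for x, y, z in cloud.points:
        lines.append(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
    path.write_text("".join(lines))
    return path


def read_pcd(path: str | Path) -> PointCloud:
    """Read an ASCII PCD file written by :func:`write_pcd`."""
    pts = []
    in_data = False
    for line in Path(path).read_text().splitlines():
        if in_data:
            parts = line.split()
            if len(parts) == 3:
                pts.append([float(v) for v in parts])
        elif line.startswith("DATA"):
            if line.split()[1] != "ascii":
                raise ValueError("only ASCII PCD is supported")
            in_data = True
    return PointCloud(points=np.array(pts, dtype=np.float64).reshape(-1, 3))
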