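"""Registration accuracy metrics and visual diagnostics.

Two metrics quantify how well two binary feature volumes agree:

* negative normalized correlation,
  ``NC(A, B) = -sum(A_i B_i) / sqrt(sum(A_i^2) sum(B_i^2))``, in [-1, 0],
  with -1 meaning identical supports and 0 disjoint ones;
* Euclidean distance error, the directed mean nearest-neighbor distance
  from the landmark (feature-point) set of one volume to the other's.

Checkerboard composites and signed subtraction volumes provide the
corresponding visual checks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .feature_cloud import PointCloud

__all__ = [
    "negative_normalized_correlation",
    "euclidean_distance_error",
    "checkerboard_composite",
    "subtraction_volume",
    "stack_binary",
]


def stack_binary(features: Sequence[np.ndarray]) -> np.ndarray:
    """Stack feature images into a {0,1} volume (255 maps to 1)."""
    vol = np.stack([np.asarray(f) for f in features], axis=0)
    return (vol > 0).astype(np.float64)


def negative_normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """NC of two equally shaped binary feature volumes; in [-1, 0]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("incompatible images: shapes differ")
    na = float((a * a).sum())
    nb = float((b * b).sum())
    if na == 0.0 or nb == 0.0:
        raise ValueError("undefined NC (zero norm)")
    return -float((a * b).sum()) / np.sqrt(na * nb)


def euclidean_distance_error(
    fs_a: PointCloud | np.ndarray,
    fs_b: PointCloud | np.ndarray,
    symmetric: bool = False,
) -> float:
    """Directed mean nearest-neighbor distance from ``fs_a`` to ``fs_b``.

    With ``symmetric=True`` the two directed means are averaged.  Note the
    directed form is asymmetric in its arguments.
    """
    pa = fs_a.points if isinstance(fs_a, PointCloud) else np.asarray(fs_a, float)
    pb = fs_b.points if isinstance(fs_b, PointCloud) else np.asarray(fs_b, float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("no landmarks")
    d_ab = cKDTree(pb).query(pa)[0].mean()
    if not symmetric:
        return float(d_ab)
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def checkerboard_composite(a: np.ndarray, b: np.ndarray, blocks: int = 8) -> np.ndarray:
    """Alternate ``blocks x blocks`` tiles from A (even parity) and B (odd)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("incompatible images: shapes differ")
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    rows, cols = a.shape
    r_edges = np.linspace(0, rows, blocks + 1).astype(int)
    c_edges = np.linspace(0, cols, blocks + 1).astype(int)
    out = a.copy()
    for i in range(blocks):
        for j in range(blocks):
            if (i + j) % 2 == 1:
                out[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]] = \
                    b[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
    return out


def subtraction_volume(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed voxelwise difference A - B of two binary feature volumes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("incompatible images: shapes differ")
    return a - b


def orthogonal_sections(vol: np.ndarray) -> dict[str, np.ndarray]:
    """Central transverse/sagittal/coronal sections of a (z, y, x) volume."""
    z, y, x = vol.shape
    return {
        "transverse": vol[z // 2, :, :],
        "coronal": vol[:, y // 2, :],
        "sagittal": vol[:, :, x // 2],
    }
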