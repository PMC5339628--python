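"""Volume I/O and intensity normalization.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index and ``z`` the slice index, all 0-based.
Slices are stored row-major, so ``slices[z][y, x]`` addresses one voxel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pydicom
import SimpleITK as sitk
from PIL import Image

__all__ = [
    "IntensityVolume",
    "WindowSpec",
    "read_dicom_series",
    "normalize_intensity",
    "normalize_volume",
    "write_volume",
    "write_png_slices",
]

#: display window used for CT series that carry no window tags (soft-tissue window)
CT_FALLBACK_WINDOW = (40.0, 400.0)


@dataclass
class WindowSpec:
    """Display window: the intensity interval mapped onto [0, 255].

    ``imin``/``imax`` are derived as ``wc -/+ ww / 2``.
    """

    wc: float
    ww: float

    def __post_init__(self) -> None:
        if self.ww <= 0:
            raise ValueError("invalid window: ww must be > 0")

    @property
    def imin(self) -> float:
        return self.wc - self.ww / 2.0

    @property
    def imax(self) -> float:
        return self.wc + self.ww / 2.0


@dataclass
class IntensityVolume:
    """A z-ordered stack of 2D intensity slices with basic geometry metadata."""

    slices: list[np.ndarray]
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # mm per pixel (x, y)
    slice_thickness: float = 1.0  # mm
    modality: Literal["CT", "PET"] = "CT"
    window: WindowSpec | None = None

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("volume must contain at least one slice")
        shape = self.slices[0].shape
        if any(s.shape != shape for s in self.slices):
            raise ValueError("inconsistent series: slices differ in shape")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def as_array(self) -> np.ndarray:
        """Stack slices into a (z, rows, cols) array."""
        return np.stack(self.slices, axis=0)

    def default_window(self) -> WindowSpec:
        """Window from metadata, or the modality fallback.

        CT falls back to a soft-tissue window (wc=40, ww=400); PET falls
        back to the full data range of the volume.
        """
        if self.window is not None:
            return self.window
        if self.modality == "CT":
            return WindowSpec(*CT_FALLBACK_WINDOW)
        arr = self.as_array()
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            hi = lo + 1.0
        return WindowSpec(wc=(hi + lo) / 2.0, ww=hi - lo)


def _first(value) -> float:
    """First element of a possibly multi-valued DICOM tag."""
    try:
        return float(value[0])
    except (TypeError, IndexError):
        return float(value)


def read_dicom_series(directory: str | os.PathLike) -> IntensityVolume:
    """Read a single-frame DICOM series into an :class:`IntensityVolume`.

    Slices are sorted by slice position (Image Position Patient z, falling
    back to Instance Number), independent of file names.  Rescale
    slope/intercept are applied when present; window center/width are
    captured from the first slice that carries them.
    """
    directory = Path(directory)
    datasets = []
    for p in sorted(directory.iterdir()) if directory.is_dir() else []:
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(p))
            _ = ds.pixel_array
        except Exception:
            continue
        datasets.append(ds)
    if not datasets:
        raise FileNotFoundError(f"no series found in {directory}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        if slope != 1.0 or intercept != 0.0:
            arr = arr * slope + intercept
        slices.append(arr)
    if len({s.shape for s in slices}) != 1:
        raise ValueError("inconsistent series: slices differ in shape")

    ds0 = datasets[0]
    spacing = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(ds0, "SliceThickness", 1.0))
    modality = str(getattr(ds0, "Modality", "CT"))
    modality = "PET" if modality.upper() in ("PT", "PET") else "CT"

    window = None
    for ds in datasets:
        if hasattr(ds, "WindowCenter") and hasattr(ds, "WindowWidth"):
            ww = _first(ds.WindowWidth)
            if ww > 0:
                window = WindowSpec(wc=_first(ds.WindowCenter), ww=ww)
                break

    return IntensityVolume(
        slices=slices,
        pixel_spacing=(float(spacing[1]), float(spacing[0])),
        slice_thickness=thickness,
        modality=modality,
        window=window,
    )


def normalize_intensity(vol: IntensityVolume, window: WindowSpec | None = None) -> IntensityVolume:
    """Map intensities onto [0, 255] through the display window.

    ``I' = (I - Imin) / (Imax - Imin) * 255`` with ``Imin = wc - ww/2`` and
    ``Imax = wc + ww/2``; values outside the window are clipped.
    """
    w = window if window is not None else vol.default_window()
    out = []
    span = w.imax - w.imin
    for s in vol.slices:
        # multiply before dividing so I = Imax maps to exactly 255
        out.append(np.clip((s.astype(np.float64) - w.imin) * 255.0 / span,
                           0.0, 255.0))
    return IntensityVolume(
        slices=out,
        pixel_spacing=vol.pixel_spacing,
        slice_thickness=vol.slice_thickness,
        modality=vol.modality,
        window=WindowSpec(127.5, 255.0),
    )


# alias used by pipeline code for readability
normalize_volume = normalize_intensity


def _to_sitk(vol: IntensityVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.as_array())
    img.SetSpacing((vol.pixel_spacing[0], vol.pixel_spacing[1], vol.slice_thickness))
    return img


def write_volume(vol: IntensityVolume | np.ndarray, path: str | os.PathLike,
                 pixel_spacing: tuple[float, float] = (1.0, 1.0),
                 slice_thickness: float = 1.0) -> Path:
    """Write a volume as MetaImage (.mha) or NIfTI (.nii/.nii.gz) by extension."""
    if isinstance(vol, np.ndarray):
        vol = IntensityVolume(slices=list(vol.astype(np.float64)),
                              pixel_spacing=pixel_spacing,
                              slice_thickness=slice_thickness)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(vol), str(path))
    return path


def read_volume(path: str | os.PathLike) -> IntensityVolume:
    """Read an .mha/.nii volume back into an :class:`IntensityVolume`."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    sp = img.GetSpacing()
    return IntensityVolume(slices=list(arr), pixel_spacing=(sp[0], sp[1]),
                           slice_thickness=sp[2] if len(sp) > 2 else 1.0)


def write_png_slices(slices: Sequence[np.ndarray], directory: str | os.PathLike,
                     prefix: str = "slice") -> list[Path]:
    """Export slices as 8-bit grayscale PNGs (values clipped to [0, 255])."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(slices):
        arr = np.clip(np.asarray(s, dtype=np.float64), 0, 255).astype(np.uint8)
        p = directory / f"{prefix}_{i:04d}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths
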