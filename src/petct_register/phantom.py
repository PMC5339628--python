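"""Synthetic whole-body PET/CT phantom with per-slice ground truth.

The phantom emulates the structure the pipeline relies on: head and trunk
slices whose body cross-section is a single connected region (a circle,
then an ellipse), leg slices with two circular regions, a scanning-bed
shadow strip below the body in CT, and low-intensity isolated background
speckle in PET.  The PET body is rendered at PET resolution through a known
per-slice affine misalignment and with a Gaussian edge profile standing in
for the scanner point-spread function, so partial-volume information lets
the upsampled PET localize the body boundary at sub-pixel precision, as
real PET does.

All intensities are rounded to integers so DICOM round-trips are exact.
Every stochastic element is driven by a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage, special

from .io_core import IntensityVolume, WindowSpec
from .registration import AffineParams, rotation_angle_2d

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom_pair",
    "write_phantom_dicom",
    "transform_errors",
]

# deterministic DICOM UID prefix for phantom series
_UID_PREFIX = "1.2.826.0.1.3680043.10.1405."

# body outline harmonics (fractions of the local radius); the odd
# harmonics break affine symmetry so the slice rotation is identifiable
_HEAD_H2 = 0.10
_HEAD_H3 = 0.14
_TRUNK_H3 = 0.08
_TRUNK_H5 = 0.04
_TAPER = 0.04


@dataclass
class PhantomSpec:
    """Geometry, artifact, and misalignment settings of the phantom.

    Shapes scale with the CT slice size; the defaults are a desk-scale
    pair (40 slices, 128x128 CT, 32x32 PET, mirroring the 4x resolution
    ratio of clinical whole-body PET/CT).
    """

    n_slices: int = 40
    ct_shape: tuple[int, int] = (128, 128)
    pet_shape: tuple[int, int] = (32, 32)
    head_frac: float = 0.2
    leg_frac: float = 0.7
    bed_area_px: int = 100  # CT bed-shadow pixel count (at least)
    speckle_count: int = 8  # isolated PET noise pixels per slice
    speckle_max_intensity: float = 30.0
    max_rotation_deg: float = 10.0
    max_translation_px: float = 8.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0
    # rendering constants (fractions of the CT slice size)
    body_intensity: float = 200.0
    bed_intensity: float = 90.0
    pet_psf_sigma_px: float = 2.0  # Gaussian edge width, CT pixels

    def __post_init__(self) -> None:
        if self.leg_frac <= self.head_frac:
            raise ValueError("leg_frac must exceed head_frac")
        cr, cc = self.ct_shape
        pr, pc = self.pet_shape
        if cr % pr or cc % pc:
            raise ValueError("pet_shape must divide ct_shape by an integer factor")
        if self.n_slices < 4:
            raise ValueError("need at least 4 slices")

    # ---- derived geometry -------------------------------------------------
    @property
    def factor(self) -> int:
        return self.ct_shape[0] // self.pet_shape[0]

    @property
    def center(self) -> tuple[float, float]:
        return (self.ct_shape[1] / 2.0, self.ct_shape[0] * 0.47)

    @property
    def head_radius(self) -> float:
        return 0.133 * self.ct_shape[1]

    @property
    def trunk_axes(self) -> tuple[float, float]:
        return (0.30 * self.ct_shape[1], 0.235 * self.ct_shape[0])

    @property
    def leg_radius(self) -> float:
        return 0.133 * self.ct_shape[1]

    @property
    def leg_offset(self) -> float:
        return 0.1875 * self.ct_shape[1]

    def region_of(self, z: int) -> str:
        frac = z / self.n_slices
        if frac < self.head_frac:
            return "head"
        if frac > self.leg_frac:
            return "legs"
        return "trunk"

    def validate_geometry(self) -> None:
        cx, cy = self.center
        w = self.ct_shape[1]
        h = self.ct_shape[0]
        smax = self.scale_range[1]
        margin = self.max_translation_px + 3.0 * self.pet_psf_sigma_px
        # worst-case radial excursion of the harmonic outlines (+ taper)
        head_factor = 1.0 + _HEAD_H2 + _HEAD_H3
        trunk_factor = (1.0 + _TRUNK_H3 + _TRUNK_H5) * (1.0 + _TAPER)
        half_x = max(self.trunk_axes[0] * trunk_factor,
                     self.leg_offset + self.leg_radius) * smax + margin
        half_y = max(self.trunk_axes[1] * trunk_factor,
                     self.head_radius * head_factor,
                     self.leg_radius) * smax + margin
        bed_bottom = cy + self.trunk_axes[1] + 8 + 4
        if (half_x > min(cx, w - cx) or half_y > min(cy, h - cy)
                or bed_bottom > h):
            raise ValueError("spec out of bounds: body or bed exceeds the frame")


@dataclass
class PhantomGroundTruth:
    """Per-slice true misalignments, artifact masks and region counts."""

    transforms: list[AffineParams]
    bed_mask: list[np.ndarray]  # CT-res bool, per slice
    body_mask_ct: list[np.ndarray]  # CT-res bool body silhouette, per slice
    speckle_mask_pet: list[np.ndarray]  # PET-res bool, per slice
    pet_support_mask_ct: list[np.ndarray]  # CT-res bool: ideal denoised PET support
    true_counts: list[int]
    m1: int
    m2: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "m1": self.m1,
                "m2": self.m2,
                "true_counts": self.true_counts,
                "transforms": [t.to_dict() for t in self.transforms],
            },
            indent=1,
        )

    @staticmethod
    def transforms_from_json(text: str) -> list[AffineParams]:
        return [AffineParams.from_dict(d) for d in json.loads(text)["transforms"]]


# ---------------------------------------------------------------------------
# analytic body model


def _body_fields(spec: PhantomSpec, z: int, x: np.ndarray, y: np.ndarray):
    """Signed distance (CT px, radial) and normalized radius of the body.

    Head and trunk cross-sections are star-shaped polar curves with mild
    low-order harmonics.  The asymmetric (3rd-harmonic) term matters: a
    perfect ellipse is mapped onto itself by a one-parameter family of
    affines (the 2nd harmonic is affinely absorbable), which would make
    the true rotation unidentifiable from the contours.  Its amplitude is
    sized to a few pixels — several times the boundary-extraction noise —
    so the rotation is recoverable in principle at every slice.  Real body
    outlines are not affinely symmetric either.
    """
    cx, cy = spec.center
    region = spec.region_of(z)
    if region == "legs":
        r = spec.leg_radius
        d1 = np.hypot(x - (cx - spec.leg_offset), y - cy) - r
        d2 = np.hypot(x - (cx + spec.leg_offset), y - cy) - r
        d = np.minimum(d1, d2)
        rho = 1.0 + d / r
        return d, rho
    dx, dy = x - cx, y - cy
    r_pix = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    if region == "head":
        r0 = spec.head_radius
        radius = r0 * (1.0 + _HEAD_H2 * np.cos(2.0 * phi + 0.4)
                       + _HEAD_H3 * np.cos(3.0 * phi))
    else:
        a, b = spec.trunk_axes
        taper = 1.0 + _TAPER * math.sin(2.0 * math.pi * z / spec.n_slices)
        a, b = a * taper, b * taper
        ell = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        radius = ell * (1.0 + _TRUNK_H3 * np.cos(3.0 * phi)
                        + _TRUNK_H5 * np.sin(5.0 * phi))
    d = r_pix - radius
    rho = r_pix / radius
    return d, rho


def _pet_intensity(spec: PhantomSpec, d: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Smooth interior emission times the Gaussian-blurred silhouette."""
    base = spec.body_intensity - 40.0 * np.clip(rho, 0.0, 1.0) ** 2
    edge = special.ndtr(-d / spec.pet_psf_sigma_px)  # Phi(-d / sigma)
    return base * edge


def _smooth_series(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """A smooth sinusoid over z with random amplitude (0.5-1x) and phase."""
    amp = amplitude * rng.uniform(0.5, 1.0)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    cycles = rng.uniform(0.5, 1.5)
    return amp * np.sin(2.0 * math.pi * cycles * np.arange(n) / n + phase)


def generate_phantom_pair(
    spec: PhantomSpec | None = None,
) -> tuple[IntensityVolume, IntensityVolume, PhantomGroundTruth]:
    """Generate a misaligned CT/PET pair plus ground truth."""
    spec = spec or PhantomSpec()
    spec.validate_geometry()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_slices
    h, w = spec.ct_shape
    ph, pw = spec.pet_shape
    f = spec.factor
    cx, cy = spec.center

    # smooth per-slice misalignment curves
    theta = np.deg2rad(_smooth_series(rng, n, spec.max_rotation_deg))
    tx = _smooth_series(rng, n, spec.max_translation_px)
    ty = _smooth_series(rng, n, spec.max_translation_px)
    half_span = (spec.scale_range[1] - spec.scale_range[0]) / 2.0
    mid = (spec.scale_range[1] + spec.scale_range[0]) / 2.0
    sx = mid + _smooth_series(rng, n, half_span)
    sy = mid + _smooth_series(rng, n, half_span)

    # pixel-center grids
    yy_ct, xx_ct = np.mgrid[0:h, 0:w].astype(np.float64)
    yy_pet, xx_pet = np.mgrid[0:ph, 0:pw].astype(np.float64)
    xx_pet_ct = xx_pet * f + (f - 1) / 2.0  # PET pixel centers in CT coords
    yy_pet_ct = yy_pet * f + (f - 1) / 2.0

    # bed strip geometry (4 rows tall, below the trunk, CT only)
    bed_rows = 4
    bed_cols = int(math.ceil(spec.bed_area_px / bed_rows))
    bed_r0 = int(round(cy + spec.trunk_axes[1] + 8))
    bed_c0 = int(round(cx - bed_cols / 2.0))

    ct_slices, pet_slices = [], []
    transforms, bed_masks, body_masks = [], [], []
    speckle_masks, support_fields, true_counts = [], [], []

    for z in range(n):
        # ---- CT: canonical body + bed shadow
        d_ct, rho_ct = _body_fields(spec, z, xx_ct, yy_ct)
        body = d_ct < 0.0
        ct = np.zeros((h, w))
        ct[body] = (spec.body_intensity - 40.0 * np.clip(rho_ct[body], 0, 1) ** 2)
        bed = np.zeros((h, w), dtype=bool)
        bed[bed_r0:bed_r0 + bed_rows, bed_c0:bed_c0 + bed_cols] = True
        bed &= ~body
        ct[bed] = spec.bed_intensity
        ct = np.floor(ct + 0.5)
        ct_slices.append(ct)
        bed_masks.append(bed)
        body_masks.append(body)
        true_counts.append(2 if spec.region_of(z) == "legs" else 1)

        # ---- true misalignment: p_pet = M (p - C) + T + C
        c, s = math.cos(theta[z]), math.sin(theta[z])
        m2 = np.array([[c * sx[z], -s * sy[z]], [s * sx[z], c * sy[z]]])
        m3 = np.eye(3)
        m3[:2, :2] = m2
        t3 = np.array([tx[z], ty[z], 0.0])
        params = AffineParams(m=m3, center=np.array([cx, cy, 0.0]), translation=t3)
        transforms.append(params)

        # ---- PET: canonical field sampled through the inverse misalignment
        mi = np.linalg.inv(m2)

        def canonical_intensity(px: np.ndarray, py: np.ndarray) -> np.ndarray:
            qx = mi[0, 0] * (px - cx - tx[z]) + mi[0, 1] * (py - cy - ty[z]) + cx
            qy = mi[1, 0] * (px - cx - tx[z]) + mi[1, 1] * (py - cy - ty[z]) + cy
            d, rho = _body_fields(spec, z, qx, qy)
            return _pet_intensity(spec, d, rho)

        pet = canonical_intensity(xx_pet_ct, yy_pet_ct)

        # isolated background speckle, well clear of the body's blur tail
        elig = pet < 0.01
        elig = ndimage.binary_erosion(elig, structure=np.ones((5, 5)), border_value=0)
        elig[:2, :] = elig[-2:, :] = False
        elig[:, :2] = elig[:, -2:] = False
        speckle = np.zeros((ph, pw), dtype=bool)
        cand = np.flatnonzero(elig)
        rng.shuffle(cand)
        placed: list[tuple[int, int]] = []
        for flat in cand:
            if len(placed) >= spec.speckle_count:
                break
            r, cidx = divmod(int(flat), pw)
            if all(max(abs(r - pr_), abs(cidx - pc_)) >= 3 for pr_, pc_ in placed):
                placed.append((r, cidx))
                speckle[r, cidx] = True
                pet[r, cidx] = rng.uniform(4.0, spec.speckle_max_intensity)
        pet = np.floor(pet + 0.5)
        pet_slices.append(pet)
        speckle_masks.append(speckle)

        # ideal denoised PET support at CT resolution (threshold applied below)
        support_fields.append(canonical_intensity(xx_ct, yy_ct))

    pet_volume = np.stack(pet_slices)
    # the pipeline's fallback PET window maps [min, max] onto [0, 255]; the
    # default denoising threshold of 2 gray levels above the background peak
    # then corresponds to this raw intensity:
    vmin, vmax = float(pet_volume.min()), float(pet_volume.max())
    raw_threshold = vmin + 2.0 * (vmax - vmin) / 255.0
    support_masks = [fld > raw_threshold for fld in support_fields]

    m1 = true_counts.index(1)
    m2_ = len(true_counts) - 1 - true_counts[::-1].index(1)

    ct_vol = IntensityVolume(
        slices=ct_slices, pixel_spacing=(1.0, 1.0), slice_thickness=1.0,
        modality="CT", window=WindowSpec(127.5, 255.0),
    )
    pet_vol = IntensityVolume(
        slices=pet_slices, pixel_spacing=(float(f), float(f)), slice_thickness=1.0,
        modality="PET", window=None,
    )
    truth = PhantomGroundTruth(
        transforms=transforms, bed_mask=bed_masks, body_mask_ct=body_masks,
        speckle_mask_pet=speckle_masks, pet_support_mask_ct=support_masks,
        true_counts=true_counts, m1=m1, m2=m2_, seed=spec.seed,
    )
    return ct_vol, pet_vol, truth


# ---------------------------------------------------------------------------
# ground-truth comparison


def transform_errors(
    recovered: list[AffineParams],
    truth: list[AffineParams],
    eval_point: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice translation (px) and rotation (deg) error of the recovery.

    Composes each recovered transform with the true misalignment; a perfect
    recovery gives the identity.  The translation error is the residual
    displacement of the body center, the rotation error the angle of the
    composition's orthogonal factor.
    """
    if len(recovered) != len(truth):
        raise ValueError("sequences not in correspondence")
    t_err, r_err = [], []
    for rec, tru in zip(recovered, truth):
        comp = rec.compose(tru)
        point = np.array([*(eval_point or tru.center[:2]), 0.0])
        disp = comp.apply(point) - point
        t_err.append(float(np.hypot(disp[0], disp[1])))
        r_err.append(abs(math.degrees(rotation_angle_2d(comp.m[:2, :2]))))
    return np.array(t_err), np.array(r_err)


# ---------------------------------------------------------------------------
# DICOM export


def _write_series(vol: IntensityVolume, directory: Path, modality: str,
                  series_uid: str, window: WindowSpec | None) -> list[Path]:
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    sop_class = "1.2.840.10008.5.1.4.1.1.2" if modality == "CT" else "1.2.840.10008.5.1.4.1.1.128"
    for i, s in enumerate(vol.slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = sop_class
        meta.MediaStorageSOPInstanceUID = f"{series_uid}.{i + 1}"
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = sop_class
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = series_uid.rsplit(".", 1)[0]
        ds.Modality = "CT" if modality == "CT" else "PT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * vol.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.pixel_spacing[1], vol.pixel_spacing[0]]
        ds.SliceThickness = vol.slice_thickness
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = s.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        if window is not None:
            ds.WindowCenter = window.wc
            ds.WindowWidth = window.ww
        ds.PixelData = np.ascontiguousarray(s.astype(np.uint16)).tobytes()
        p = directory / f"{modality.lower()}_{i:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


def write_phantom_dicom(
    ct: IntensityVolume, pet: IntensityVolume, truth: PhantomGroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the pair as two DICOM series plus a ground-truth JSON sidecar."""
    directory = Path(directory)
    ct_dir = directory / "ct"
    pet_dir = directory / "pet"
    _write_series(ct, ct_dir, "CT", _UID_PREFIX + f"{truth.seed}.1", ct.window)
    _write_series(pet, pet_dir, "PET", _UID_PREFIX + f"{truth.seed}.2", pet.window)
    truth_path = directory / "truth.json"
    truth_path.write_text(truth.to_json())
    return {"ct": ct_dir, "pet": pet_dir, "truth": truth_path}
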