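"""End-to-end registration pipeline.

Order of stages: normalization; GFS on CT; B-spline upsampling, median
filtering and DTD on PET; trunk-slice extraction; per-slice contour cloud
extraction and downsampling; multithread affine ICP; resampling of the
moving volume; NC/ED metrics plus checkerboard/subtraction diagnostics.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io_core
from .ct_preprocess import SelectionPolicy, gfs_segment
from .evaluation import (
    checkerboard_composite,
    euclidean_distance_error,
    negative_normalized_correlation,
    orthogonal_sections,
    stack_binary,
    subtraction_volume,
)
from .feature_cloud import (
    DownsampleSpec,
    PointCloud,
    build_point_cloud_sequences,
    downsample_cloud,
)
from .io_core import IntensityVolume
from .pet_preprocess import RegionOffsets, bspline_upsample, dtd_segment, median_filter
from .registration import ICPOptions, RegistrationResult, register_sequence, resample_moving

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_pipeline_volumes"]

log = logging.getLogger("petct_register")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@contextmanager
def _stage(name: str, timings: dict):
    t0 = time.perf_counter()
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc
    finally:
        timings[name] = round(time.perf_counter() - t0, 4)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with the published defaults."""

    ct_dir: str | None = None
    pet_dir: str | None = None
    out_dir: str | None = None
    selection: SelectionPolicy = field(default_factory=SelectionPolicy)
    offsets: RegionOffsets = field(default_factory=RegionOffsets)
    median_kernel: int = 3
    downsample: DownsampleSpec = field(default_factory=DownsampleSpec)
    icp: ICPOptions = field(default_factory=ICPOptions)
    connectivity: int = 8
    metrics_full_volume: bool = False
    ed_symmetric: bool = False
    checkerboard_blocks: int = 8
    write_pngs: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "selection" in d:
            d["selection"] = SelectionPolicy(**d["selection"])
        if "offsets" in d:
            d["offsets"] = RegionOffsets(**d["offsets"])
        if "downsample" in d:
            d["downsample"] = DownsampleSpec(**d["downsample"])
        if "icp" in d:
            d["icp"] = ICPOptions(**d["icp"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from DICOM directories; returns the run report."""
    timings: dict = {}
    with _stage("input", timings):
        if not config.ct_dir or not Path(config.ct_dir).is_dir():
            raise FileNotFoundError(f"CT directory not found: {config.ct_dir}")
        if not config.pet_dir or not Path(config.pet_dir).is_dir():
            raise FileNotFoundError(f"PET directory not found: {config.pet_dir}")
        ct = io_core.read_dicom_series(config.ct_dir)
        pet = io_core.read_dicom_series(config.pet_dir)
        log.info("read CT %s slices %sx%s, PET %s slices %sx%s",
                 ct.n_slices, *ct.slice_shape, pet.n_slices, *pet.slice_shape)
    report = run_pipeline_volumes(ct, pet, config, timings=timings)
    return report


def run_pipeline_volumes(
    ct: IntensityVolume,
    pet: IntensityVolume,
    config: PipelineConfig | None = None,
    timings: dict | None = None,
) -> dict:
    """Run the pipeline on in-memory volumes (the DICOM-free entry point)."""
    config = config or PipelineConfig()
    timings = {} if timings is None else timings
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if ct.n_slices != pet.n_slices:
        raise PipelineError("[input] sequences not in correspondence: "
                            f"{ct.n_slices} CT vs {pet.n_slices} PET slices")
    n = ct.n_slices
    ct_shape = ct.slice_shape

    with _stage("normalize", timings):
        ct_norm = io_core.normalize_intensity(ct)
        pet_norm = io_core.normalize_intensity(pet)

    with _stage("ct_gfs", timings):
        ct_seg, ct_feat = [], []
        for i, s in enumerate(ct_norm.slices):
            seg, feat = gfs_segment(s, i, n, config.selection)
            ct_seg.append(seg)
            ct_feat.append(feat)
        log.info("GFS done: %d slices", n)

    with _stage("pet_preprocess", timings):
        pet_seg, pet_feat = [], []
        for i, s in enumerate(pet_norm.slices):
            up = bspline_upsample(s, ct_shape)
            med = median_filter(up, config.median_kernel)
            seg, feat = dtd_segment(med, i, n, config.selection, config.offsets)
            pet_seg.append(seg)
            pet_feat.append(feat)
        log.info("PET chain done: %d slices at %sx%s", n, *ct_shape)

    with _stage("feature_clouds", timings):
        fixed, moving, trunk = build_point_cloud_sequences(
            ct_feat, pet_feat, connectivity=config.connectivity,
            out_dir=(out_dir / "clouds") if out_dir else None,
        )
        log.info("trunk range [%d, %d] (%d slices), cloud sizes %d-%d pts",
                 trunk.m1, trunk.m2, trunk.m2 - trunk.m1 + 1,
                 min(len(c) for c in fixed), max(len(c) for c in fixed))

    with _stage("downsample", timings):
        fixed_ds = [downsample_cloud(c, config.downsample) for c in fixed]
        moving_ds = [downsample_cloud(c, config.downsample) for c in moving]

    with _stage("icp", timings):
        result = register_sequence(fixed_ds, moving_ds, config.icp)
        log.info("ICP done: %d transforms, mean cost %.4f",
                 len(result.transforms), result.final_cost)

    with _stage("resample", timings):
        registered_seg = resample_moving(pet_seg, result)
        registered_feat = resample_moving(pet_feat, result, binary=True)

    with _stage("metrics", timings):
        metrics = compute_metrics(
            ct_feat, pet_feat, registered_feat, trunk,
            full_volume=config.metrics_full_volume,
            symmetric=config.ed_symmetric,
        )
        log.info("metrics: %s", metrics)

    report = {
        "trunk_range": trunk.to_dict(),
        "metrics": metrics,
        "n_slices": n,
        "cloud_points": {
            "fixed": [len(c) for c in fixed],
            "moving": [len(c) for c in moving],
            "fixed_downsampled": [len(c) for c in fixed_ds],
            "moving_downsampled": [len(c) for c in moving_ds],
        },
        "icp": {
            "final_cost": result.final_cost,
            "iterations_used": result.iterations_used,
        },
        "stage_seconds": timings,
    }

    if out_dir:
        with _stage("outputs", timings):
            _write_outputs(out_dir, config, ct, ct_seg, ct_feat, pet_feat,
                           registered_seg, registered_feat, trunk, result,
                           metrics, report)
    report["result"] = result
    return report


def compute_metrics(ct_feat, pet_feat, registered_feat, trunk,
                    full_volume: bool = False, symmetric: bool = False) -> dict:
    """NC and ED before/after registration on binary feature volumes.

    By default the metrics cover the trunk-range sub-volume only (the
    region ICP actually registers); ``full_volume=True`` includes every
    slice.  ED is directed from the (registered) PET feature points to the
    CT feature points.
    """
    lo, hi = (0, len(ct_feat) - 1) if full_volume else (trunk.m1, trunk.m2)
    a_ct = stack_binary(ct_feat[lo:hi + 1])
    b_before = stack_binary(pet_feat[lo:hi + 1])
    b_after = stack_binary(registered_feat[lo:hi + 1])

    def points(vol):
        z, y, x = np.nonzero(_boundary3d(vol))
        return np.stack([x, y, z + lo], axis=1).astype(np.float64)

    ct_pts = points(a_ct)
    metrics = {
        "nc_before": negative_normalized_correlation(a_ct, b_before),
        "nc_after": negative_normalized_correlation(a_ct, b_after),
        "ed_before": euclidean_distance_error(points(b_before), ct_pts, symmetric),
        "ed_after": euclidean_distance_error(points(b_after), ct_pts, symmetric),
    }
    return {k: round(float(v), 6) for k, v in metrics.items()}


def _boundary3d(vol: np.ndarray) -> np.ndarray:
    """Per-slice boundary voxels (4-neighbor test within each slice)."""
    from scipy import ndimage
    fg = vol > 0
    structure = np.zeros((1, 3, 3), dtype=int)
    structure[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    return fg & ~interior


def _write_outputs(out_dir, config, ct, ct_seg, ct_feat, pet_feat,
                   registered_seg, registered_feat, trunk, result,
                   metrics, report) -> None:
    io_core.write_volume(np.stack(registered_seg), out_dir / "registered_pet.mha",
                         pixel_spacing=ct.pixel_spacing,
                         slice_thickness=ct.slice_thickness)
    (out_dir / "transforms.json").write_text(
        json.dumps(result.to_dict(), indent=1, sort_keys=True) + "\n")
    (out_dir / "metrics.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True) + "\n")
    (out_dir / "report.json").write_text(
        json.dumps({k: v for k, v in report.items() if k != "result"},
                   indent=1, sort_keys=True) + "\n")
    if config.write_pngs:
        mid = (trunk.m1 + trunk.m2) // 2
        io_core.write_png_slices(
            [checkerboard_composite(ct_feat[mid], pet_feat[mid],
                                    config.checkerboard_blocks),
             checkerboard_composite(ct_feat[mid], registered_feat[mid],
                                    config.checkerboard_blocks)],
            out_dir / "diagnostics", prefix="checkerboard")
        a = stack_binary(ct_feat[trunk.m1:trunk.m2 + 1])
        for tag, feats in (("before", pet_feat), ("after", registered_feat)):
            diff = subtraction_volume(a, stack_binary(feats[trunk.m1:trunk.m2 + 1]))
            secs = orthogonal_sections(diff)
            io_core.write_png_slices(
                [(s + 1.0) * 127.5 for s in secs.values()],
                out_dir / "diagnostics", prefix=f"subtraction_{tag}")
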