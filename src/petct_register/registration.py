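"""Affine ICP on contour point clouds.

The transform model is ``p' = M (p - C) + T + C`` with a full matrix M
(rotation, anisotropic scaling, shear), rotation center C and translation
T.  ICP alternates nearest-neighbor correspondence search with a
Levenberg-Marquardt minimization of the summed squared Euclidean
correspondence distances over (M, T), C staying fixed at the fixed cloud's
centroid.  Slice sequences are registered per slice by default, the slices
split into contiguous groups processed on worker threads; results are
independent of the thread count.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .feature_cloud import PointCloud

__all__ = [
    "AffineParams",
    "ICPOptions",
    "RegistrationResult",
    "apply_affine",
    "icp_register",
    "register_sequence",
    "resample_moving",
    "rotation_angle_2d",
]


@dataclass
class AffineParams:
    """Affine transform ``p' = M (p - C) + T + C``."""

    m: np.ndarray  # (3, 3)
    center: np.ndarray  # (3,)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.float64).reshape(3, 3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls, center: Sequence[float] = (0.0, 0.0, 0.0)) -> "AffineParams":
        return cls(m=np.eye(3), center=np.asarray(center, float), translation=np.zeros(3))

    def linear_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent plain form ``p' = M p + b`` with ``b = T + C - M C``."""
        b = self.translation + self.center - self.m @ self.center
        return self.m.copy(), b

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        out = (pts - self.center) @ self.m.T + self.translation + self.center
        return out[0] if single else out

    def compose(self, inner: "AffineParams") -> "AffineParams":
        """Transform applying ``inner`` first, then ``self``."""
        m1, b1 = inner.linear_offset()
        m2, b2 = self.linear_offset()
        m = m2 @ m1
        b = m2 @ b1 + b2
        return AffineParams(m=m, center=np.zeros(3), translation=b)

    def to_dict(self) -> dict:
        return {
            "m": self.m.tolist(),
            "center": self.center.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineParams":
        return cls(m=np.array(d["m"]), center=np.array(d["center"]),
                   translation=np.array(d["translation"]))


def apply_affine(point: Sequence[float], params: AffineParams) -> np.ndarray:
    """Apply ``p' = M (p - C) + T + C`` to a single (x, y, z) point."""
    return params.apply(np.asarray(point, dtype=np.float64))


def rotation_angle_2d(m: np.ndarray) -> float:
    """Rotation angle (radians) of the orthogonal factor of a 2x2 matrix.

    Polar decomposition M = R S via SVD; returns the angle of R.
    """
    m = np.asarray(m, dtype=np.float64).reshape(2, 2)
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:  # reflection: flip the smaller singular direction
        u[:, -1] *= -1
        r = u @ vt
    return float(np.arctan2(r[1, 0], r[0, 0]))


@dataclass
class ICPOptions:
    """ICP settings.

    ``rotation_starts`` lists initial in-plane rotations (degrees) tried in
    order; the run with the lowest final cost wins (ties: earlier start).
    ICP's basin of attraction for rotation is narrow on near-symmetric body
    outlines, so a small deterministic multi-start makes recovery robust
    across the plausible patient-positioning range.
    """

    max_iterations: int = 50
    param_tolerance: float = 1e-6
    cost_tolerance: float = 1e-8
    n_threads: int = 4
    mode: Literal["per_slice", "global"] = "per_slice"
    correspondence: Literal["moving-to-fixed", "fixed-to-moving"] = "moving-to-fixed"
    rotation_starts: tuple[float, ...] = (0.0, -4.0, 4.0, -8.0, 8.0, -12.0, 12.0)
    #: "point-to-contour" measures the Euclidean distance to the polyline
    #: through consecutive fixed points (clouds are stored in outline
    #: order), removing the pixel-sampling ruggedness of the cost surface;
    #: "point-to-point" uses the nearest sample itself.
    matching: Literal["point-to-contour", "point-to-point"] = "point-to-contour"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.param_tolerance <= 0 or self.cost_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.n_threads < 1:
            raise ValueError("n_threads must be >= 1")


@dataclass
class RegistrationResult:
    """Per-slice (or single global) transforms plus convergence info."""

    transforms: list[AffineParams]
    slice_ids: list[int]
    final_cost: float
    iterations_used: int
    per_slice_cost: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "slice_ids": self.slice_ids,
            "transforms": [t.to_dict() for t in self.transforms],
            "final_cost": self.final_cost,
            "iterations_used": self.iterations_used,
            "per_slice_cost": self.per_slice_cost,
        }


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core


def _lm_solve(pts: np.ndarray, targets: np.ndarray, center: np.ndarray,
              theta0: np.ndarray, dims: int,
              max_inner: int = 25, gtol: float = 1e-12) -> np.ndarray:
    """LM minimization of sum ||M (p - C) + T + C - q||^2 over (M, T).

    ``theta`` packs the dims*dims entries of M (row-major) followed by the
    dims entries of T.  Damping starts at 1e-3, grows x10 on a rejected
    step and shrinks x0.1 on an accepted one.  The residual is linear in
    theta, so this converges in very few steps; the schedule matters only
    for conditioning.
    """
    q = pts - center  # (n, dims)
    n = len(q)
    jac = np.zeros((n * dims, dims * dims + dims))
    for a in range(dims):
        jac[a::dims, a * dims:(a + 1) * dims] = q
        jac[a::dims, dims * dims + a] = 1.0

    def residual(theta: np.ndarray) -> np.ndarray:
        m = theta[: dims * dims].reshape(dims, dims)
        t = theta[dims * dims:]
        return (q @ m.T + t + center - targets).ravel()

    theta = theta0.copy()
    r = residual(theta)
    cost = float(r @ r)
    lam = 1e-3
    jtj = jac.T @ jac
    diag = np.diag(np.diag(jtj))
    for _ in range(max_inner):
        g = jac.T @ r
        if np.abs(g).max() < gtol:
            break
        try:
            step = np.linalg.solve(jtj + lam * diag, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(jtj + lam * diag, -g, rcond=None)[0]
        cand = theta + step
        r_cand = residual(cand)
        cost_cand = float(r_cand @ r_cand)
        if cost_cand < cost:
            theta, r, cost = cand, r_cand, cost_cand
            lam = max(lam * 0.1, 1e-12)
            if np.abs(step).max() < 1e-14:
                break
        else:
            lam *= 10.0
            if lam > 1e12:
                break
    return theta


def _pack_identity(dims: int, t0: np.ndarray) -> np.ndarray:
    theta = np.zeros(dims * dims + dims)
    theta[: dims * dims] = np.eye(dims).ravel()
    theta[dims * dims:] = t0
    return theta


def _theta_to_params(theta: np.ndarray, center3: np.ndarray, dims: int) -> AffineParams:
    m3 = np.eye(3)
    t3 = np.zeros(3)
    m3[:dims, :dims] = theta[: dims * dims].reshape(dims, dims)
    t3[:dims] = theta[dims * dims:]
    return AffineParams(m=m3, center=center3, translation=t3)


def icp_register(fixed: PointCloud, moving: PointCloud,
                 opts: ICPOptions | None = None, dims: int = 2) -> tuple[AffineParams, float, int]:
    """Affine ICP of one moving cloud onto one fixed cloud.

    Returns (params, final_cost, iterations) where ``final_cost`` is the
    mean squared nearest-neighbor distance under the final transform.  With
    ``dims=2`` the z row/column of M stay identity and Tz = 0 (per-slice
    registration); ``dims=3`` fits the full 3D affine.

    The correspondence direction defaults to nearest *fixed* neighbor for
    every transformed moving point; ``opts.correspondence`` selects the
    converse pairing instead.
    """
    opts = opts or ICPOptions()
    fpts = fixed.points[:, :dims]
    mpts = moving.points[:, :dims]
    if len(fpts) == 0 or len(mpts) == 0:
        raise ValueError("empty point cloud")

    center = fpts.mean(axis=0)
    centered = mpts - mpts.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9) if len(mpts) > 1 else 0
    translation_only = rank < dims
    if translation_only:
        warnings.warn(
            "rank-deficient configuration: moving cloud is degenerate; "
            "solving translation-only model",
            stacklevel=2,
        )

    tree = cKDTree(fpts)
    cm = mpts.mean(axis=0)
    nf = len(fpts)

    # polyline segments fpts[j] -> fpts[(j+1) % nf] in outline order; very
    # long segments (component junctions, wrap-around of open chains) are
    # excluded via an adaptive length cutoff
    use_segments = (
        opts.matching == "point-to-contour"
        and opts.correspondence == "moving-to-fixed"
        and nf >= 3
    )
    if use_segments:
        seg_a = fpts
        seg_b = fpts[(np.arange(nf) + 1) % nf]
        seg_v = seg_b - seg_a
        seg_len2 = (seg_v ** 2).sum(axis=1)
        lengths = np.sqrt(seg_len2)
        cutoff = 4.0 * max(float(np.median(lengths)), 1.0)
        seg_ok = (lengths <= cutoff) & (seg_len2 > 0)

    def nn_cost(theta: np.ndarray):
        m = theta[: dims * dims].reshape(dims, dims)
        t = theta[dims * dims:]
        transformed = (mpts - center) @ m.T + t + center
        if opts.correspondence != "moving-to-fixed":
            dist, idx = cKDTree(transformed).query(fpts)
            return float(np.mean(dist ** 2)), mpts[idx], fpts
        dist, idx = tree.query(transformed)
        targets = fpts[idx].copy()
        if not use_segments:
            return float(np.mean(dist ** 2)), mpts, targets
        best_d2 = dist ** 2
        for off in (-1, 0):  # the two outline segments meeting at the NN
            j = (idx + off) % nf
            a, v = seg_a[j], seg_v[j]
            tpar = np.clip(
                ((transformed - a) * v).sum(axis=1)
                / np.maximum(seg_len2[j], 1e-12),
                0.0, 1.0,
            )
            proj = a + tpar[:, None] * v
            d2 = ((transformed - proj) ** 2).sum(axis=1)
            upd = seg_ok[j] & (d2 < best_d2)
            targets[upd] = proj[upd]
            best_d2[upd] = d2[upd]
        return float(np.mean(best_d2)), mpts, targets

    def run_from(theta: np.ndarray) -> tuple[np.ndarray, float, int]:
        prev_cost = np.inf
        best_theta, best_cost = theta, np.inf
        iters = 0
        for iters in range(1, opts.max_iterations + 1):
            cost, src, targets = nn_cost(theta)
            if cost < best_cost:
                best_theta, best_cost = theta, cost
            # with point-to-point matching the LS solve and the fresh NN
            # search each only lower the cost; with point-to-contour the
            # candidate segment set changes with the NN sample, so a small
            # increase signals convergence rather than a bug
            if not use_segments:
                assert cost <= prev_cost + 1e-9 * (1.0 + min(prev_cost, 1e12)), \
                    "ICP cost increased"
            if cost >= prev_cost - opts.cost_tolerance:
                break
            if translation_only:
                m = theta[: dims * dims].reshape(dims, dims)
                delta = (targets - ((src - center) @ m.T + center)).mean(axis=0)
                theta_new = theta.copy()
                theta_new[dims * dims:] = delta
            else:
                theta_new = _lm_solve(src, targets, center, theta, dims)
            if np.abs(theta_new - theta).max() < opts.param_tolerance:
                theta = theta_new
                prev_cost = cost
                break
            theta = theta_new
            prev_cost = cost
        final_cost = nn_cost(theta)[0]  # cost under the final parameters
        if final_cost <= best_cost:
            return theta, final_cost, iters
        return best_theta, best_cost, iters

    best: tuple[np.ndarray, float, int] | None = None
    for angle_deg in (opts.rotation_starts or (0.0,)):
        a = np.deg2rad(angle_deg)
        m0 = np.eye(dims)
        m0[:2, :2] = [[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]
        theta0 = np.zeros(dims * dims + dims)
        theta0[: dims * dims] = m0.ravel()
        # start with the rotated moving centroid aligned to the fixed one
        theta0[dims * dims:] = fpts.mean(axis=0) - ((cm - center) @ m0.T + center)
        candidate = run_from(theta0)
        if best is None or candidate[1] < best[1]:
            best = candidate
        if translation_only:
            break  # rotation starts are meaningless for a degenerate cloud
    theta, cost, iters = best

    center3 = np.zeros(3)
    center3[:dims] = center
    if dims == 2 and len(fixed.points):
        center3[2] = float(fixed.points[0, 2])
    params = _theta_to_params(theta, center3, dims)
    return params, cost, iters


def _split_groups(n: int, k: int) -> list[range]:
    """Split range(n) into at most k contiguous, near-equal groups."""
    k = min(k, n) if n else 0
    bounds = np.linspace(0, n, k + 1).astype(int)
    return [range(bounds[i], bounds[i + 1]) for i in range(k)]


def register_sequence(
    fixed_clouds: Sequence[PointCloud],
    moving_clouds: Sequence[PointCloud],
    opts: ICPOptions | None = None,
    slice_ids: Sequence[int] | None = None,
) -> RegistrationResult:
    """Register per-slice cloud sequences (or one global 3D affine).

    In ``per_slice`` mode each slice gets its own 2D-constrained affine;
    slices are partitioned into ``n_threads`` contiguous groups executed on
    a thread pool.  Slices are mutually independent, so the result is
    bit-identical for any thread count.  In ``global`` mode all clouds are
    concatenated and a single 3D affine is fit.
    """
    opts = opts or ICPOptions()
    if len(fixed_clouds) != len(moving_clouds):
        raise ValueError("sequences not in correspondence")
    n = len(fixed_clouds)
    if slice_ids is None:
        slice_ids = [
            pc.source_slice if pc.source_slice is not None else i
            for i, pc in enumerate(fixed_clouds)
        ]
    slice_ids = list(slice_ids)

    if opts.mode == "global":
        fixed = PointCloud(np.vstack([pc.points for pc in fixed_clouds]))
        moving = PointCloud(np.vstack([pc.points for pc in moving_clouds]))
        params, cost, iters = icp_register(fixed, moving, opts, dims=3)
        return RegistrationResult(
            transforms=[params], slice_ids=slice_ids, final_cost=cost,
            iterations_used=iters, per_slice_cost=[cost],
        )

    results: list[tuple[AffineParams, float, int] | None] = [None] * n

    def work(indices: range) -> None:
        for i in indices:
            results[i] = icp_register(fixed_clouds[i], moving_clouds[i], opts, dims=2)

    groups = _split_groups(n, opts.n_threads)
    if len(groups) <= 1:
        for g in groups:
            work(g)
    else:
        with ThreadPoolExecutor(max_workers=len(groups)) as pool:
            list(pool.map(work, groups))

    transforms = [r[0] for r in results]
    costs = [r[1] for r in results]
    iters = max(r[2] for r in results) if results else 0
    return RegistrationResult(
        transforms=transforms, slice_ids=slice_ids,
        final_cost=float(np.mean(costs)), iterations_used=iters,
        per_slice_cost=costs,
    )


def resample_moving(
    slices: Sequence[np.ndarray],
    result: RegistrationResult,
    binary: bool = False,
) -> list[np.ndarray]:
    """Warp moving slices onto the fixed grid with the recovered transforms.

    Each registered slice is inverse-warped with bilinear interpolation
    (out-of-field pixels 0); slices outside the trunk range pass through
    unchanged.  With ``binary=True`` the interpolated result is
    re-binarized at 127.5 (for {0,255} feature images).
    """
    out = [np.asarray(s, dtype=np.float64).copy() for s in slices]
    by_slice = dict(zip(result.slice_ids, result.transforms))
    if len(result.transforms) == 1 and len(result.slice_ids) > 1:
        by_slice = {sid: result.transforms[0] for sid in result.slice_ids}
    for sid, params in by_slice.items():
        m2 = params.m[:2, :2]
        det = np.linalg.det(m2)
        if abs(det) < 1e-12:
            raise ValueError("non-invertible affine")
        mi = np.linalg.inv(m2)
        c = params.center[:2]
        t = params.translation[:2]
        off_xy = c - mi @ (t + c)
        # switch from (x, y) to scipy's (row, col) ordering
        matrix_rc = np.array([[mi[1, 1], mi[1, 0]], [mi[0, 1], mi[0, 0]]])
        offset_rc = np.array([off_xy[1], off_xy[0]])
        warped = ndimage.affine_transform(
            out[sid], matrix_rc, offset=offset_rc, order=1,
            mode="constant", cval=0.0,
        )
        if binary:
            warped = (warped > 127.5).astype(np.float64) * 255.0
        out[sid] = warped
    return out
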