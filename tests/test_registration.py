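"""Affine application, ICP recovery, sequence parallelism, and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petct_register import (
    AffineParams,
    ICPOptions,
    PointCloud,
    apply_affine,
    icp_register,
    register_sequence,
    resample_moving,
)
from petct_register.registration import rotation_angle_2d

from conftest import filled_disk


def star_cloud(n=80, z=0.0, seed=0):
    """A closed asymmetric outline (identifiable under affine maps)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = 20.0 * (1.0 + 0.15 * np.cos(2 * phi + 0.3) + 0.12 * np.cos(3 * phi))
    pts = np.stack([40 + r * np.cos(phi), 40 + r * np.sin(phi),
                    np.full(n, z)], axis=1)
    return PointCloud(points=pts, source_slice=int(z))


class TestApplyAffine:
    def test_identity_leaves_point_unchanged(self):
        a = AffineParams.identity(center=(5.0, 6.0, 7.0))
        np.testing.assert_array_equal(apply_affine((1, 2, 3), a), [1, 2, 3])

    def test_pure_translation(self):
        a = AffineParams(m=np.eye(3), center=np.zeros(3),
                         translation=[1.0, 2.0, 3.0])
        np.testing.assert_array_equal(apply_affine((0, 0, 0), a), [1, 2, 3])

    def test_diagonal_scaling_about_origin(self):
        a = AffineParams(m=np.diag([2.0, 2.0, 1.0]), center=np.zeros(3),
                         translation=np.zeros(3))
        np.testing.assert_array_equal(apply_affine((1, 2, 3), a), [2, 4, 3])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_center_reparameterization_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = AffineParams(m=np.eye(3) + 0.2 * rng.standard_normal((3, 3)),
                         center=rng.uniform(-10, 10, 3),
                         translation=rng.uniform(-10, 10, 3))
        m, b = a.linear_offset()
        plain = AffineParams(m=m, center=np.zeros(3), translation=b)
        p = rng.uniform(-20, 20, 3)
        np.testing.assert_allclose(apply_affine(p, a), apply_affine(p, plain),
                                   atol=1e-9)

    def test_compose_applies_inner_first(self):
        shift = AffineParams(m=np.eye(3), center=np.zeros(3),
                             translation=[1.0, 0.0, 0.0])
        scale = AffineParams(m=np.diag([2.0, 1.0, 1.0]), center=np.zeros(3),
                             translation=np.zeros(3))
        combined = scale.compose(shift)
        np.testing.assert_allclose(apply_affine((1, 1, 0), combined), [4, 1, 0])

    def test_rotation_angle_of_scaled_rotation(self):
        ang = np.deg2rad(17.0)
        r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        m = r @ np.diag([1.3, 0.8])
        assert rotation_angle_2d(m) == pytest.approx(ang, abs=1e-12)


class TestIcpRegister:
    def test_self_registration_is_identity(self):
        cloud = star_cloud()
        params, cost, _ = icp_register(cloud, cloud, ICPOptions())
        np.testing.assert_allclose(params.m[:2, :2], np.eye(2), atol=1e-6)
        np.testing.assert_allclose(params.translation[:2], 0.0, atol=1e-6)
        assert cost == pytest.approx(0.0, abs=1e-9)

    def test_translation_recovered(self):
        fixed = star_cloud()
        moving = PointCloud(points=fixed.points + [5.0, 3.0, 0.0])
        params, cost, _ = icp_register(fixed, moving, ICPOptions())
        np.testing.assert_allclose(params.translation[:2], [-5.0, -3.0],
                                   atol=1e-3)
        assert cost < 1e-3

    def test_rotation_recovered(self):
        fixed = star_cloud()
        ang = np.deg2rad(5.0)
        r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        c = fixed.points[:, :2].mean(axis=0)
        moved = fixed.points.copy()
        moved[:, :2] = (moved[:, :2] - c) @ r.T + c
        params, cost, _ = icp_register(fixed, PointCloud(points=moved),
                                       ICPOptions())
        np.testing.assert_allclose(params.m[:2, :2], r.T, atol=1e-2)
        assert cost < 1e-2

    def test_empty_cloud_rejected(self):
        empty = PointCloud(points=np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty point cloud"):
            icp_register(star_cloud(), empty, ICPOptions())

    def test_degenerate_cloud_falls_back_to_translation(self):
        line = PointCloud(
            points=np.array([[float(i), 0.0, 0.0] for i in range(10)])
        )
        target = PointCloud(points=line.points + [2.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="rank-deficient"):
            params, _, _ = icp_register(target, line, ICPOptions())
        np.testing.assert_allclose(params.m, np.eye(3), atol=1e-12)

    def test_point_to_point_matching_also_converges(self):
        fixed = star_cloud()
        moving = PointCloud(points=fixed.points + [2.0, -1.0, 0.0])
        params, cost, _ = icp_register(
            fixed, moving, ICPOptions(matching="point-to-point")
        )
        np.testing.assert_allclose(params.translation[:2], [-2.0, 1.0],
                                   atol=1e-2)


class TestRegisterSequence:
    def test_thread_count_does_not_change_results(self):
        fixed = [star_cloud(z=float(z)) for z in range(6)]
        moving = [
            PointCloud(points=f.points + [3.0, 1.0, 0.0],
                       source_slice=f.source_slice)
            for f in fixed
        ]
        results = []
        for nt in (1, 2, 4, 8):
            res = register_sequence(fixed, moving, ICPOptions(n_threads=nt))
            results.append([t.to_dict() for t in res.transforms])
        assert all(r == results[0] for r in results[1:])

    def test_one_transform_per_slice(self):
        fixed = [star_cloud(z=float(z)) for z in range(4)]
        res = register_sequence(fixed, fixed, ICPOptions())
        assert len(res.transforms) == 4
        assert res.slice_ids == [c.source_slice for c in fixed]

    def test_length_mismatch_rejected(self):
        fixed = [star_cloud()]
        with pytest.raises(ValueError, match="sequences not in correspondence"):
            register_sequence(fixed, fixed * 2, ICPOptions())


def result_for(transforms, slice_ids):
    from petct_register import RegistrationResult

    return RegistrationResult(transforms=transforms, slice_ids=slice_ids,
                              final_cost=0.0, iterations_used=1)


class TestResampleMoving:
    def test_identity_transforms_leave_volume_unchanged(self):
        vol = [filled_disk((32, 32), (16, 16), 8) * 200.0 for _ in range(3)]
        res = result_for([AffineParams.identity() for _ in range(3)], [0, 1, 2])
        out = resample_moving(vol, res)
        for a, b in zip(out, vol):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_integer_translation_shifts_columns(self):
        img = np.zeros((16, 16))
        img[6:10, 6:10] = 100.0
        # transform maps moving -> fixed as x' = x + 3 (pixels move right)
        t = AffineParams(m=np.eye(3), center=np.zeros(3),
                         translation=[3.0, 0.0, 0.0])
        out = resample_moving([img], result_for([t], [0]))
        np.testing.assert_allclose(out[0][6:10, 9:13], 100.0)
        assert not out[0][:, :9].any()

    def test_slices_outside_trunk_pass_through(self):
        vol = [np.full((8, 8), float(i)) for i in range(4)]
        t = AffineParams(m=np.eye(3), center=np.zeros(3),
                         translation=[1.0, 0.0, 0.0])
        out = resample_moving(vol, result_for([t], [2]))
        np.testing.assert_array_equal(out[0], vol[0])
        np.testing.assert_array_equal(out[3], vol[3])

    def test_singular_transform_rejected(self):
        sing = AffineParams(m=np.zeros((3, 3)), center=np.zeros(3),
                            translation=np.zeros(3))
        with pytest.raises(ValueError, match="non-invertible affine"):
            resample_moving([np.zeros((8, 8))], result_for([sing], [0]))
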