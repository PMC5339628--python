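"""Trunk range, feature points, the averaging downsampler, and PCD files."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petct_register import (
    DownsampleSpec,
    PointCloud,
    build_point_cloud_sequences,
    count_connected_regions,
    downsample_cloud,
    extract_feature_points,
    extract_trunk_range,
)
from petct_register.feature_cloud import read_pcd, write_pcd


def feature_with_regions(k):
    """A 32x32 feature image with k well-separated foreground blobs."""
    img = np.zeros((32, 32))
    for i in range(k):
        r = 4 + 8 * i
        img[r:r + 4, 4:8] = 255.0
    return img


class TestConnectedRegions:
    def test_all_zero_image_has_none(self):
        assert count_connected_regions(np.zeros((8, 8))) == 0

    def test_single_blob(self):
        assert count_connected_regions(feature_with_regions(1)) == 1

    def test_diagonal_touch_depends_on_connectivity(self):
        img = np.zeros((6, 6))
        img[1:3, 1:3] = 255.0
        img[3:5, 3:5] = 255.0  # touches only at the corner
        assert count_connected_regions(img, connectivity=8) == 1
        assert count_connected_regions(img, connectivity=4) == 2

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="not a feature image"):
            count_connected_regions(np.full((4, 4), 7.0))


class TestTrunkRange:
    def test_basic_interval(self):
        feats = [feature_with_regions(k) for k in (2, 1, 1, 1, 2)]
        tr = extract_trunk_range(feats)
        assert (tr.m1, tr.m2) == (1, 3)
        assert tr.ncr == [2, 1, 1, 1, 2]

    def test_all_single_region_spans_everything(self):
        feats = [feature_with_regions(1)] * 4
        tr = extract_trunk_range(feats)
        assert (tr.m1, tr.m2) == (0, 3)

    def test_interior_multi_region_slice_stays_inside_range(self):
        feats = [feature_with_regions(k) for k in (2, 1, 2, 1, 2)]
        tr = extract_trunk_range(feats)
        assert (tr.m1, tr.m2) == (1, 3)  # slice 2 is inside despite count 2

    def test_no_single_region_slice_is_an_error(self):
        with pytest.raises(ValueError, match="no trunk slices found"):
            extract_trunk_range([feature_with_regions(2)])

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            extract_trunk_range([])


class TestFeaturePoints:
    def test_empty_image_gives_empty_cloud(self):
        assert len(extract_feature_points(np.zeros((8, 8)))) == 0

    def test_filled_3x3_square_has_8_boundary_points(self):
        img = np.zeros((8, 8))
        img[2:5, 2:5] = 255.0
        cloud = extract_feature_points(img, slice_id=3)
        assert len(cloud) == 8  # center pixel excluded
        assert (cloud.points[:, 2] == 3.0).all()

    def test_point_count_never_exceeds_foreground(self):
        rng = np.random.default_rng(0)
        img = (rng.random((16, 16)) > 0.6) * 255.0
        cloud = extract_feature_points(img)
        assert len(cloud) <= (img > 0).sum()

    def test_each_boundary_pixel_emitted_once(self):
        img = np.zeros((16, 16))
        img[3:12, 3:12] = 255.0
        cloud = extract_feature_points(img)
        assert len(np.unique(cloud.points, axis=0)) == len(cloud)


class TestDownsampler:
    def test_alpha_1_axis_ordering_returns_sorted_cloud(self):
        pts = np.array([[3.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        out = downsample_cloud(
            PointCloud(points=pts), DownsampleSpec(alpha=1, ordering="axis")
        )
        np.testing.assert_array_equal(out.points[:, 0], [1.0, 2.0, 3.0])

    def test_alpha_1_contour_ordering_is_identity(self):
        pts = np.array([[3.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        out = downsample_cloud(PointCloud(points=pts), DownsampleSpec(alpha=1))
        np.testing.assert_array_equal(out.points, pts)

    def test_two_points_average_to_midpoint(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        out = downsample_cloud(PointCloud(points=pts), DownsampleSpec(alpha=2))
        np.testing.assert_array_equal(out.points, [[1.0, 0.0, 0.0]])

    def test_remainder_group_kept_as_its_own_point(self):
        pts = np.array([[float(i), 0, 0] for i in range(5)])
        out = downsample_cloud(
            PointCloud(points=pts), DownsampleSpec(alpha=2, ordering="axis")
        )
        assert len(out) == 3
        np.testing.assert_array_equal(out.points[2], [4.0, 0.0, 0.0])

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="invalid sample ratio"):
            DownsampleSpec(alpha=0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        n=st.integers(min_value=1, max_value=500),
        alpha=st.sampled_from([1, 2, 5, 50]),
        ordering=st.sampled_from(["contour", "axis"]),
    )
    def test_output_size_is_ceil_n_over_alpha(self, n, alpha, ordering):
        rng = np.random.default_rng(n * 13 + alpha)
        cloud = PointCloud(points=rng.uniform(-50, 50, size=(n, 3)))
        out = downsample_cloud(
            cloud, DownsampleSpec(alpha=alpha, ordering=ordering)
        )
        assert len(out) == math.ceil(n / alpha)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        groups=st.integers(min_value=1, max_value=40),
        alpha=st.sampled_from([1, 2, 5]),
        ordering=st.sampled_from(["contour", "axis"]),
    )
    def test_centroid_preserved_when_alpha_divides_n(self, groups, alpha,
                                                     ordering):
        rng = np.random.default_rng(groups * 7 + alpha)
        cloud = PointCloud(points=rng.uniform(-50, 50, size=(groups * alpha, 3)))
        out = downsample_cloud(
            cloud, DownsampleSpec(alpha=alpha, ordering=ordering)
        )
        np.testing.assert_allclose(out.centroid(), cloud.centroid(), atol=1e-9)


class TestCloudSequences:
    def test_pet_trunk_ids_equal_ct_trunk_ids(self, ct_features, pet_features,
                                              tmp_path):
        fixed, moving, trunk = build_point_cloud_sequences(
            ct_features, pet_features, out_dir=tmp_path
        )
        assert len(fixed) == len(moving) == trunk.m2 - trunk.m1 + 1
        assert [c.source_slice for c in fixed] == [c.source_slice for c in moving]
        n_files = len(list(tmp_path.glob("ct_*.pcd")))
        assert n_files == trunk.m2 - trunk.m1 + 1
        assert len(list(tmp_path.glob("pet_*.pcd"))) == n_files

    def test_trunk_ends_before_leg_region(self, ct_features):
        trunk = extract_trunk_range(ct_features)
        assert trunk.m2 < 0.8 * len(ct_features)

    def test_length_mismatch_rejected(self, ct_features):
        with pytest.raises(ValueError, match="sequences not in correspondence"):
            build_point_cloud_sequences(ct_features, ct_features[:-1])


class TestPcdRoundTrip:
    def test_coordinates_roundtrip_exactly(self, tmp_path):
        rng = np.random.default_rng(9)
        cloud = PointCloud(points=rng.standard_normal((57, 3)) * 123.456)
        write_pcd(cloud, tmp_path / "c.pcd")
        back = read_pcd(tmp_path / "c.pcd")
        np.testing.assert_array_equal(back.points, cloud.points)
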