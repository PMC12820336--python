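import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alpsfw.alps_index import (
    ALPSComponents,
    ROISpec,
    apply_affine_tensor,
    compute_alps,
    default_roi_specs,
    extract_components,
    sphere_roi,
)
from alpsfw.core_io import ValidationError
from alpsfw.tensor_model import TensorMap


def brute_force_sphere(center, diameter, grid_shape, voxel_size=(1, 1, 1)):
    """Independent lattice enumeration of the center-distance rule."""
    mask = np.zeros(grid_shape, bool)
    r2 = (diameter / 2) ** 2
    for x in range(grid_shape[0]):
        for y in range(grid_shape[1]):
            for z in range(grid_shape[2]):
                d2 = sum(((a - c) * v) ** 2 for a, c, v in zip((x, y, z), center, voxel_size))
                if d2 <= r2:
                    mask[x, y, z] = True
    return mask


def _constant_tensor(grid, diag=(1.2e-3, 0.8e-3, 0.9e-3)):
    data = np.zeros(grid + (6,))
    data[..., 0], data[..., 1], data[..., 2] = diag
    return TensorMap(data=data)


class TestSphereROI:
    def test_five_mm_sphere_has_81_voxels(self):
        spec = ROISpec(name="L_proj", center=(10, 10, 6), diameter_mm=5.0)
        mask = sphere_roi(spec, (24, 24, 12))
        assert int(mask.sum()) == 81
        oracle = brute_force_sphere((10, 10, 6), 5.0, (24, 24, 12))
        assert np.array_equal(mask, oracle)

    def test_one_mm_sphere_is_single_voxel(self):
        spec = ROISpec(name="L_proj", center=(5, 5, 5), diameter_mm=1.0)
        mask = sphere_roi(spec, (12, 12, 12))
        assert int(mask.sum()) == 1
        assert mask[5, 5, 5]

    def test_corner_center_rejected(self):
        spec = ROISpec(name="L_proj", center=(0, 0, 0), diameter_mm=5.0)
        with pytest.raises(ValidationError, match="exceeds"):
            sphere_roi(spec, (24, 24, 12))

    def test_anisotropic_voxels_shrink_mask(self):
        spec = ROISpec(name="L_proj", center=(6, 6, 6), diameter_mm=5.0)
        mask = sphere_roi(spec, (13, 13, 13), voxel_size=(1.0, 1.0, 2.5))
        oracle = brute_force_sphere((6, 6, 6), 5.0, (13, 13, 13), (1.0, 1.0, 2.5))
        assert np.array_equal(mask, oracle)


class TestTensorReorientation:
    def test_identity_transform_is_noop(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0.2e-3, 1.5e-3, (8, 8, 6, 6))
        tm = TensorMap(data=data)
        out = apply_affine_tensor(tm, np.eye(4))
        assert np.allclose(out.data, data, atol=1e-12)

    def test_90_degree_rotation_swaps_components(self):
        grid = (9, 9, 9)
        tm = _constant_tensor(grid, diag=(1.0e-3, 2.0e-3, 3.0e-3))
        t = np.eye(4)
        t[:3, :3] = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        center = np.array([4, 4, 4])
        t[:3, 3] = center - t[:3, :3] @ center  # rotate about the grid center
        out = apply_affine_tensor(tm, t)
        # D' = R D R^T swaps the x and y diagonal entries
        assert out.data[4, 4, 4, 0] == pytest.approx(2.0e-3, rel=1e-9)
        assert out.data[4, 4, 4, 1] == pytest.approx(1.0e-3, rel=1e-9)
        assert out.data[4, 4, 4, 2] == pytest.approx(3.0e-3, rel=1e-9)

    def test_rigid_roundtrip_error_bounded_by_interpolation(self):
        """Transform then inverse-transform on a smooth phantom."""
        from scipy.spatial.transform import Rotation

        grid = (16, 16, 12)
        xx, yy, zz = np.meshgrid(*(np.arange(n) for n in grid), indexing="ij")
        smooth = 0.8e-3 + 0.2e-3 * np.sin(xx / 16) * np.cos(yy / 16)
        data = np.zeros(grid + (6,))
        data[..., 0] = smooth
        data[..., 1] = 0.6e-3
        data[..., 2] = 0.7e-3
        tm = TensorMap(data=data)
        r = Rotation.from_euler("z", 9, degrees=True).as_matrix()
        t = np.eye(4)
        t[:3, :3] = r
        center = (np.asarray(grid) - 1) / 2
        t[:3, 3] = center - r @ center
        back = apply_affine_tensor(apply_affine_tensor(tm, t), np.linalg.inv(t))
        inner = (slice(4, -4),) * 3
        md = data[..., :3].mean()
        err = np.abs(back.data[inner] - data[inner]).max()
        assert err <= 1e-3 * md

    def test_non_invertible_transform_rejected(self):
        tm = _constant_tensor((6, 6, 6))
        with pytest.raises(ValidationError, match="invertible"):
            apply_affine_tensor(tm, np.zeros((4, 4)))


class TestExtractComponents:
    def test_constant_field_identity(self):
        grid = (24, 24, 10)
        tm = _constant_tensor(grid)
        comp = extract_components(tm, default_roi_specs(grid))
        assert comp.Dxxproj_L == pytest.approx(1.2e-3, rel=1e-14)
        assert comp.Dyyproj_L == pytest.approx(0.8e-3, rel=1e-14)
        assert comp.Dzzassoc_L == pytest.approx(0.9e-3, rel=1e-14)

    def test_roi_localization(self):
        grid = (24, 24, 10)
        rois = default_roi_specs(grid)
        tm = _constant_tensor(grid, diag=(2.0e-3, 1.0e-3, 1.0e-3))
        inside = sphere_roi(rois["L_proj"], grid)
        tm.data[inside, 0] = 1.0e-3
        comp = extract_components(tm, rois)
        assert comp.Dxxproj_L == pytest.approx(1.0e-3, rel=1e-14)
        assert comp.Dxxassoc_L == pytest.approx(2.0e-3, rel=1e-14)

    def test_linear_gradient_mean_equals_center_value(self):
        """Sphere symmetry: a linear Dxx ramp averages to the center value."""
        grid = (24, 24, 10)
        rois = default_roi_specs(grid)
        tm = _constant_tensor(grid)
        ramp = 1.0e-3 + 1e-5 * np.arange(grid[0])[:, None, None]
        tm.data[..., 0] = ramp
        comp = extract_components(tm, rois)
        cx = rois["L_proj"].center[0]
        assert comp.Dxxproj_L == pytest.approx(1.0e-3 + 1e-5 * cx, rel=1e-12)

    def test_empty_roi_mask_intersection_rejected(self):
        grid = (24, 24, 10)
        tm = _constant_tensor(grid)
        tm.mask[:] = False
        with pytest.raises(ValidationError, match="empty"):
            extract_components(tm, default_roi_specs(grid))


def _components(vals):
    return ALPSComponents(**dict(zip(
        ("Dxxproj_L", "Dxxassoc_L", "Dyyproj_L", "Dzzassoc_L",
         "Dxxproj_R", "Dxxassoc_R", "Dyyproj_R", "Dzzassoc_R"), vals)))


class TestComputeAlps:
    def test_isotropic_components_give_unity(self):
        res = compute_alps(_components([1.0e-3] * 8))
        assert res.left == res.right == res.mean == 1.0

    def test_printed_formula_arithmetic(self):
        res = compute_alps(_components(
            [1.0e-3, 1.2e-3, 0.7e-3, 0.9e-3, 1.0e-3, 1.2e-3, 0.7e-3, 0.9e-3]))
        assert res.left == pytest.approx(1.375, rel=1e-12)

    def test_mirror_symmetric_components_collapse(self):
        vals = [1.0e-3, 1.2e-3, 0.7e-3, 0.9e-3]
        res = compute_alps(_components(vals + vals))
        assert res.mean == pytest.approx(res.left, rel=1e-12)
        assert res.left == pytest.approx(res.right, rel=1e-12)

    def test_mean_is_four_over_four_not_average_of_sides(self):
        """On an asymmetric fixture the 4/4 ratio differs from (L+R)/2."""
        c = _components([1.0e-3, 1.2e-3, 0.7e-3, 0.9e-3,
                         0.9e-3, 0.8e-3, 0.5e-3, 0.6e-3])
        res = compute_alps(c)
        four_over_four = ((c.Dxxproj_L + c.Dxxassoc_L + c.Dxxproj_R + c.Dxxassoc_R) / 4) / (
            (c.Dyyproj_L + c.Dzzassoc_L + c.Dyyproj_R + c.Dzzassoc_R) / 4)
        assert res.mean == pytest.approx(four_over_four, rel=1e-14)
        assert abs(res.mean - (res.left + res.right) / 2) > 1e-3

    @settings(max_examples=50, deadline=None)
    @given(
        vals=st.lists(st.floats(0.1e-3, 2.9e-3), min_size=8, max_size=8),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, vals, k):
        a = compute_alps(_components(vals))
        b = compute_alps(_components([v * k for v in vals]))
        assert b.left == pytest.approx(a.left, rel=1e-9)
        assert b.right == pytest.approx(a.right, rel=1e-9)
        assert b.mean == pytest.approx(a.mean, rel=1e-9)

    def test_dxx_reduction_strictly_lowers_side_and_mean(self):
        vals = [1.0e-3, 1.2e-3, 0.7e-3, 0.9e-3, 1.0e-3, 1.2e-3, 0.7e-3, 0.9e-3]
        base = compute_alps(_components(vals))
        reduced = list(vals)
        reduced[0] *= 0.8
        reduced[1] *= 0.8
        res = compute_alps(_components(reduced))
        assert res.left < base.left
        assert res.mean < base.mean
        assert res.right == base.right

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError, match="denominator"):
            compute_alps(_components([1e-3, 1e-3, 0.0, 0.0, 1e-3, 1e-3, 1e-3, 1e-3]))
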