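import numpy as np
import pytest

import petmap as pm
from petmap import phantom, preprocess, registration as reg
from petmap.grid import GridError


@pytest.fixture(scope="module")
def smooth_template(small_grid):
    """A mildly smoothed template: registration test image."""
    tpl = phantom.make_template(small_grid)
    return preprocess.smooth_gaussian(tpl, 10.0)


def _rotz_inverse(angle_deg, translation):
    """Exact inverse parameters of a z-rotation + translation affine."""
    a = np.deg2rad(-angle_deg)
    R = np.array([[np.cos(a), -np.sin(a), 0.0],
                  [np.sin(a), np.cos(a), 0.0],
                  [0.0, 0.0, 1.0]])
    t = -R @ np.asarray(translation)
    return reg.AffineParams(tuple(t), (0.0, 0.0, -angle_deg))


class TestAffineParams:
    def test_identity(self):
        p = reg.AffineParams.identity()
        assert p.is_identity
        assert np.allclose(p.matrix(), np.eye(4))

    def test_vector_round_trip(self):
        p = reg.AffineParams((1.0, -2.0, 3.0), (4.0, -1.0, 2.0),
                             (1.02, 0.98, 1.01), (0.01, -0.02, 0.005))
        q = reg.AffineParams.from_vector(p.to_vector())
        assert np.allclose(q.matrix(), p.matrix(), atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            reg.AffineParams(scale=(0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            reg.AffineParams(translation_mm=(1.0, 2.0))


class TestApplyTransform:
    def test_identity_transform(self, smooth_template):
        tf = reg.SpatialTransform(reg.AffineParams.identity(),
                                  smooth_template.grid)
        out = reg.apply_transform(smooth_template, tf)
        assert np.allclose(out.data, smooth_template.data)

    def test_integer_shift_nearest(self, smooth_template):
        vs = smooth_template.grid.voxel_size_mm[0]
        # pull-back by +1 voxel along x: output[i] = input[i + 1]
        tf = reg.SpatialTransform(
            reg.AffineParams(translation_mm=(vs, 0.0, 0.0)),
            smooth_template.grid)
        out = reg.apply_transform(smooth_template, tf, "nearest")
        assert np.allclose(out.data[:-1], smooth_template.data[1:])

    def test_trilinear_preserves_range(self, smooth_template):
        p = reg.AffineParams((3.0, -2.0, 1.0), (2.0, 1.0, -1.0))
        tf = reg.SpatialTransform(p, smooth_template.grid)
        out = reg.apply_transform(smooth_template, tf)
        assert out.data.min() >= smooth_template.data.min() - 1e-9
        assert out.data.max() <= smooth_template.data.max() + 1e-9

    def test_unknown_interpolation(self, smooth_template):
        tf = reg.SpatialTransform(reg.AffineParams.identity(),
                                  smooth_template.grid)
        with pytest.raises(ValueError):
            reg.apply_transform(smooth_template, tf, "cubic")

    def test_round_trip_rms_below_2_percent(self):
        # a 2 mm grid: interpolation error of the double resampling must be
        # judged at a resolution where the smoothed template is well sampled
        grid = pm.VolumeGrid.mni_like()
        tpl = preprocess.smooth_gaussian(phantom.make_template(grid), 10.0)
        p = reg.AffineParams((4.0, -3.0, 2.0), (0.0, 0.0, 3.0))
        fwd = reg.apply_transform(tpl, reg.SpatialTransform(p, grid))
        inv = _rotz_inverse(3.0, (4.0, -3.0, 2.0))
        assert np.allclose(inv.matrix() @ p.matrix(), np.eye(4), atol=1e-12)
        back = reg.apply_transform(fwd, reg.SpatialTransform(inv, grid))
        mask = phantom.make_gm_wm_mask(tpl, threshold_fraction=0.3)
        rms = np.sqrt(np.mean(
            (back.data[mask.data] - tpl.data[mask.data]) ** 2))
        dyn = tpl.data.max() - tpl.data.min()
        assert rms < 0.02 * dyn


@pytest.fixture(scope="module")
def textured():
    grid = pm.VolumeGrid.centered((46, 55, 46), (4.0, 4.0, 4.0))
    tpl = phantom.make_template(grid, texture_amplitude=8.0)
    return preprocess.smooth_gaussian(tpl, 10.0)


@pytest.fixture(scope="module")
def fast_opts():
    return reg.AffineOptions(pyramid_mm=(8.0, 4.0), maxfev=(2000, 800),
                             xtol=1e-4)


class TestRegisterAffine:
    def test_self_registration_is_identity(self, textured, fast_opts):
        p = reg.register_affine(textured, textured, fast_opts)
        vs = textured.grid.voxel_size_mm[0]
        assert np.linalg.norm(p.translation_mm) < 0.5 * vs

    def test_pure_shift_recovered(self, textured, fast_opts):
        true = reg.AffineParams(translation_mm=(6.0, 0.0, 0.0))
        moving = reg.apply_transform(
            textured, reg.SpatialTransform(true, textured.grid))
        p = reg.register_affine(moving, textured, fast_opts)
        assert abs(p.translation_mm[0] + 6.0) < 1.0
        assert np.linalg.norm(p.translation_mm[1:]) < 1.0
        assert np.linalg.norm(p.rotation_deg) < 0.5

    def test_pure_rotation_recovered(self, textured, fast_opts):
        true = reg.AffineParams(rotation_deg=(0.0, 0.0, 5.0))
        moving = reg.apply_transform(
            textured, reg.SpatialTransform(true, textured.grid))
        p = reg.register_affine(moving, textured, fast_opts)
        assert abs(p.rotation_deg[2] + 5.0) < 0.5
        assert np.linalg.norm(p.rotation_deg[:2]) < 0.5

    def test_constant_volume_rejected(self, textured):
        flat = pm.BrainVolume(textured.grid,
                              np.zeros(textured.grid.shape))
        with pytest.raises(reg.RegistrationError):
            reg.register_affine(flat, textured)


class TestWarps:
    def test_zero_bspline_is_identity(self, small_grid):
        origin, n_ctrl = reg._bspline_layout(small_grid, 30.0)
        step = reg.BSplineStep(30.0, origin, n_ctrl,
                               np.zeros((3,) + tuple(n_ctrl)))
        warp = reg.BSplineWarp(small_grid, [step])
        assert np.allclose(warp.displacement(), 0.0)
        assert warp.rms_mm == 0.0

    def test_zero_dct_is_identity(self, small_grid):
        warp = reg.DCTWarp(small_grid, (4, 5, 4))
        assert np.allclose(warp.displacement(), 0.0)
        # evaluated at an arbitrary point grid too
        assert np.allclose(warp.displacement(pm.VolumeGrid.centered(
            (8, 8, 8), (10.0, 10.0, 10.0))), 0.0)

    def test_transform_json_round_trip(self, small_grid, tmp_path):
        p = reg.AffineParams((1.0, 2.0, -1.0), (0.5, -0.5, 1.0))
        rng = np.random.default_rng(0)
        coeffs = 0.5 * rng.standard_normal((3, 4, 4, 4))
        warp = reg.DCTWarp(small_grid, (4, 4, 4), coeffs)
        tf = reg.SpatialTransform(p, small_grid, warp)
        d = reg.transform_to_dict(tf)
        back = reg.transform_from_dict(d)
        assert np.allclose(back.affine.matrix(), p.matrix())
        assert np.allclose(back.warp.displacement(small_grid),
                           warp.displacement(small_grid))

    def test_aligned_input_keeps_coefficients_small(self, smooth_template):
        opts = reg.WarpOptions(n_iter=3, n_iter_dct=2, inner_iter=2)
        warp = reg.refine_bspline(smooth_template, smooth_template,
                                  reg.AffineParams.identity(), opts)
        assert warp.rms_mm < 0.2


class TestSpaces:
    def test_mni_tal_grids(self):
        grid = pm.VolumeGrid.mni_like()
        vol = pm.BrainVolume(grid, np.full(grid.shape, 3.0))
        out = reg.mni_to_tal(vol)
        assert out.grid.shape == (128, 128, 60)
        assert out.grid.voxel_size_mm == (2.25, 2.25, 2.25)
        assert out.grid.space == "TAL_LIKE"

    def test_constant_maps_to_constant_inside(self):
        grid = pm.VolumeGrid.mni_like()
        vol = pm.BrainVolume(grid, np.full(grid.shape, 3.0))
        out = reg.mni_to_tal(vol)
        # the TAL grid is wider than the MNI field of view at the edges;
        # check interior voxels only
        assert np.allclose(out.data[30:-30, 30:-30, 10:-10], 3.0)

    def test_wrong_space_rejected(self):
        grid = pm.VolumeGrid.tal_like()
        vol = pm.BrainVolume(grid, np.zeros(grid.shape))
        with pytest.raises(GridError):
            reg.mni_to_tal(vol)

    def test_round_trip_rms(self):
        grid = pm.VolumeGrid.mni_like()
        tpl = preprocess.smooth_gaussian(phantom.make_template(grid), 10.0)
        back = reg.tal_to_mni(reg.mni_to_tal(tpl))
        mask = phantom.make_gm_wm_mask(tpl, threshold_fraction=0.3)
        rms = np.sqrt(np.mean((back.data[mask.data] - tpl.data[mask.data]) ** 2))
        dyn = tpl.data.max() - tpl.data.min()
        assert rms < 0.02 * dyn
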