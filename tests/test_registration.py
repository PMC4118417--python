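"""Transforms, warping, costs, optimizers and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffreg.embedding import ImageGrid
from diffreg.registration import (
    FFDTransform,
    RegistrationOptions,
    RigidTransform,
    _n_ctrl,
    field_error,
    l2_cost,
    mi_cost,
    register_ffd,
    register_rigid,
    rigid_error,
    warp,
)
from diffreg.synthetic import (
    DeformationSpec,
    PhantomSpec,
    make_phantom,
    sample_rbf_deformation,
)

angles = st.floats(-20, 20, allow_nan=False)
shifts = st.floats(-8, 8, allow_nan=False)


@pytest.fixture(scope="module")
def phantom():
    imgs, labels = make_phantom(PhantomSpec(shape=(64, 64), seed=11))
    return imgs, labels


class TestRigidTransform:
    @settings(deadline=None, max_examples=30)
    @given(angles, shifts, shifts)
    def test_inverse_round_trips_points(self, th, tr, tc):
        T = RigidTransform(th, (tr, tc), (10.0, 12.0))
        pts = np.array([[0.0, 0.0], [5.0, 7.0], [20.0, 3.0]])
        back = T.inverse().apply(T.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(angles, shifts, angles, shifts)
    def test_compose_matches_sequential_application(self, t1, s1, t2, s2):
        A = RigidTransform(t1, (s1, -s1), (8.0, 8.0))
        B = RigidTransform(t2, (s2, s2 / 2), (8.0, 8.0))
        pts = np.array([[1.0, 2.0], [14.0, 3.0]])
        assert np.allclose(A.compose(B).apply(pts), A.apply(B.apply(pts)),
                           atol=1e-9)


class TestWarp:
    def test_identity_returns_input_unchanged(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        out, mask = warp(img, RigidTransform(0.0))
        assert out is img
        assert mask.all()

    def test_integer_translation_moves_delta_exactly(self):
        img = np.zeros((16, 16))
        img[8, 7] = 1.0
        # output(u) = img(u + t): the peak moves by -t
        out, _ = warp(img, RigidTransform(0.0, (3.0, -2.0)))
        assert out[5, 9] == 1.0
        assert out.sum() == 1.0

    def test_round_trip_interior(self, rng):
        # smooth image: bilinear resampling error stays well below 1%
        rows, cols = np.mgrid[0:64, 0:64].astype(float)
        img = np.sin(rows / 9.0) * np.cos(cols / 7.0)
        T = RigidTransform(7.0, (3.0, -2.0), (31.5, 31.5))
        once, _ = warp(img, T)
        back, mask = warp(once, T.inverse())
        interior = np.zeros((64, 64), bool)
        interior[12:-12, 12:-12] = True
        err = np.abs(back - img)[interior & mask].mean()
        assert err < 0.01 * (img.max() - img.min())

    def test_dense_field_warp_matches_ffd(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        ctrl = rng.normal(0, 0.5, (_n_ctrl(24, 4), _n_ctrl(24, 4), 2))
        T = FFDTransform(ctrl, 4.0, (24, 24))
        a, _ = warp(img, T)
        b, _ = warp(img, T.dense_field())
        assert np.allclose(a, b, atol=1e-12)


class TestCosts:
    def test_l2_zero_iff_equal(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        assert l2_cost(a, a) == 0.0
        assert l2_cost(a, a + 2.0) == pytest.approx(4.0)

    def test_l2_matches_per_pixel_loop(self, rng):
        a, b = rng.uniform(0, 1, (4, 4)), rng.uniform(0, 1, (4, 4))
        expected = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(4) for j in range(4)
        ) / 16.0
        assert l2_cost(a, b) == pytest.approx(expected)

    def test_l2_empty_mask_error(self, rng):
        a = rng.uniform(0, 1, (4, 4))
        with pytest.raises(ValueError, match="empty mask"):
            l2_cost(a, a, mask=np.zeros((4, 4), bool))

    def test_mi_self_equals_histogram_entropy(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        hist, _ = np.histogram(a, bins=32)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert -mi_cost(a, a, bins=32) == pytest.approx(entropy, rel=1e-10)

    def test_mi_diagonal_joint_histogram(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        # joint counts [[2, 0], [0, 2]] -> MI = log 2
        assert -mi_cost(a, a, bins=2) == pytest.approx(np.log(2.0))

    def test_mi_independent_near_zero(self, rng):
        a = rng.uniform(0, 1, (64, 64))
        b = rng.uniform(0, 1, (64, 64))
        assert -mi_cost(a, b, bins=8) < 0.05

    def test_mi_validation(self, rng):
        a = rng.uniform(0, 1, (4, 4))
        with pytest.raises(ValueError):
            mi_cost(a, a, bins=1)
        with pytest.raises(ValueError, match="empty mask"):
            mi_cost(a, a, mask=np.zeros((4, 4), bool))


class TestFFDTransform:
    def test_zero_lattice_is_identity(self):
        T = FFDTransform(np.zeros((_n_ctrl(32, 4), _n_ctrl(32, 4), 2)), 4.0,
                         (32, 32))
        assert T.is_identity
        assert np.all(T.dense_field() == 0.0)

    def test_control_grid_shape_contract(self):
        # spacing 4 on a 64-pixel axis: 64/4 + 3 = 19 control points
        assert _n_ctrl(64, 4.0) == 19
        with pytest.raises(ValueError, match="control grid"):
            FFDTransform(np.zeros((5, 5, 2)), 4.0, (64, 64))

    def test_constant_lattice_translates(self):
        n = _n_ctrl(24, 4)
        ctrl = np.zeros((n, n, 2))
        ctrl[:, :, 0] = 1.5
        T = FFDTransform(ctrl, 4.0, (24, 24))
        D = T.dense_field()
        assert np.allclose(D[:, :, 0], 1.5, atol=1e-9)
        assert np.allclose(D[:, :, 1], 0.0, atol=1e-9)


class TestRegisterRigid:
    def test_identical_images_identity(self, phantom):
        img = phantom[0][0]
        res = register_rigid(img, img, "l2")
        assert abs(res.transform.theta) < 1e-3
        assert np.linalg.norm(res.transform.t) < 1e-3

    def test_known_translation_recovered(self, phantom):
        img = phantom[0][0]
        truth = RigidTransform(0.0, (4.0, -3.0), (31.5, 31.5))
        fixed, _ = warp(img, truth, cval=float(np.median(img.data)))
        res = register_rigid(fixed, img, "l2")
        _, t_err, _ = rigid_error(res.transform, truth)
        assert t_err < 0.5

    def test_known_rotation_recovered(self, phantom):
        img = phantom[0][0]
        truth = RigidTransform(5.0, (0.0, 0.0), (31.5, 31.5))
        fixed, _ = warp(img, truth, cval=float(np.median(img.data)))
        res = register_rigid(fixed, img, "l2")
        r_err, _, _ = rigid_error(res.transform, truth)
        assert r_err < 0.5

    def test_mi_cross_modality_recovery(self, phantom):
        imgs, _ = phantom
        truth = RigidTransform(4.0, (-3.0, 2.0), (31.5, 31.5))
        fixed, _ = warp(imgs[1], truth, cval=float(np.median(imgs[1].data)))
        res = register_rigid(fixed, imgs[0], "mi")
        assert rigid_error(res.transform, truth)[2] < 1.0

    def test_cost_trace_non_increasing(self, phantom):
        img = phantom[0][0]
        truth = RigidTransform(3.0, (2.0, 1.0), (31.5, 31.5))
        fixed, _ = warp(img, truth, cval=float(np.median(img.data)))
        res = register_rigid(fixed, img, "l2")
        assert all(b <= a + 1e-12 for a, b in zip(res.cost_trace,
                                                  res.cost_trace[1:]))


class TestRegisterFFD:
    def test_identical_images_stay_identity(self, phantom):
        img = phantom[0][0]
        res = register_ffd(img, img, "l2")
        max_disp = np.linalg.norm(res.transform.dense_field(), axis=-1).max()
        assert max_disp < 0.1

    def test_small_deformation_recovered(self, phantom):
        imgs, labels = phantom
        img = imgs[0]
        spec = DeformationSpec(kind="rbf", max_displacement=4.0, seed=5)
        field = sample_rbf_deformation(spec, img.shape)
        fixed, _ = warp(img, field, cval=float(np.median(img.data)))
        res = register_ffd(fixed, img, "l2")
        assert field_error(res.transform, field, mask=labels > 0) < 1.0

    def test_cost_trace_non_increasing(self, phantom):
        imgs, _ = phantom
        img = imgs[0]
        field = sample_rbf_deformation(
            DeformationSpec(kind="rbf", max_displacement=3.0, seed=6), img.shape
        )
        fixed, _ = warp(img, field, cval=float(np.median(img.data)))
        res = register_ffd(fixed, img, "l2")
        assert all(b <= a + 1e-12 for a, b in zip(res.cost_trace,
                                                  res.cost_trace[1:]))


class TestErrorMetrics:
    def test_rigid_error_zero_for_exact(self):
        T = RigidTransform(3.0, (1.0, 2.0))
        assert rigid_error(T, T) == (0.0, 0.0, 0.0)

    def test_rigid_error_three_four_five(self):
        est = RigidTransform(3.0, (4.0, 0.0))
        truth = RigidTransform(0.0, (0.0, 0.0))
        r, t, combined = rigid_error(est, truth)
        assert (r, t) == (3.0, 4.0)
        assert combined == pytest.approx(5.0)

    def test_field_error_uniform_offset(self, rng):
        truth = rng.normal(size=(8, 8, 2))
        est = truth + np.array([1.0, 0.0])
        assert field_error(est, truth) == pytest.approx(1.0)

    def test_field_error_matches_loop(self, rng):
        a, b = rng.normal(size=(5, 5, 2)), rng.normal(size=(5, 5, 2))
        expected = np.mean(
            [
                np.hypot(*(a[i, j] - b[i, j]))
                for i in range(5)
                for j in range(5)
            ]
        )
        assert field_error(a, b) == pytest.approx(expected)

    def test_spacing_scales_errors(self):
        est = RigidTransform(0.0, (3.0, 4.0))
        truth = RigidTransform(0.0, (0.0, 0.0))
        assert rigid_error(est, truth, spacing=2.0)[1] == pytest.approx(10.0)


class TestIndependentCrossCheck:
    def test_translation_agrees_with_simpleitk(self, phantom):
        """Same problem solved by an unrelated registration toolkit."""
        sitk = pytest.importorskip("SimpleITK")
        img = phantom[0][0]
        truth = RigidTransform(0.0, (3.5, -2.25), (31.5, 31.5))
        fixed, _ = warp(img, truth, cval=float(np.median(img.data)))
        ours = register_rigid(fixed, img, "l2").transform

        f = sitk.GetImageFromArray(np.ascontiguousarray(fixed.data[:, :, 0]))
        m = sitk.GetImageFromArray(np.ascontiguousarray(img.data[:, :, 0]))
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetOptimizerAsRegularStepGradientDescent(1.0, 1e-4, 200)
        reg.SetInitialTransform(sitk.TranslationTransform(2), inPlace=False)
        reg.SetInterpolator(sitk.sitkLinear)
        out = reg.Execute(f, m)
        # SimpleITK orders offsets (x, y) = (col, row)
        tc, tr = out.GetParameters()
        assert np.hypot(ours.t[0] - tr, ours.t[1] - tc) < 0.5
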