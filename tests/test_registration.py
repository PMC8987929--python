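"""Linear/template/Demons registration and transform application."""

import numpy as np
import pytest
import SimpleITK as sitk

from fuskit.core import PowerDopplerMovie
from fuskit.registration import (
    LinearTransform,
    apply_transform,
    build_template,
    demons_register,
    denoise_for_registration,
    linear_register,
    ncc,
    warp_image,
)
from fuskit.synthetic import generate_misaligned_cohort, inject_motion


def _radial_warp_transform(shape, amplitude=1.5, ring=12.0, width=8.0):
    """Smooth synthetic radial displacement field (pull convention)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    rr = np.hypot(yy - cy, xx - cx)
    amp = amplitude * np.exp(-(((rr - ring) / width) ** 2))
    with np.errstate(invalid="ignore"):
        fdx = amp * (xx - cx) / np.maximum(rr, 1e-6)
        fdy = amp * (yy - cy) / np.maximum(rr, 1e-6)
    field = np.stack([fdx, fdy], axis=-1)
    img = sitk.GetImageFromArray(field.astype(np.float64), isVector=True)
    return sitk.DisplacementFieldTransform(sitk.Image(img)), fdx, fdy


class TestDenoise:
    def test_full_rank_equals_plain_mean(self, rng):
        movie = PowerDopplerMovie(rng.random((20, 8, 8)) + 1, dt=0.4)
        out = denoise_for_registration(movie, k=20)
        assert np.allclose(out, movie.data.mean(axis=0), atol=1e-10)

    def test_rank1_movie_with_k1(self, rng):
        spatial = rng.random((8, 8)) + 1
        temporal = 1 + 0.1 * rng.random(30)
        movie = PowerDopplerMovie(temporal[:, None, None] * spatial, dt=0.4)
        out = denoise_for_registration(movie, k=1)
        assert np.allclose(out, movie.data.mean(axis=0), atol=1e-10)

    def test_registration_on_denoised_mean_recovers_motion(self, phantom32):
        """The registration images the pipeline actually uses: denoised means
        of noisy movies still support sub-half-pixel shift recovery."""
        rng = np.random.default_rng(5)
        truth = phantom32.baseline
        noisy = lambda: truth[None] * (
            1 + 0.05 * rng.standard_normal((30,) + truth.shape)
        )
        fixed_mean = denoise_for_registration(PowerDopplerMovie(noisy(), dt=0.4), k=4)
        moved = inject_motion(noisy(), (2.0, -1.0), 0.0, order=3)
        moving_mean = denoise_for_registration(PowerDopplerMovie(moved, dt=0.4), k=4)
        tf = linear_register(moving_mean, fixed_mean)
        assert np.abs(tf.content_shift - np.array([2.0, -1.0])).max() < 0.5

    def test_truncation_preserves_stationary_mean(self, phantom32):
        """For a stationary movie the truncated mean stays within a small
        fraction of the plain mean (the constant temporal component is the
        leading singular direction)."""
        rng = np.random.default_rng(6)
        truth = phantom32.baseline
        movie = PowerDopplerMovie(
            truth[None] * (1 + 0.1 * rng.standard_normal((40,) + truth.shape)), dt=0.4
        )
        den = denoise_for_registration(movie, k=2)
        raw = movie.data.mean(axis=0)
        assert np.abs(den - raw).max() < 0.02 * raw.max()

    def test_bad_k_rejected(self, rng):
        movie = PowerDopplerMovie(rng.random((10, 4, 4)) + 1, dt=0.4)
        with pytest.raises(ValueError):
            denoise_for_registration(movie, k=0)


class TestLinearRegister:
    def test_identity_for_identical_images(self, phantom64):
        tf = linear_register(phantom64.baseline, phantom64.baseline)
        assert np.abs(tf.content_shift).max() < 1e-3
        assert abs(tf.rotation_deg) < 1e-3
        assert np.abs(tf.matrix - np.eye(2)).max() < 1e-3

    def test_translation_recovered(self, phantom64):
        moving = inject_motion(phantom64.baseline, (3.0, -2.0), 0.0, order=3)
        tf = linear_register(moving, phantom64.baseline)
        assert np.abs(tf.content_shift - np.array([3.0, -2.0])).max() < 0.5

    def test_rotation_recovered(self, phantom64):
        moving = inject_motion(phantom64.baseline, (0.0, 0.0), 2.0, order=3)
        tf = linear_register(moving, phantom64.baseline)
        assert abs(tf.rotation_deg - 2.0) < 0.5

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant image"):
            linear_register(np.ones((32, 32)), np.ones((32, 32)))

    def test_json_round_trip(self, phantom64):
        moving = inject_motion(phantom64.baseline, (1.0, 1.5), 0.5, order=3)
        tf = linear_register(moving, phantom64.baseline)
        back = LinearTransform.from_json(tf.to_json())
        assert np.allclose(back.content_shift, tf.content_shift, atol=1e-9)
        a = warp_image(moving, tf, interpolation="linear")
        b = warp_image(moving, back, interpolation="linear")
        assert np.allclose(a, b, equal_nan=True)


class TestBuildTemplate:
    def test_identical_inputs_converge_immediately(self, phantom32):
        img = phantom32.baseline
        res = build_template([img, img.copy(), img.copy()])
        assert len(res.convergence_history) == 1
        assert res.converged
        for tf in res.transforms:
            assert np.abs(tf.content_shift).max() < 1e-6

    def test_known_shifts_recovered(self, phantom64):
        """Injected translations are recovered (up to the cohort-mean offset
        that defines the common space) and the template stays sharp."""
        images, truths = generate_misaligned_cohort(
            phantom64, n_acquisitions=8, max_rotation=0.0, seed=4
        )
        res = build_template(images)
        assert res.converged
        est = np.array([tf.content_shift for tf in res.transforms])
        inj = np.array([[t["dy"], t["dx"]] for t in truths])
        resid = (est - est.mean(0)) - (inj - inj.mean(0))
        err = np.hypot(resid[:, 0], resid[:, 1])
        assert (err < 0.5).mean() >= 0.9
        # the common space drifts only boundedly from the source image
        from fuskit.registration import estimate_shift

        assert np.abs(estimate_shift(phantom64.baseline, res.template)).max() < 2.0

    def test_convergence_history_decreasing(self, phantom64):
        images, _ = generate_misaligned_cohort(phantom64, n_acquisitions=6, seed=9)
        res = build_template(images)
        hist = res.convergence_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_needs_two_images(self, phantom32):
        with pytest.raises(ValueError, match="2 images"):
            build_template([phantom32.baseline])


class TestDemons:
    def test_identical_images_give_negligible_field(self, phantom64):
        d = demons_register(phantom64.smooth_baseline, phantom64.smooth_baseline)
        assert d.magnitude.mean() < 0.1

    def test_radial_warp_recovered(self, phantom64):
        img = phantom64.smooth_baseline
        tf_true, fdx, fdy = _radial_warp_transform(img.shape, amplitude=1.5)
        warped = sitk.GetArrayFromImage(
            sitk.Resample(
                sitk.GetImageFromArray(img), sitk.GetImageFromArray(img),
                tf_true, sitk.sitkLinear, 0.0,
            )
        )
        d = demons_register(warped, img)
        # estimated pull field approximately inverts the applied one
        interior = phantom64.mask.copy()
        interior[:4] = interior[-4:] = False
        interior[:, :4] = interior[:, -4:] = False
        epe = np.hypot(d.field[..., 0] + fdx, d.field[..., 1] + fdy)[interior]
        assert epe.mean() < 0.75

    def test_round_trip_residual_small(self, phantom64):
        img = phantom64.smooth_baseline
        tf_true, _, _ = _radial_warp_transform(img.shape, amplitude=1.2)
        warped = sitk.GetArrayFromImage(
            sitk.Resample(
                sitk.GetImageFromArray(img), sitk.GetImageFromArray(img),
                tf_true, sitk.sitkLinear, 0.0,
            )
        )
        fwd = demons_register(warped, img)  # img -> warped correspondence
        bwd = demons_register(img, warped)
        comp = sitk.CompositeTransform(2)
        comp.AddTransform(fwd.transform)
        comp.AddTransform(bwd.transform)
        h, w = img.shape
        pts = [(x, y) for y in range(8, h - 8, 8) for x in range(8, w - 8, 8)]
        resid = [np.hypot(*(np.array(comp.TransformPoint(p)) - p)) for p in pts]
        assert np.mean(resid) < 0.5


class TestApplyTransform:
    def test_identity_preserves_movie(self, phantom32):
        movie = PowerDopplerMovie(
            np.stack([phantom32.smooth_baseline] * 5), dt=0.4, mask=phantom32.mask
        )
        out = apply_transform(movie, LinearTransform.identity(movie.shape))
        assert out.n_frames == movie.n_frames
        assert np.abs(out.data - movie.data).max() < 1e-6 * movie.data.max()

    def test_translation_round_trip_bounded_by_interp_error(self, rng):
        # globally smooth image: no intensity cliff for interpolation to ring on
        from scipy import ndimage

        img = 100 + 50 * ndimage.gaussian_filter(rng.standard_normal((32, 32)), 3)
        movie = PowerDopplerMovie(np.stack([img] * 3), dt=0.4)
        fwd = LinearTransform.identity(movie.shape)
        fwd.transform.SetTranslation((1.7, -2.3))
        bwd = LinearTransform.identity(movie.shape)
        bwd.transform.SetTranslation((-1.7, 2.3))
        out = apply_transform(apply_transform(movie, fwd), bwd)
        span = img.max() - img.min()
        # interior pixels only: near the border the B-spline support touches
        # pixels invalidated by the first resampling
        interior = out.mask.copy()
        interior[:4] = interior[-4:] = False
        interior[:, :4] = interior[:, -4:] = False
        dev = np.abs(out.data[0] - img)[interior]
        assert dev.max() < 0.01 * span

    def test_constant_frames_stay_constant(self):
        movie = PowerDopplerMovie(np.full((4, 16, 16), 3.0), dt=0.4)
        tf = LinearTransform.identity((16, 16))
        tf.transform.SetTranslation((0.5, 0.25))
        out = apply_transform(movie, tf)
        assert np.allclose(out.data[:, out.mask], 3.0, atol=1e-9)

    def test_shape_mismatch_rejected(self, phantom32):
        movie = PowerDopplerMovie(np.ones((3, 8, 8)), dt=0.4)
        with pytest.raises(ValueError, match="grid"):
            apply_transform(movie, LinearTransform.identity((16, 16)))

    def test_ncc_guard(self):
        with pytest.raises(ValueError, match="constant"):
            ncc(np.ones((4, 4)), np.ones((4, 4)))
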