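"""Groupwise alignment of acquisitions: iterative linear template building
followed by non-linear Demons refinement.

All acquisitions of a cohort imaged in the same coronal plane are aligned by
(1) computing a mean image, (2) linearly registering every acquisition onto
it, (3) recomputing the mean, and iterating until two successive templates
no longer differ; each acquisition is then refined with diffeomorphic
Demons.  Registration is estimated on SVD-denoised temporal means and
applied to the original frames.

Transforms follow the resampling ("pull") convention: they map points of the
fixed/template grid into the moving image.  ``content_shift`` reports the
more intuitive quantity — by how many pixels the moving image's content is
displaced relative to the fixed image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import PowerDopplerMovie

__all__ = [
    "LinearTransform",
    "DisplacementTransform",
    "TemplateRegistration",
    "denoise_for_registration",
    "linear_register",
    "build_template",
    "demons_register",
    "apply_transform",
    "warp_image",
    "ncc",
    "estimate_shift",
]


def _to_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(img, dtype=np.float64))


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation between two images over valid pixels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    good = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        good &= mask
    av, bv = a[good], b[good]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant image: similarity undefined")
    return float(np.corrcoef(av, bv)[0, 1])


def estimate_shift(reference: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Sub-pixel (row, col) content shift of ``moving`` relative to ``reference``
    via phase cross-correlation (positive means content moved down/right)."""
    shift, _, _ = phase_cross_correlation(
        np.asarray(reference, float), np.asarray(moving, float), upsample_factor=50
    )
    return -np.asarray(shift)


@dataclass
class LinearTransform:
    """2D affine in the pull convention, with similarity bookkeeping."""

    transform: sitk.AffineTransform
    similarity: float = np.nan
    shape: tuple[int, int] = (0, 0)

    @property
    def content_shift(self) -> np.ndarray:
        """(row, col) displacement of the moving content relative to fixed."""
        c = ((self.shape[1] - 1) / 2.0, (self.shape[0] - 1) / 2.0)  # (x, y)
        p = self.transform.TransformPoint(c)
        return np.array([p[1] - c[1], p[0] - c[0]])

    @property
    def matrix(self) -> np.ndarray:
        return np.array(self.transform.GetMatrix()).reshape(2, 2)

    @property
    def rotation_deg(self) -> float:
        """Rotation of the moving content relative to fixed (degrees), in the
        array (row, col) convention used by the synthetic motion injector."""
        u, _, vt = np.linalg.svd(self.matrix)
        r = u @ vt
        # the transform acts in (x, y) = (col, row); swapping axes flips the
        # sign of the angle relative to (row, col) convention
        return float(-np.degrees(np.arctan2(r[1, 0], r[0, 0])))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "affine2d",
                "matrix": list(self.transform.GetMatrix()),
                "translation": list(self.transform.GetTranslation()),
                "center": list(self.transform.GetCenter()),
                "similarity": self.similarity,
                "shape": list(self.shape),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearTransform":
        d = json.loads(text)
        tf = sitk.AffineTransform(2)
        tf.SetMatrix(d["matrix"])
        tf.SetTranslation(d["translation"])
        tf.SetCenter(d["center"])
        return cls(transform=tf, similarity=d.get("similarity", np.nan), shape=tuple(d["shape"]))

    @staticmethod
    def identity(shape: tuple[int, int]) -> "LinearTransform":
        tf = sitk.AffineTransform(2)
        tf.SetCenter(((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0))
        return LinearTransform(transform=tf, similarity=1.0, shape=shape)


@dataclass
class DisplacementTransform:
    """Dense displacement field (pull convention), plus the field in numpy
    form with shape (rows, cols, 2) and (dx, dy) component order."""

    transform: sitk.DisplacementFieldTransform
    field: np.ndarray
    similarity: float = np.nan

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.field[..., 0], self.field[..., 1])


@dataclass
class TemplateRegistration:
    """Result of iterative template construction."""

    template: np.ndarray
    transforms: list[LinearTransform]
    convergence_history: list[float] = field(default_factory=list)
    converged: bool = True


def denoise_for_registration(movie: PowerDopplerMovie, k: int) -> np.ndarray:
    """Temporal mean of the rank-k SVD truncation of the movie.

    With k equal to the frame count this is the plain temporal mean; smaller
    k suppresses temporal noise before the mean is taken, which is what the
    registration is estimated on (the transforms are then applied to the
    original data).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > movie.n_frames:
        raise ValueError(f"k ({k}) must be <= n_frames ({movie.n_frames})")
    t = movie.n_frames
    x = movie.data.reshape(t, -1).T  # Casorati (pixels, time)
    if k == t:
        recon = x
    else:
        u, s, vh = np.linalg.svd(x, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vh[:k]
    return recon.mean(axis=1).reshape(movie.shape)


def linear_register(moving: np.ndarray, fixed: np.ndarray) -> LinearTransform:
    """2D affine registration of ``moving`` onto ``fixed`` (NCC metric).

    Initialized with a sub-pixel phase-correlation translation estimate, then
    refined with a multi-resolution gradient-descent affine fit.  Returns the
    transform together with the final NCC similarity.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"image shapes differ: {moving.shape} vs {fixed.shape}")
    if not (np.isfinite(moving).all() and np.isfinite(fixed).all()):
        raise ValueError("images must be finite")
    if moving.std() == 0 or fixed.std() == 0:
        raise ValueError("constant image: similarity undefined")
    shape = fixed.shape
    shift = estimate_shift(fixed, moving)  # content shift (row, col)
    init = sitk.AffineTransform(2)
    init.SetCenter(((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0))
    init.SetTranslation((float(shift[1]), float(shift[0])))
    fixed_img, moving_img = _to_sitk(fixed), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.5, minStep=1e-6, numberOfIterations=300, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SetInitialTransform(init, inPlace=True)
    final = sitk.AffineTransform(reg.Execute(fixed_img, moving_img))
    out = LinearTransform(transform=final, shape=shape)
    warped = warp_image(moving, out, interpolation="linear")
    out.similarity = ncc(warped, fixed)
    return out


def warp_image(
    image: np.ndarray,
    transform: "LinearTransform | DisplacementTransform",
    interpolation: str = "bspline",
    default_value: float = np.nan,
) -> np.ndarray:
    """Resample a 2D image through a transform; out-of-frame pixels become
    ``default_value`` (NaN by default, i.e. marked invalid)."""
    interp = {
        "linear": sitk.sitkLinear,
        "bspline": sitk.sitkBSpline,
        "nearest": sitk.sitkNearestNeighbor,
    }[interpolation]
    img = _to_sitk(np.asarray(image, dtype=float))
    res = sitk.Resample(img, img, transform.transform, interp, float(default_value))
    return sitk.GetArrayFromImage(res)


def build_template(
    images: list[np.ndarray],
    tol: float = 1e-3,
    max_iter: int = 10,
) -> TemplateRegistration:
    """Iterative mean -> register-all -> new mean template construction.

    The residual tracked per iteration is the mean absolute difference
    between successive templates, normalized by the template's dynamic
    range; iteration stops when it falls below ``tol`` ("no residual
    difference between two successive means" — the default 1e-3 sits just
    above the sub-pixel interpolation noise floor of vessel-speckled Doppler
    images, below which successive means only jitter).  The common space is
    defined only up to a global transform (in particular the cohort-mean
    shift), so recovered per-acquisition motion should be compared after
    removing that common offset.  Non-convergence at
    ``max_iter`` returns the best template with a warning and the
    ``converged`` flag cleared.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images to build a template")
    images = [np.asarray(im, dtype=float) for im in images]
    template = np.mean(images, axis=0)
    history: list[float] = []
    transforms: list[LinearTransform] = []
    converged = False
    for _ in range(max_iter):
        transforms = [linear_register(im, template) for im in images]
        warped = np.stack(
            [warp_image(im, tf, interpolation="linear") for im, tf in zip(images, transforms)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            new_template = np.nanmean(warped, axis=0)
        new_template = np.where(np.isfinite(new_template), new_template, template)
        rng_ = template.max() - template.min()
        residual = float(np.mean(np.abs(new_template - template)) / max(rng_, 1e-12))
        history.append(residual)
        template = new_template
        if residual < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"template construction did not converge in {max_iter} iterations "
            f"(last residual {history[-1]:.3g}); returning best template"
        )
    return TemplateRegistration(
        template=template,
        transforms=transforms,
        convergence_history=history,
        converged=converged,
    )


def demons_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    iterations: int = 100,
    smoothing_sigma: float = 1.0,
) -> DisplacementTransform:
    """Diffeomorphic Demons refinement after linear pre-alignment.

    Returns a dense displacement field (pull convention).  If the warped
    moving image's NCC similarity to the fixed image drops more than 10%
    below its pre-warp value the registration is considered divergent and
    aborted with diagnostics.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"image shapes differ: {moving.shape} vs {fixed.shape}")
    pre = ncc(moving, fixed)
    dem = sitk.DiffeomorphicDemonsRegistrationFilter()
    dem.SetNumberOfIterations(int(iterations))
    dem.SetSmoothDisplacementField(True)
    dem.SetStandardDeviations(float(smoothing_sigma))
    field_img = dem.Execute(_to_sitk(fixed), _to_sitk(moving))
    tf = sitk.DisplacementFieldTransform(sitk.Image(field_img))
    field = sitk.GetArrayFromImage(field_img)  # (rows, cols, (dx, dy))
    out = DisplacementTransform(transform=tf, field=field)
    warped = warp_image(moving, out, interpolation="linear")
    post = ncc(warped, fixed)
    out.similarity = post
    if post < pre - 0.1 * abs(pre):
        raise RuntimeError(
            f"Demons registration diverged: NCC fell from {pre:.4f} to {post:.4f}"
        )
    return out


def apply_transform(
    movie: PowerDopplerMovie,
    transform: "LinearTransform | DisplacementTransform",
    interpolation: str = "bspline",
) -> PowerDopplerMovie:
    """Resample every frame of a movie through one transform.

    Frame count and ordering are untouched.  Pixels pulled from outside the
    frame, or whose interpolation support touches previously invalidated
    pixels, are marked invalid: NaN in the data and removed from the mask.
    Cubic B-spline interpolation is the default for the final resampling
    (use ``nearest`` for label images).
    """
    if isinstance(transform, DisplacementTransform):
        if transform.field.shape[:2] != movie.shape:
            raise ValueError(
                f"displacement field {transform.field.shape[:2]} does not match movie grid {movie.shape}"
            )
    elif isinstance(transform, LinearTransform):
        if tuple(transform.shape) != tuple(movie.shape):
            raise ValueError(
                f"transform grid {transform.shape} does not match movie grid {movie.shape}"
            )
    src_valid = np.isfinite(movie.data).all(axis=0)
    data = movie.data
    if not src_valid.all():
        # fill invalid pixels from their nearest valid neighbor so the
        # B-spline prefilter (whose IIR tail reaches past any fixed erosion)
        # never sees an artificial intensity jump; the mask bookkeeping below
        # still marks everything these pixels influence as invalid
        _, idx = ndimage.distance_transform_edt(~src_valid, return_indices=True)
        data = movie.data[:, idx[0], idx[1]]
    frames = np.stack([warp_image(f, transform, interpolation=interpolation) for f in data])
    valid = np.isfinite(frames).all(axis=0)
    # a pixel is valid only if its whole interpolation footprint was valid
    carried = warp_image(src_valid.astype(float), transform, "linear", default_value=0.0)
    valid &= np.nan_to_num(carried) > 0.999
    if interpolation == "bspline" and not src_valid.all():
        # cubic support reaches 2 px beyond the linear footprint
        valid &= ndimage.binary_erosion(valid, np.ones((5, 5)), border_value=1)
    mask_img = warp_image(
        movie.mask.astype(float), transform, interpolation="nearest", default_value=0.0
    )
    out = movie.with_data(np.where(valid[None], frames, np.nan))
    out.mask = (mask_img > 0.5) & valid
    return out
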