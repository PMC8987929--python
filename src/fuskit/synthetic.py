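"""Synthetic fUS acquisition generator with known ground truth.

Real acquisitions of this kind (rat coronal slices, Power Doppler every
0.4 s under visual stimulation or every 2.8 s per slice at rest) are not
publicly deposited, so every analysis stage here is validated against
synthetic movies whose generating parameters are known by construction:

* a vascular-looking baseline image (smooth tissue field plus vessel
  speckle) with a label atlas laid out on one coronal slice;
* resting-state runs whose ROI mean time-courses carry programmed pairwise
  Pearson correlations, built from shared band-limited (0.01-0.08 Hz)
  latent signals plus independent white measurement noise;
* stimulation runs with block-locked %CBV responses of programmed amplitude
  and temporal shape (initial peak / late peak / sustained), added
  multiplicatively on the baseline;
* raw compound-frame stacks (tissue clutter + fast-decorrelating blood
  signal) for validating the SVD clutter filter against a true blood-power
  image.

All generators are deterministic given a seed (``numpy.random.default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import AtlasLabels, CompoundFrameStack, PowerDopplerMovie
from .stimulus import StimulationProtocol

__all__ = [
    "PhantomSpec",
    "Phantom",
    "GroundTruth",
    "default_phantom_spec",
    "generate_phantom",
    "generate_resting_movie",
    "generate_stimulation_movie",
    "generate_compound_stack",
    "response_shape",
    "inject_motion",
    "generate_misaligned_cohort",
    "null_group_table",
]

# latent resting fluctuations live in the band analyzed by ReHo/fALFF,
# which makes their local-connectivity ground truth analytic
RESTING_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of the synthetic coronal slice.

    ``region_layout`` maps region name -> boolean pixel mask (the synthetic
    atlas).  ``vessel_density`` is the fraction of brain pixels carrying
    bright vessel speckle; ``baseline_intensity`` sets the mean Doppler level
    inside the brain (arbitrary units).
    """

    grid_shape: tuple[int, int]
    region_layout: dict[str, np.ndarray]
    pixel_size: float = 0.1
    vessel_density: float = 0.15
    baseline_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 16 or self.grid_shape[1] < 16:
            raise ValueError("grid_shape must be at least 16x16")
        if not 0.0 <= self.vessel_density <= 1.0:
            raise ValueError("vessel_density must lie in [0, 1]")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")


@dataclass
class Phantom:
    """Realized phantom: baseline image, brain mask and atlas labels."""

    baseline: np.ndarray
    smooth_baseline: np.ndarray
    mask: np.ndarray
    vessel_mask: np.ndarray
    atlas: AtlasLabels
    spec: PhantomSpec

    def region_pixels(self, name: str) -> np.ndarray:
        return self.atlas.region_mask(name)


@dataclass
class GroundTruth:
    """Programmed signal content of one synthetic acquisition.

    ``programmed_response`` maps region name -> (amplitude in %CBV, shape
    label); shapes are ``initial-peak`` / ``late-peak`` / ``sustained`` /
    ``none``.  ``programmed_correlations`` maps (roi_a, roi_b) -> target
    Pearson r of the ROI mean time-courses.  ``noise_sd`` is white
    measurement noise per pixel per frame as a fraction of baseline;
    ``fluct_amp`` is the amplitude of the shared resting fluctuations as a
    fraction of baseline.  ``motion`` optionally holds per-acquisition
    (dy, dx, rotation_deg) misalignment.
    """

    programmed_response: dict[str, tuple[float, str]] = field(default_factory=dict)
    programmed_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.01
    fluct_amp: float = 0.02
    motion: tuple[float, float, float] | None = None
    peak_time: float = 6.0
    late_peak_delay: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, r in self.programmed_correlations.items():
            if not np.isfinite(r) or abs(r) > 1:
                raise ValueError(f"target correlation for {pair} must satisfy |r| <= 1, got {r}")
        for region, (amp, kind) in self.programmed_response.items():
            if not np.isfinite(amp):
                raise ValueError(f"amplitude for {region} must be finite")
            if kind not in ("initial-peak", "late-peak", "sustained", "none"):
                raise ValueError(f"unknown response shape {kind!r} for {region}")


def _ellipse_mask(shape: tuple[int, int], center, semi_axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + ((cc - center[1]) / semi_axes[1]) ** 2 <= 1.0


def default_phantom_spec(
    grid_shape: tuple[int, int] = (64, 64),
    pixel_size: float = 0.1,
    vessel_density: float = 0.15,
    baseline_intensity: float = 100.0,
) -> PhantomSpec:
    """A coronal-slice-like layout with eight named ROIs.

    Regions are disjoint ellipses inside a brain-shaped ellipse: visual
    cortex subdivisions dorsally, colliculus/pretectum in the midbrain,
    hippocampus and thalamus in between.  Coordinates scale with the grid.
    """
    h, w = grid_shape
    # (name, center (row frac, col frac), semi-axes (row frac, col frac))
    defs = [
        ("V1", (0.22, 0.30), (0.08, 0.10)),
        ("V2ML", (0.22, 0.62), (0.08, 0.10)),
        ("V2MM", (0.22, 0.85), (0.07, 0.07)),
        ("RSC", (0.40, 0.16), (0.08, 0.08)),
        ("CA1", (0.45, 0.46), (0.09, 0.12)),
        ("SC", (0.45, 0.80), (0.09, 0.10)),
        ("Thal", (0.68, 0.38), (0.10, 0.12)),
        ("Pt", (0.68, 0.72), (0.09, 0.09)),
    ]
    layout = {
        name: _ellipse_mask(grid_shape, (c[0] * h, c[1] * w), (a[0] * h, a[1] * w))
        for name, c, a in defs
    }
    return PhantomSpec(
        grid_shape=grid_shape,
        region_layout=layout,
        pixel_size=pixel_size,
        vessel_density=vessel_density,
        baseline_intensity=baseline_intensity,
    )


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Build the baseline image, brain mask and atlas for a spec.

    Overlapping regions are rejected by name.  The brain mask is an ellipse
    united with all region pixels, so it always covers the atlas.  With
    ``vessel_density`` 0 the baseline equals its spatially smooth component.
    """
    names = sorted(spec.region_layout)
    masks = {n: np.asarray(spec.region_layout[n], dtype=bool) for n in names}
    for n, m in masks.items():
        if m.shape != tuple(spec.grid_shape):
            raise ValueError(f"region {n!r} mask shape {m.shape} != grid {spec.grid_shape}")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"overlapping regions in layout: {a!r} and {b!r}")
    h, w = spec.grid_shape
    brain = _ellipse_mask(spec.grid_shape, (0.5 * h, 0.5 * w), (0.46 * h, 0.46 * w))
    for m in masks.values():
        brain |= m
    rng = np.random.default_rng(seed)
    # smooth tissue field: lognormal of a heavily smoothed Gaussian field
    g = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=max(h, w) / 12)
    g = (g - g.mean()) / max(g.std(), 1e-12)
    smooth = spec.baseline_intensity * np.exp(0.25 * g)
    smooth = np.where(brain, smooth, 0.01 * spec.baseline_intensity)
    vessel_mask = np.zeros(spec.grid_shape, dtype=bool)
    baseline = smooth.copy()
    n_vessels = int(round(spec.vessel_density * brain.sum()))
    if n_vessels > 0:
        idx = np.flatnonzero(brain)
        chosen = rng.choice(idx, size=n_vessels, replace=False)
        vessel_mask.flat[chosen] = True
        # vessels are bright: multiplicative boost, 2x-6x
        boost = 2.0 + 4.0 * rng.random(n_vessels)
        baseline.flat[chosen] = baseline.flat[chosen] * boost
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    name_table: dict[int, str] = {}
    for k, n in enumerate(names, start=1):
        labels[masks[n]] = k
        name_table[k] = n
    atlas = AtlasLabels(labels=labels, names=name_table)
    return Phantom(
        baseline=baseline,
        smooth_baseline=smooth,
        mask=brain,
        vessel_mask=vessel_mask,
        atlas=atlas,
        spec=spec,
    )


def _bandlimited_orthonormal_latents(
    n_frames: int, dt: float, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k latent time-courses, band-limited to 0.01-0.08 Hz, with exactly
    orthonormal (hence exactly uncorrelated) columns scaled to unit variance."""
    lo, hi = RESTING_BAND
    nyq = 0.5 / dt
    z = rng.standard_normal((n_frames, k))
    if hi < nyq:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=1.0 / dt, output="sos")
        z = signal.sosfiltfilt(sos, z, axis=0)
    z = z - z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    # unit sample variance (ddof 0) per column
    return q * np.sqrt(n_frames)


def _target_matrix(
    roi_names: list[str], programmed: dict[tuple[str, str], float]
) -> np.ndarray:
    k = len(roi_names)
    index = {n: i for i, n in enumerate(roi_names)}
    r = np.eye(k)
    for (a, b), val in programmed.items():
        if a not in index or b not in index:
            raise ValueError(f"programmed correlation names unknown region: {(a, b)}")
        r[index[a], index[b]] = r[index[b], index[a]] = val
    return r


def _mixing_from_correlation(r: np.ndarray, roi_names: list[str]) -> np.ndarray:
    """Mixing matrix L with L L^T = r; rejects non-PSD targets by pair."""
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        # name the strongest off-diagonal pair as the likely offender
        off = np.abs(r - np.diag(np.diag(r)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            "programmed correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g}); check pair ({roi_names[i]!r}, {roi_names[j]!r})"
        )
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate_resting_movie(
    phantom: Phantom,
    truth: GroundTruth,
    n_frames: int = 407,
    dt: float = 2.8,
    slice_id: int = 0,
    t0: float = 0.0,
) -> PowerDopplerMovie:
    """Resting-state movie with programmed ROI-pair correlations.

    Each region's pixels share one latent band-limited signal; mixing weights
    are solved so that the *expected* Pearson r between ROI mean time-courses
    (latent signal plus the ROI-averaged white measurement noise) equals the
    programmed value.  Infeasible (non-PSD) targets are rejected naming the
    offending pair.
    """
    if n_frames < 64:
        raise ValueError("n_frames must be >= 64")
    if dt <= 0:
        raise ValueError("dt must be positive")
    roi_names = phantom.atlas.region_names
    r_target = _target_matrix(roi_names, truth.programmed_correlations)
    # noise attenuation of the ROI mean: a_i = s / sqrt(s^2 + noise^2 / n_i)
    n_pix = np.array(
        [phantom.atlas.region_mask(n).sum() for n in roi_names], dtype=float
    )
    if truth.fluct_amp <= 0:
        raise ValueError("fluct_amp must be positive for a resting movie")
    atten = truth.fluct_amp / np.sqrt(
        truth.fluct_amp**2 + truth.noise_sd**2 / np.maximum(n_pix, 1.0)
    )
    r_latent = r_target / np.outer(atten, atten)
    np.fill_diagonal(r_latent, 1.0)
    if np.any(np.abs(r_latent) > 1 + 1e-9):
        i, j = np.unravel_index(
            np.argmax(np.abs(r_latent - np.eye(len(roi_names)))), r_latent.shape
        )
        raise ValueError(
            "programmed correlation infeasible at this noise level for pair "
            f"({roi_names[i]!r}, {roi_names[j]!r}): compensated r = {r_latent[i, j]:.3f}"
        )
    mix = _mixing_from_correlation(r_latent, roi_names)
    rng = np.random.default_rng(truth.seed)
    latents = _bandlimited_orthonormal_latents(n_frames, dt, len(roi_names), rng)
    region_signals = latents @ mix.T  # (n_frames, k), empirical corr == r_latent
    fluct = np.zeros((n_frames,) + tuple(phantom.spec.grid_shape))
    for i, name in enumerate(roi_names):
        m = phantom.atlas.region_mask(name)
        fluct[:, m] = truth.fluct_amp * region_signals[:, i][:, None]
    noise = truth.noise_sd * rng.standard_normal(fluct.shape)
    data = phantom.baseline[None, :, :] * (1.0 + fluct + np.where(phantom.mask, noise, 0.0))
    return PowerDopplerMovie(
        data=data,
        dt=dt,
        pixel_size=phantom.spec.pixel_size,
        mask=phantom.mask.copy(),
        t0=t0,
        slice_id=slice_id,
    )


def response_shape(
    kind: str,
    t_rel: np.ndarray,
    stim_duration: float,
    peak_time: float = 6.0,
    late_peak_delay: float = 5.0,
) -> np.ndarray:
    """Unit-peak temporal response shape, evaluated at times after block onset.

    * ``sustained``     — boxcar of height 1 over the stimulation window;
    * ``initial-peak``  — gamma-variate with its mode at ``peak_time`` s
      after onset (early transient that decays during the block);
    * ``late-peak``     — gamma-variate peaking ``late_peak_delay`` s after
      the stimulation offset (sharper, so it has decayed before the next
      block);
    * ``none``          — all zeros.
    """
    t = np.asarray(t_rel, dtype=float)
    if kind == "none":
        return np.zeros_like(t)
    if kind == "sustained":
        return ((t >= -1e-9) & (t < stim_duration - 1e-9)).astype(float)
    if kind == "initial-peak":
        tp, alpha = peak_time, 3.0
    elif kind == "late-peak":
        tp, alpha = stim_duration + late_peak_delay, 8.0
    else:
        raise ValueError(f"unknown response shape {kind!r}")
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tp
    out[pos] = x**alpha * np.exp(alpha * (1.0 - x))
    return out


def generate_stimulation_movie(
    phantom: Phantom,
    truth: GroundTruth,
    protocol: StimulationProtocol,
) -> tuple[PowerDopplerMovie, dict]:
    """Stimulation run with programmed block-locked %CBV responses.

    Responses are multiplicative on baseline: ``pd = baseline * (1 + a/100 *
    shape + noise)``.  Returns the movie plus a ground-truth dict per region
    with the programmed amplitude, shape label, stimulation-window mean %CBV
    and the block time-to-maximum on the frame grid.
    """
    for region in truth.programmed_response:
        if region not in phantom.atlas.region_names:
            raise ValueError(f"programmed response names unknown region {region!r}")
    t = protocol.frame_times
    n_frames = protocol.n_frames
    rng = np.random.default_rng(truth.seed)
    resp = np.zeros((n_frames,) + tuple(phantom.spec.grid_shape))
    gt: dict[str, dict] = {}
    # block-relative grid for ground-truth summaries
    n_block = int(round((protocol.stim_duration + protocol.post_rest) / protocol.dt))
    t_block = np.arange(n_block) * protocol.dt
    for region, (amp, kind) in truth.programmed_response.items():
        curve = np.zeros(n_frames)
        for onset in protocol.onsets:
            curve += response_shape(
                kind,
                t - onset,
                protocol.stim_duration,
                peak_time=truth.peak_time,
                late_peak_delay=truth.late_peak_delay,
            )
        m = phantom.atlas.region_mask(region)
        resp[:, m] = (amp / 100.0) * curve[:, None]
        shape_block = response_shape(
            kind,
            t_block,
            protocol.stim_duration,
            peak_time=truth.peak_time,
            late_peak_delay=truth.late_peak_delay,
        )
        in_stim = t_block < protocol.stim_duration - 1e-9
        gt[region] = {
            "amplitude_pct": amp,
            "shape": kind,
            "stim_mean_pct": float(amp * shape_block[in_stim].mean()) if kind != "none" else 0.0,
            "tmax_s": float(t_block[int(np.argmax(shape_block))]) if kind != "none" else np.nan,
        }
    noise = truth.noise_sd * rng.standard_normal(resp.shape)
    data = phantom.baseline[None, :, :] * (1.0 + resp + np.where(phantom.mask, noise, 0.0))
    movie = PowerDopplerMovie(
        data=data,
        dt=protocol.dt,
        pixel_size=phantom.spec.pixel_size,
        mask=phantom.mask.copy(),
    )
    return movie, gt


def generate_compound_stack(
    phantom: Phantom,
    n_frames: int = 200,
    frame_rate: float = 500.0,
    tissue_amp: float = 100.0,
    blood_amp: float = 1.0,
    seed: int = 0,
) -> tuple[CompoundFrameStack, np.ndarray]:
    """Raw compound-frame stack: tissue clutter plus blood signal.

    Tissue is a rank-1 space x time product (spatially coherent, slowly
    modulated in time, amplitude ``tissue_amp``); blood is confined to vessel
    pixels and decorrelates frame to frame (white in time, amplitude
    ``blood_amp`` scaled by a per-vessel strength).  Returns the stack and
    the realized ground-truth blood-power image (mean square of the blood
    component) for clutter-filter validation.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    # one slow modulation period across the stack; constant spatial pattern
    # keeps the tissue component exactly rank 1
    t_sig = 1.0 + 0.05 * np.sin(2.0 * np.pi * t / (n_frames / frame_rate))
    spatial = phantom.smooth_baseline / phantom.smooth_baseline.max()
    tissue = tissue_amp * t_sig[:, None, None] * spatial[None, :, :]
    blood = np.zeros_like(tissue)
    if blood_amp > 0 and phantom.vessel_mask.any():
        nv = int(phantom.vessel_mask.sum())
        strength = 0.5 + rng.random(nv)  # heterogeneous vessel amplitudes
        series = rng.standard_normal((n_frames, nv)) * (blood_amp * strength)[None, :]
        blood[:, phantom.vessel_mask] = series
    blood_power = (blood**2).mean(axis=0)
    stack = CompoundFrameStack(frames=tissue + blood, frame_rate=frame_rate)
    return stack, blood_power


def inject_motion(
    image: np.ndarray,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Apply a small rigid misalignment (rotation about the center, then a
    (row, col) translation) to a 2D image or to every frame of a movie."""
    img = np.asarray(image, dtype=float)
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    center = (np.array(img.shape[-2:]) - 1) / 2.0
    # ndimage pulls: output(x) = input(A x + offset); invert the forward map
    a_inv = rot.T
    offset = center - a_inv @ (center + np.asarray(translation))
    if img.ndim == 2:
        return ndimage.affine_transform(img, a_inv, offset=offset, order=order, mode="nearest")
    return np.stack(
        [
            ndimage.affine_transform(f, a_inv, offset=offset, order=order, mode="nearest")
            for f in img
        ]
    )


def generate_misaligned_cohort(
    phantom: Phantom,
    n_acquisitions: int = 8,
    max_translation: float = 3.0,
    max_rotation: float = 2.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[dict]]:
    """Copies of the phantom baseline under known small rigid misalignments.

    Exercises template registration: translations up to ``max_translation``
    pixels and rotations up to ``max_rotation`` degrees, drawn uniformly.
    Returns the images and the injected (dy, dx, rot) per acquisition; the
    first acquisition is left unmoved as an anchor.
    """
    rng = np.random.default_rng(seed)
    images, truths = [], []
    for i in range(n_acquisitions):
        if i == 0:
            dy = dx = rot = 0.0
        else:
            dy, dx = rng.uniform(-max_translation, max_translation, size=2)
            rot = rng.uniform(-max_rotation, max_rotation)
        images.append(inject_motion(phantom.baseline, (dy, dx), rot, order=3))
        truths.append({"dy": float(dy), "dx": float(dx), "rotation_deg": float(rot)})
    return images, truths


def null_group_table(
    rois: list[str],
    n_per_group: int = 7,
    groups: tuple[str, str] = ("SHR", "WKY"),
    sd: float = 1.0,
    seed: int = 0,
):
    """Long-form null ROI metric table: i.i.d. Gaussian values, no group
    effect — the input for statistical-calibration runs."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for a in range(n_per_group):
            for roi in rois:
                rows.append(
                    {
                        "animal": f"{g}_{a}",
                        "group": g,
                        "roi": roi,
                        "value": float(rng.normal(scale=sd)),
                    }
                )
    return pd.DataFrame(rows)
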