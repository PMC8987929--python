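"""Long-range resting-state functional connectivity.

ROI mean time-courses are extracted from band-pass-filtered (0.00067-0.13 Hz)
Power Doppler movies; interleaved two-slice runs are synchronized by
re-interpolating the second slice onto the first slice's time grid (the two
slices alternate, 1.4 s apart within the 2.8 s per-slice period).  Pairwise
Pearson correlations over 1-20 min of acquisition form the connectivity
matrix (the first minute is discarded); Fisher Z values back the group
statistics, and seed-based maps correlate a seed ROI's mean time-course with
every pixel.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import AtlasLabels, ConnectivityMatrix, PixelMap, PowerDopplerMovie, ROITimeCourse

__all__ = [
    "extract_roi_timecourses",
    "sync_slices",
    "correlation_matrix",
    "seed_map",
    "fisher_z",
    "group_mean_matrix",
]

_R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform, z = atanh(r), with |r| clipped
    to 1 - 1e-7 so perfectly correlated series stay finite."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def extract_roi_timecourses(
    movie: PowerDopplerMovie, atlas: AtlasLabels
) -> list[ROITimeCourse]:
    """Unweighted mean Power Doppler over each ROI's valid pixels, per frame.

    ROIs left empty after intersection with the movie's brain mask are
    excluded with a warning.
    """
    if atlas.labels.shape != movie.shape:
        raise ValueError("atlas is not aligned to the movie grid")
    out = []
    for name in atlas.region_names:
        roi = atlas.region_mask(name) & movie.mask
        if not roi.any():
            warnings.warn(f"ROI {name!r} empty after masking; excluded")
            continue
        out.append(
            ROITimeCourse(
                roi_name=name,
                values=movie.data[:, roi].mean(axis=1),
                timestamps=movie.timestamps,
                slice_id=movie.slice_id,
            )
        )
    return out


def sync_slices(
    tc1: ROITimeCourse, tc2: ROITimeCourse, offset: float
) -> tuple[ROITimeCourse, ROITimeCourse]:
    """Synchronize a second-slice time-course onto the first slice's grid.

    ``offset`` is the acquisition lag of slice 2 behind slice 1 within each
    period (half the per-slice period for strict interleaving, e.g. 1.4 s for
    2.8 s per-slice sampling).  The slice-2 series is shifted by the offset
    and linearly re-interpolated onto slice-1 timestamps; both series are
    trimmed to the overlapping interval.
    """
    period = float(np.median(np.diff(tc1.timestamps)))
    if offset >= period:
        raise ValueError(f"offset ({offset} s) must be < per-slice period ({period} s)")
    t2 = tc2.timestamps + offset
    lo, hi = max(tc1.timestamps[0], t2[0]), min(tc1.timestamps[-1], t2[-1])
    keep = (tc1.timestamps >= lo - 1e-9) & (tc1.timestamps <= hi + 1e-9)
    if keep.sum() < 2:
        raise ValueError("series share no usable overlap after the shift")
    t_common = tc1.timestamps[keep]
    v2 = np.interp(t_common, t2, tc2.values)
    return (
        ROITimeCourse(tc1.roi_name, tc1.values[keep], t_common, tc1.slice_id),
        ROITimeCourse(tc2.roi_name, v2, t_common, tc2.slice_id),
    )


def correlation_matrix(
    timecourses: list[ROITimeCourse],
    discard_initial: float = 60.0,
) -> ConnectivityMatrix:
    """Pairwise Pearson matrix over frames after the initial discard window.

    All time-courses must share one time grid (synchronize interleaved slices
    first).  Constant series get their row/column marked invalid (NaN) rather
    than poisoning the matrix.  Fisher Z is computed off-diagonal with the
    usual |r| clipping.
    """
    if len(timecourses) < 2:
        raise ValueError("need at least two time-courses")
    t0 = timecourses[0].timestamps
    for tc in timecourses[1:]:
        if len(tc.timestamps) != len(t0) or not np.allclose(tc.timestamps, t0):
            raise ValueError("time-courses are not on a common grid; run sync_slices first")
    keep = t0 >= (t0[0] + discard_initial - 1e-9)
    if keep.sum() < 32:
        raise ValueError(f"only {int(keep.sum())} frames left after discarding; need >= 32")
    x = np.stack([tc.values[keep] for tc in timecourses])
    sd = x.std(axis=1)
    valid = sd > 0
    r = np.full((len(timecourses),) * 2, np.nan)
    if valid.any():
        sub = np.corrcoef(x[valid])
        sub = np.clip((sub + sub.T) / 2.0, -1.0, 1.0)  # exact symmetry contract
        ii = np.flatnonzero(valid)
        r[np.ix_(ii, ii)] = sub
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        roi_names=[tc.roi_name for tc in timecourses],
        r=r,
        z=z,
        n_frames_used=int(keep.sum()),
    )


def seed_map(
    movie: PowerDopplerMovie,
    atlas: AtlasLabels,
    seed_roi: str,
    discard_initial: float = 0.0,
) -> PixelMap:
    """Per-pixel Pearson correlation with a seed ROI's mean time-course."""
    roi = atlas.region_mask(seed_roi) & movie.mask
    if not roi.any():
        raise ValueError(f"seed ROI {seed_roi!r} is empty")
    keep = movie.timestamps >= (movie.timestamps[0] + discard_initial - 1e-9)
    data = movie.data[keep]
    seed = data[:, roi].mean(axis=1)
    seed = seed - seed.mean()
    s_sd = seed.std()
    if s_sd == 0:
        raise ValueError("seed time-course is constant")
    px = data.reshape(data.shape[0], -1)
    px = px - px.mean(axis=0)
    px_sd = px.std(axis=0)
    valid = (px_sd > 0) & movie.mask.ravel()
    r = np.zeros(px.shape[1])
    r[valid] = (seed @ px[:, valid]) / (len(seed) * s_sd * px_sd[valid])
    return PixelMap(
        values=r.reshape(movie.shape), mask=valid.reshape(movie.shape), units="r"
    )


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group average: mean of Fisher-Z values, back-transformed to r for
    display (the group statistics themselves stay on the Z scale)."""
    if not matrices:
        raise ValueError("no matrices to average")
    names = matrices[0].roi_names
    for m in matrices[1:]:
        if m.roi_names != names:
            raise ValueError("matrices have differing ROI sets")
    z = np.nanmean(np.stack([m.z for m in matrices]), axis=0)
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        roi_names=names, r=r, z=z, n_frames_used=matrices[0].n_frames_used
    )
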