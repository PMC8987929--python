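"""Block-design visual stimulation: protocol timing and response quantification.

The stimulation paradigm is 30 s of initial rest followed by five repeats of
30 s flicker + 45 s rest (405 s total, one Power Doppler image every 0.4 s).
Responses are quantified as percent CBV change relative to the rest-period
baseline, summarized per ROI, averaged across the five blocks, and mapped
pixel-wise as activation Z maps and time-to-maximum (Tmax) maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import PixelMap, PowerDopplerMovie
from .stats import t_to_z

__all__ = [
    "StimulationProtocol",
    "build_protocol",
    "percent_cbv",
    "block_average",
    "tmax_map",
    "activation_map",
]

# rest frames this close after a stimulation offset are excluded from the
# baseline, to keep post-stimulus undershoot/late peaks out of the reference
DEFAULT_BASELINE_EXCLUSION_S = 5.0


@dataclass(frozen=True)
class StimulationProtocol:
    """Block-design timeline: initial rest, then n_blocks x (stim + rest)."""

    initial_rest: float
    stim_duration: float
    post_rest: float
    n_blocks: int
    dt: float

    @property
    def total_duration(self) -> float:
        return self.initial_rest + self.n_blocks * (self.stim_duration + self.post_rest)

    @property
    def n_frames(self) -> int:
        # frames at t = 0, dt, 2*dt, ... strictly inside [0, total_duration)
        return int(np.floor(self.total_duration / self.dt - 1e-9)) + 1

    @property
    def onsets(self) -> np.ndarray:
        """Stimulation onset times in seconds, strictly increasing."""
        return self.initial_rest + np.arange(self.n_blocks) * (self.stim_duration + self.post_rest)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def stim_mask(self) -> np.ndarray:
        """Boolean frame mask of stimulation periods, half-open [onset, offset)."""
        t = self.frame_times
        mask = np.zeros(self.n_frames, dtype=bool)
        for onset in self.onsets:
            mask |= (t >= onset - 1e-9) & (t < onset + self.stim_duration - 1e-9)
        return mask

    def rest_mask(self) -> np.ndarray:
        return ~self.stim_mask()

    def baseline_mask(self, exclusion_s: float = DEFAULT_BASELINE_EXCLUSION_S) -> np.ndarray:
        """Rest frames used as baseline: rest excluding ``exclusion_s`` seconds
        immediately after each stimulation offset."""
        t = self.frame_times
        mask = self.rest_mask()
        for onset in self.onsets:
            offset = onset + self.stim_duration
            mask &= ~((t >= offset - 1e-9) & (t < offset + exclusion_s - 1e-9))
        return mask


def build_protocol(
    initial_rest: float,
    stim_duration: float,
    post_rest: float,
    n_blocks: int,
    dt: float,
) -> StimulationProtocol:
    """Validated protocol constructor.

    Warns when ``dt`` does not divide the block durations to within one
    frame; frame masks then use nearest-frame rounding.
    """
    for name, v in (
        ("initial_rest", initial_rest),
        ("stim_duration", stim_duration),
        ("post_rest", post_rest),
        ("dt", dt),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    for name, v in (
        ("initial_rest", initial_rest),
        ("stim_duration", stim_duration),
        ("post_rest", post_rest),
    ):
        frac = (v / dt) % 1.0
        if min(frac, 1 - frac) > 1e-6:
            warnings.warn(
                f"{name}={v} s is not a multiple of dt={dt} s; block edges round to the nearest frame"
            )
    return StimulationProtocol(initial_rest, stim_duration, post_rest, int(n_blocks), dt)


def percent_cbv(
    series: np.ndarray,
    protocol: StimulationProtocol,
    baseline_exclusion_s: float = DEFAULT_BASELINE_EXCLUSION_S,
) -> np.ndarray:
    """Rest-normalized percent CBV change: 100 * (s - baseline) / baseline.

    ``series`` is a 1D time-course or a (time, ...) array.  The baseline is
    the mean over rest frames (excluding a short post-offset window); by
    construction the mean of the output over those frames is 0.
    """
    x = np.asarray(series, dtype=float)
    bmask = protocol.baseline_mask(baseline_exclusion_s)
    if bmask.sum() < 10:
        raise ValueError(f"need >= 10 rest frames for the baseline, have {int(bmask.sum())}")
    if x.shape[0] != protocol.n_frames:
        raise ValueError(
            f"series has {x.shape[0]} frames but the protocol defines {protocol.n_frames}"
        )
    baseline = x[bmask].mean(axis=0)
    if np.any(baseline <= 0):
        raise ValueError("rest-period baseline is non-positive; not a physical Doppler level")
    return 100.0 * (x - baseline) / baseline


def block_average(
    series: np.ndarray,
    protocol: StimulationProtocol,
    post_window: float = 15.0,
    pre_window: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Onset-locked average over the protocol's blocks.

    Returns ``(t_rel, mean)`` where ``t_rel`` runs from ``-pre_window`` to
    ``stim_duration + post_window`` and ``mean`` is the across-block mean of
    the epochs (per pixel if ``series`` is (time, ...)).  Epochs running past
    the end of the record are truncated (with a warning) to the common length.
    """
    x = np.asarray(series, dtype=float)
    n_pre = int(round(pre_window / protocol.dt))
    n_post = int(round((protocol.stim_duration + post_window) / protocol.dt))
    onset_idx = np.round(protocol.onsets / protocol.dt).astype(int)
    lengths = []
    for oi in onset_idx:
        if oi - n_pre < 0:
            raise ValueError("pre_window extends before the start of the record")
        lengths.append(min(n_post, x.shape[0] - oi))
    n_keep = min(lengths)
    if n_keep < n_post:
        warnings.warn("post_window extends past the record; epochs truncated to overlap")
    epochs = np.stack([x[oi - n_pre : oi + n_keep] for oi in onset_idx], axis=0)
    t_rel = (np.arange(-n_pre, n_keep)) * protocol.dt
    return t_rel, epochs.mean(axis=0)


def tmax_map(
    movie_pct: PowerDopplerMovie,
    protocol: StimulationProtocol,
    search_window: float | None = None,
) -> PixelMap:
    """Pixel-wise time to maximal CBV increase on the block-averaged response.

    ``movie_pct`` holds %CBV data.  For each pixel the five blocks are
    averaged and the argmax time within ``[0, search_window]`` after onset is
    reported in seconds (ties resolve to the earliest frame).  The default
    window spans the stimulation plus 15 s of the following rest, where late
    peaks are expected.
    """
    if search_window is None:
        search_window = protocol.stim_duration + 15.0
    post = max(0.0, search_window - protocol.stim_duration)
    t_rel, avg = block_average(movie_pct.data, protocol, post_window=post)
    sel = (t_rel >= 0) & (t_rel <= search_window + 1e-9)
    t_sel = t_rel[sel]
    avg_sel = avg[sel]
    valid = np.isfinite(avg_sel).all(axis=0) & movie_pct.mask
    idx = np.argmax(np.where(np.isfinite(avg_sel), avg_sel, -np.inf), axis=0)
    values = t_sel[idx]
    return PixelMap(values=np.where(valid, values, 0.0), mask=valid, units="s")


def activation_map(
    cohort_pct: list[PowerDopplerMovie],
    protocol: StimulationProtocol,
    p_threshold: float = 0.001,
) -> tuple[PixelMap, np.ndarray]:
    """Pixel-based activation statistics across animals.

    For each animal the per-pixel effect is the mean %CBV over stimulation
    frames minus the mean over baseline rest frames.  A one-sample t statistic
    across animals is converted to Z by probability matching and thresholded
    two-sided at ``p_threshold``.  Returns the Z map and the significance mask.
    """
    if len(cohort_pct) < 3:
        raise ValueError("need at least 3 animals for the pixel-based statistics")
    smask = protocol.stim_mask()
    bmask = protocol.baseline_mask()
    effects = np.stack(
        [m.data[smask].mean(axis=0) - m.data[bmask].mean(axis=0) for m in cohort_pct], axis=0
    )
    mask = np.logical_and.reduce([m.mask for m in cohort_pct])
    n = effects.shape[0]
    mean = effects.mean(axis=0)
    sd = effects.std(axis=0, ddof=1)
    valid = mask & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, mean / (sd / np.sqrt(n)), 0.0)
    z = np.where(valid, t_to_z(t, n - 1), 0.0)
    z_crit = sstats.norm.isf(p_threshold / 2.0)
    sig = valid & (np.abs(z) > z_crit)
    return PixelMap(values=z, mask=valid, units="Z"), sig
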