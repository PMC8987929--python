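"""Local functional connectivity: coherence-based regional homogeneity (ReHo)
and fractional amplitude of low-frequency fluctuations (fALFF).

ReHo here is spectral: for a pixel and its eight neighbors, the magnitude-
squared coherence of every unordered pixel pair is computed from Welch
band-averaged cross- and power-spectra in the 0.01-0.08 Hz band, averaged
over the 36 pairs of the 3x3 cluster, and assigned to the center pixel.
Maps are expressed as Z scores over the brain mask.  fALFF is the fraction of
the amplitude spectrum falling inside the same band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import PixelMap, PowerDopplerMovie
from .filters import gaussian_smooth
from .stats import one_sample_z_map

__all__ = [
    "SpectralConfig",
    "band_coherence",
    "reho_map",
    "zscore_map",
    "falff_map",
    "group_reho_stat_map",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimation settings for the coherence band.

    Defaults: Hann window of 64 samples, 50% overlap, linear detrending per
    segment, band 0.01-0.08 Hz with inclusive edges.
    """

    band: tuple[float, float] = (0.01, 0.08)
    welch_window: int = 64
    welch_overlap: float = 0.5
    detrend: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        if not 0.0 <= self.welch_overlap <= 0.9:
            raise ValueError("welch_overlap must lie in [0, 0.9]")
        if self.welch_window < 8:
            raise ValueError("welch_window too small")

    @property
    def noverlap(self) -> int:
        return int(round(self.welch_overlap * self.welch_window))

    def band_bins(self, dt: float) -> np.ndarray:
        freqs = np.fft.rfftfreq(self.welch_window, d=dt)
        lo, hi = self.band
        if hi >= 0.5 / dt + 1e-12:
            raise ValueError(f"band upper edge {hi} Hz >= Nyquist ({0.5 / dt:.6g} Hz)")
        sel = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
        if not sel.any():
            raise ValueError(
                f"no frequency bin inside band [{lo}, {hi}] Hz at resolution "
                f"{freqs[1]:.6g} Hz (window {self.welch_window}, dt {dt})"
            )
        return sel


def _check_lengths(n: int, cfg: SpectralConfig) -> None:
    if n < 2 * cfg.welch_window:
        raise ValueError(
            f"series length {n} must be >= 2x the Welch window ({cfg.welch_window})"
        )


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    cfg: SpectralConfig = SpectralConfig(),
    pointwise: bool = False,
) -> float:
    """Band-averaged magnitude-squared coherence of two series in [0, 1].

    Default reading (band-averaged estimates of the spectra):

        Coh = |<Sxy>_band|^2 / (<Sxx>_band * <Syy>_band)

    where ``< >_band`` averages the Welch estimates over the in-band
    frequency bins.  With ``pointwise=True`` the per-bin coherence
    |Sxy(f)|^2/(Sxx(f) Syy(f)) is averaged over the band instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    _check_lengths(len(x), cfg)
    sel = cfg.band_bins(dt)
    detrend = "linear" if cfg.detrend else "constant"
    kw = dict(
        fs=1.0 / dt,
        window="hann",
        nperseg=cfg.welch_window,
        noverlap=cfg.noverlap,
        detrend=detrend,
    )
    _, sxy = signal.csd(x, y, **kw)
    _, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    if pointwise:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(sxy[sel]) ** 2 / (sxx[sel] * syy[sel])
        return float(np.mean(c))
    num = np.abs(sxy[sel].mean()) ** 2
    den = sxx[sel].mean() * syy[sel].mean()
    if den == 0:
        raise ValueError("zero in-band power; coherence undefined")
    return float(num / den)


def _segment_spectra(data: np.ndarray, dt: float, cfg: SpectralConfig) -> np.ndarray:
    """Windowed, detrended per-segment rFFT of (..., time) data, scaled
    exactly as scipy's Welch/CSD machinery (so cross-products of these
    spectra reproduce ``scipy.signal.csd`` bin for bin)."""
    n = data.shape[-1]
    _check_lengths(n, cfg)
    nperseg = cfg.welch_window
    step = nperseg - cfg.noverlap
    nseg = (n - nperseg) // step + 1
    idx = np.arange(nperseg)[None, :] + step * np.arange(nseg)[:, None]
    segs = data[..., idx]  # (..., nseg, nperseg)
    if cfg.detrend:
        segs = signal.detrend(segs, type="linear", axis=-1)
    else:
        segs = segs - segs.mean(axis=-1, keepdims=True)
    win = signal.get_window("hann", nperseg)
    f = np.fft.rfft(segs * win, axis=-1)
    # scipy scaling: 1/(fs * sum(win^2)), one-sided doubling except DC/Nyquist
    scale = dt / (win * win).sum()
    d = np.full(f.shape[-1], 2.0)
    d[0] = 1.0
    if nperseg % 2 == 0:
        d[-1] = 1.0
    return f * np.sqrt(scale * d)


def reho_map(
    movie: PowerDopplerMovie,
    cfg: SpectralConfig = SpectralConfig(),
    pointwise: bool = False,
) -> PixelMap:
    """Regional homogeneity: mean band coherence over the 36 unordered pixel
    pairs of each 3x3 cluster, assigned to the center pixel (values in [0,1],
    before Z-scoring).

    At mask edges the cluster is truncated to its valid in-mask members and
    the mean runs over the remaining pairs; centers with fewer than 3 valid
    cluster pixels are masked out.
    """
    t, h, w = movie.data.shape
    data = np.moveaxis(movie.data, 0, -1)  # (H, W, T)
    sel = cfg.band_bins(movie.dt)
    spec = _segment_spectra(data, movie.dt, cfg)[..., sel]  # (H, W, nseg, nb)
    pxx = (np.abs(spec) ** 2).mean(axis=2)  # (H, W, nb): Welch PSD per pixel
    mean_pxx = pxx.mean(axis=-1)  # <Sxx>_band
    nb = spec.shape[-1]

    pad = [(1, 1), (1, 1)] + [(0, 0)] * (spec.ndim - 2)
    spec_p = np.pad(spec, pad)
    pxx_p = np.pad(pxx, [(1, 1), (1, 1), (0, 0)])
    mean_pxx_p = np.pad(mean_pxx, 1)
    mask_p = np.pad(movie.mask, 1)

    def view(a, o):
        return a[1 + o[0] : 1 + o[0] + h, 1 + o[1] : 1 + o[1] + w]

    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    member_count = np.sum([view(mask_p, o) for o in offsets], axis=0)
    coh_sum = np.zeros((h, w))
    pair_count = np.zeros((h, w))
    for i, o1 in enumerate(offsets):
        s1, m1 = view(spec_p, o1), view(mask_p, o1)
        p1, mp1 = view(pxx_p, o1), view(mean_pxx_p, o1)
        for o2 in offsets[i + 1 :]:
            s2, m2 = view(spec_p, o2), view(mask_p, o2)
            valid = m1 & m2
            if not valid.any():
                continue
            sxy = (np.conj(s1) * s2).mean(axis=2)  # (H, W, nb) cross-spectrum
            with np.errstate(divide="ignore", invalid="ignore"):
                if pointwise:
                    p2 = view(pxx_p, o2)
                    coh = (np.abs(sxy) ** 2 / (p1 * p2)).sum(axis=-1) / nb
                else:
                    mp2 = view(mean_pxx_p, o2)
                    coh = np.abs(sxy.mean(axis=-1)) ** 2 / (mp1 * mp2)
            coh_sum[valid] += coh[valid]
            pair_count[valid] += 1
    out_mask = movie.mask & (member_count >= 3) & (pair_count >= 1)
    values = np.zeros((h, w))
    values[out_mask] = coh_sum[out_mask] / pair_count[out_mask]
    return PixelMap(values=values, mask=out_mask, units="coherence")


def zscore_map(pmap: PixelMap, mask: np.ndarray | None = None) -> PixelMap:
    """Express a map as Z scores over the mask: subtract the in-mask mean and
    divide by the in-mask (population) standard deviation."""
    mask = pmap.mask if mask is None else (np.asarray(mask, dtype=bool) & pmap.mask)
    vals = pmap.values[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 valid pixels to Z-score")
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant map: cannot Z-score (zero standard deviation)")
    z = np.zeros_like(pmap.values)
    z[mask] = (pmap.values[mask] - vals.mean()) / sd
    return PixelMap(values=z, mask=mask, units="Z")


def falff_map(
    movie: PowerDopplerMovie,
    band: tuple[float, float] = (0.01, 0.08),
    mask: np.ndarray | None = None,
) -> PixelMap:
    """Fractional amplitude of low-frequency fluctuations.

    Per pixel: sum of the amplitude spectrum (|rFFT|) over the band divided by
    the sum over all positive frequencies (DC excluded); values in [0, 1].
    All-zero series are masked out.
    """
    lo, hi = band
    t = movie.n_frames
    freqs = np.fft.rfftfreq(t, d=movie.dt)
    sel_band = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12) & (freqs > 0)
    sel_all = freqs > 0
    if sel_band.sum() < 3:
        raise ValueError(
            f"series supports only {int(sel_band.sum())} bins in [{lo}, {hi}] Hz; need >= 3"
        )
    mask = movie.mask if mask is None else (np.asarray(mask, dtype=bool) & movie.mask)
    data = movie.data - movie.data.mean(axis=0)
    amp = np.abs(np.fft.rfft(data, axis=0))
    total = amp[sel_all].sum(axis=0)
    inband = amp[sel_band].sum(axis=0)
    valid = mask & (total > 0)
    values = np.zeros(movie.shape)
    values[valid] = inband[valid] / total[valid]
    return PixelMap(values=values, mask=valid, units="fraction")


def group_reho_stat_map(
    maps: list[PixelMap],
    fwhm_mm: float = 0.3,
    pixel_size: float = 0.1,
    p_threshold: float = 0.001,
) -> tuple[PixelMap, np.ndarray]:
    """Group statistics of per-animal ReHo Z maps.

    Each animal's map is Gaussian-smoothed (default 0.3 mm FWHM), a one-sample
    t test is run per pixel across animals, converted to a Z map by
    probability matching and thresholded two-sided at ``p_threshold``.
    Inconsistent masks are intersected with a warning.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 animals")
    mask = np.logical_and.reduce([m.mask for m in maps])
    if any(not np.array_equal(m.mask, mask) for m in maps):
        warnings.warn("inconsistent per-animal masks; using their intersection")
    smoothed = np.stack(
        [gaussian_smooth(m.values, fwhm_mm, pixel_size, mask) for m in maps]
    )
    z, valid, sig = one_sample_z_map(smoothed, mask, p_threshold=p_threshold)
    return PixelMap(values=z, mask=valid, units="Z"), sig
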