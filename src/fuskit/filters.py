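"""Temporal filtering and spatial smoothing.

Three temporal band settings are used by the pipeline:

* ``stim``  — 0.0025 Hz Butterworth high-pass plus a Gaussian low-pass with
  half-power point at 0.0375 Hz, applied to stimulation runs before
  %CBV quantification;
* ``fc``    — 0.00067–0.13 Hz band-pass for long-range functional
  connectivity;
* ``reho``  — 0.01–0.08 Hz, applied in the spectral domain only (the band
  over which coherence and fALFF are evaluated, not a time-domain filter).

All time-domain filters are zero-phase (forward-backward Butterworth, or a
real non-negative frequency-domain gain for the Gaussian low-pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = ["BandSpec", "BAND_PRESETS", "temporal_filter", "gaussian_smooth", "fwhm_to_sigma"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class BandSpec:
    """Temporal band definition.

    highpass_cut / lowpass_cut are in Hz (``None`` disables that edge);
    ``lowpass_kind`` selects a 4th-order Butterworth or a Gaussian gain with
    half-power (-3 dB) at the cutoff.
    """

    highpass_cut: float | None = None
    lowpass_cut: float | None = None
    lowpass_kind: str = "butterworth"

    def __post_init__(self) -> None:
        if self.lowpass_kind not in ("butterworth", "gaussian-half-power"):
            raise ValueError(f"unknown lowpass_kind {self.lowpass_kind!r}")
        if self.highpass_cut is not None and self.highpass_cut < 0:
            raise ValueError("highpass_cut must be >= 0")
        if (
            self.highpass_cut is not None
            and self.lowpass_cut is not None
            and not self.highpass_cut < self.lowpass_cut
        ):
            raise ValueError("need highpass_cut < lowpass_cut")

    def validate_against(self, dt: float) -> None:
        nyquist = 0.5 / dt
        for name, cut in (("highpass_cut", self.highpass_cut), ("lowpass_cut", self.lowpass_cut)):
            if cut is not None and cut >= nyquist:
                raise ValueError(
                    f"{name}={cut} Hz violates {name} < Nyquist ({nyquist:.6g} Hz at dt={dt} s)"
                )


BAND_PRESETS: dict[str, BandSpec] = {
    # stimulation runs: 0.0025 Hz HP + Gaussian LP, half power at 0.0375 Hz
    "stim": BandSpec(highpass_cut=0.0025, lowpass_cut=0.0375, lowpass_kind="gaussian-half-power"),
    # long-range functional connectivity band
    "fc": BandSpec(highpass_cut=0.00067, lowpass_cut=0.13, lowpass_kind="butterworth"),
    # ReHo / fALFF analysis band (spectral-domain only)
    "reho": BandSpec(highpass_cut=0.01, lowpass_cut=0.08, lowpass_kind="butterworth"),
}


def _gaussian_lowpass(x: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass: |H(fc)|^2 = 1/2 (half power at cutoff).

    Applied in the frequency domain on a reflect-padded copy so edges are not
    wrapped.  The gain is real and non-negative, hence exactly zero-phase.
    """
    n = x.shape[0]
    pad = n  # reflect by a full record: generous relative to any filter length
    xp = np.concatenate([x[pad - 1 :: -1], x, x[: -pad - 1 : -1]], axis=0)
    freqs = np.fft.rfftfreq(xp.shape[0], d=dt)
    gain = np.exp(-0.5 * _LN2 * (freqs / cutoff) ** 2)
    shape = (len(freqs),) + (1,) * (x.ndim - 1)
    spec = np.fft.rfft(xp, axis=0) * gain.reshape(shape)
    out = np.fft.irfft(spec, n=xp.shape[0], axis=0)
    return out[pad : pad + n]


def temporal_filter(series: np.ndarray, dt: float, band: BandSpec) -> np.ndarray:
    """Zero-phase temporal filtering along axis 0.

    ``series`` may be a 1D time-course or a (time, ...) array; the output has
    the same shape.  High-pass and Butterworth low-pass edges are 4th-order
    Butterworth run forward-backward (``sosfiltfilt``); a Gaussian low-pass is
    a real frequency-domain gain with half-power at the cutoff.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 9:
        raise ValueError("series too short to filter (need >= 9 samples)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    band.validate_against(dt)
    fs = 1.0 / dt
    out = x
    if band.highpass_cut is not None and band.highpass_cut > 0:
        sos = signal.butter(4, band.highpass_cut, btype="highpass", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=0, padtype="even")
    if band.lowpass_cut is not None:
        if band.lowpass_kind == "gaussian-half-power":
            out = _gaussian_lowpass(out, dt, band.lowpass_cut)
        else:
            sos = signal.butter(4, band.lowpass_cut, btype="lowpass", fs=fs, output="sos")
            out = signal.sosfiltfilt(sos, out, axis=0, padtype="even")
    return out


def fwhm_to_sigma(fwhm_mm: float, pixel_size: float) -> float:
    """Gaussian sigma in pixels for a given FWHM in mm."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * _LN2)) / pixel_size


def gaussian_smooth(
    values: np.ndarray,
    fwhm_mm: float,
    pixel_size: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-aware 2D Gaussian smoothing with the stated FWHM (in mm).

    Uses normalized convolution so that pixels outside the mask neither leak
    into nor dilute the smoothed map, then restores the in-mask mean (the
    smoothing is meant to trade variance for bias locally, not to shift the
    map's DC level).  Constant maps pass through unchanged.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    x = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(x, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sigma = fwhm_to_sigma(fwhm_mm, pixel_size)
    if sigma < 0.1:
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below 0.1 pixel (sigma={sigma:.3g} px); returning input unchanged"
        )
        return x.copy()
    m = mask.astype(float)
    num = ndimage.gaussian_filter(np.where(mask, x, 0.0), sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant")
    out = np.zeros_like(x)
    good = den > 1e-12
    out[good] = num[good] / den[good]
    if mask.any():
        out[mask] += x[mask].mean() - out[mask].mean()
    out[~mask] = x[~mask]
    return out
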