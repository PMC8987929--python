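"""Core in-memory containers for 2D+t functional ultrasound data.

A functional ultrasound (fUS) acquisition is a single coronal slice imaged
repeatedly: a stack of Power Doppler images whose per-pixel intensity is
taken as proportional to cerebral blood volume (CBV).  Everything downstream
(evoked-response quantification, connectivity, regional homogeneity) operates
on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PowerDopplerMovie",
    "AtlasLabels",
    "PixelMap",
    "ROITimeCourse",
    "ConnectivityMatrix",
    "CompoundFrameStack",
]


@dataclass
class PowerDopplerMovie:
    """One registered 2D+t Power Doppler acquisition.

    Parameters
    ----------
    data : ndarray, shape (n_frames, rows, cols)
        Power Doppler intensity per frame (arbitrary units, non-negative).
    dt : float
        Frame interval in seconds (0.4 s for stimulation runs, 2.8 s per
        slice for interleaved resting-state runs).
    pixel_size : float
        In-plane pixel size in mm.
    mask : ndarray of bool, shape (rows, cols)
        Brain mask; pixels outside are ignored by every analysis.
    slice_coord : float
        Anterior-posterior coordinate of the slice relative to bregma (mm).
    t0 : float
        Acquisition time of the first frame in seconds.  Non-zero for the
        second slice of an interleaved resting-state run.
    slice_id : int
        Identifier of the imaging plane within an interleaved run.
    """

    data: np.ndarray
    dt: float
    pixel_size: float = 0.1
    mask: np.ndarray | None = None
    slice_coord: float = 0.0
    t0: float = 0.0
    slice_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (n_frames, rows, cols), got {self.data.shape}")
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape does not match frame shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return self.t0 + np.arange(self.n_frames) * self.dt

    def with_data(self, data: np.ndarray) -> "PowerDopplerMovie":
        """Copy of this movie with a new data array (same geometry/timing)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class AtlasLabels:
    """Integer label image plus region-name table for one coronal slice."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be an integer image")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without a name entry: {sorted(missing)}")

    @property
    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]

    def region_mask(self, name: str) -> np.ndarray:
        for label, nm in self.names.items():
            if nm == name:
                return self.labels == label
        raise KeyError(f"region {name!r} not in atlas")

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": sorted(self.names), "name": [self.names[k] for k in sorted(self.names)]}
        )


@dataclass
class PixelMap:
    """A per-pixel scalar map (ReHo Z, fALFF fraction, Tmax seconds, activation Z)."""

    values: np.ndarray
    mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ROITimeCourse:
    """Mean Power Doppler over one ROI's pixels, per frame."""

    roi_name: str
    values: np.ndarray
    timestamps: np.ndarray
    slice_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps lengths differ")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ConnectivityMatrix:
    """ROI x ROI Pearson correlations with Fisher-Z values."""

    roi_names: list[str]
    r: np.ndarray
    z: np.ndarray
    n_frames_used: int = 0

    def to_long_table(self) -> pd.DataFrame:
        rows = []
        k = len(self.roi_names)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "roi_a": self.roi_names[i],
                        "roi_b": self.roi_names[j],
                        "r": self.r[i, j],
                        "z": self.z[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CompoundFrameStack:
    """Stack of compound plane-wave frames acquired at high frame rate.

    One Power Doppler image is formed from one such stack after SVD clutter
    filtering (e.g. 200 frames at 500 Hz -> one image per 0.4 s).
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Temporal span of the stack in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    def casorati(self) -> np.ndarray:
        """(pixels x time) Casorati matrix view of the stack."""
        t = self.frames.shape[0]
        return self.frames.reshape(t, -1).T
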