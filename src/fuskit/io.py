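"""Reading and writing of movies, atlases, maps and tables.

Movies are stored as NIfTI (rows x cols x 1 x time, uncompressed so that
byte-identical reruns are checksum-stable) or as multi-page TIFF; atlases as
integer-label NIfTI plus a TSV name table; scalar maps as NIfTI; ground truth
and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import AtlasLabels, PixelMap, PowerDopplerMovie

__all__ = [
    "save_movie_nifti",
    "load_movie_nifti",
    "save_movie_tiff",
    "load_movie_tiff",
    "save_atlas",
    "load_atlas",
    "save_map",
    "load_map",
    "save_json",
    "load_json",
]


def _affine(pixel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_size
    return aff


def save_movie_nifti(movie: PowerDopplerMovie, path: str | Path) -> Path:
    path = Path(path)
    # NIfTI spatial axes first: (rows, cols, 1, time)
    vol = np.transpose(movie.data, (1, 2, 0))[:, :, None, :]
    img = nib.Nifti1Image(vol.astype(np.float32), _affine(movie.pixel_size))
    img.header["pixdim"][4] = movie.dt
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    meta = {
        "dt": movie.dt,
        "pixel_size": movie.pixel_size,
        "slice_coord": movie.slice_coord,
        "t0": movie.t0,
        "slice_id": movie.slice_id,
    }
    sidecar = path.with_suffix(".json") if path.suffix == ".nii" else Path(str(path) + ".json")
    save_json(meta, sidecar)
    _save_mask(movie.mask, path)
    return path


def _mask_path(path: Path) -> Path:
    return path.with_name(path.stem + "_mask" + path.suffix)


def _save_mask(mask: np.ndarray, movie_path: Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4))
    nib.save(img, str(_mask_path(movie_path)))


def load_movie_nifti(path: str | Path) -> PowerDopplerMovie:
    path = Path(path)
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim == 4:
        data = np.transpose(vol[:, :, 0, :], (2, 0, 1))
    elif vol.ndim == 3:
        data = np.transpose(vol, (2, 0, 1))
    else:
        raise ValueError(f"expected a 2D+t NIfTI, got shape {vol.shape}")
    sidecar = path.with_suffix(".json") if path.suffix == ".nii" else Path(str(path) + ".json")
    meta = load_json(sidecar) if sidecar.exists() else {}
    mask = None
    mpath = _mask_path(path)
    if mpath.exists():
        mask = np.asarray(nib.load(str(mpath)).dataobj) > 0
    return PowerDopplerMovie(
        data=data,
        dt=float(meta.get("dt", img.header["pixdim"][4] or 1.0)),
        pixel_size=float(meta.get("pixel_size", abs(img.affine[0, 0]) or 0.1)),
        mask=mask,
        slice_coord=float(meta.get("slice_coord", 0.0)),
        t0=float(meta.get("t0", 0.0)),
        slice_id=int(meta.get("slice_id", 0)),
    )


def save_movie_tiff(movie: PowerDopplerMovie, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(str(path), movie.data.astype(np.float32))
    return path


def load_movie_tiff(path: str | Path, dt: float, pixel_size: float = 0.1) -> PowerDopplerMovie:
    data = tifffile.imread(str(path))
    return PowerDopplerMovie(data=np.asarray(data, dtype=float), dt=dt, pixel_size=pixel_size)


def save_atlas(atlas: AtlasLabels, label_path: str | Path, table_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(label_path))
    atlas.to_table().to_csv(table_path, sep="\t", index=False)


def load_atlas(label_path: str | Path, table_path: str | Path) -> AtlasLabels:
    labels = np.asarray(nib.load(str(label_path)).dataobj).astype(np.int64)
    table = pd.read_csv(table_path, sep="\t")
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return AtlasLabels(labels=labels, names=names)


def save_map(pmap: PixelMap, path: str | Path) -> Path:
    path = Path(path)
    data = np.where(pmap.mask, pmap.values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(data, np.eye(4))
    img.header["descrip"] = pmap.units.encode()[:79]
    nib.save(img, str(path))
    return path


def load_map(path: str | Path) -> PixelMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    mask = np.isfinite(values)
    units = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    return PixelMap(values=np.nan_to_num(values), mask=mask, units=units)


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
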