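"""TIFF stack and CSV table input/output.

Stacks are read and written as multi-page grayscale TIFF with one page per
z-slice.  Voxel spacing is taken from the ImageJ-style metadata when present
(``spacing`` for dz, X/Y resolution tags for dx/dy) and defaults to isotropic
unit spacing otherwise.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InputFormatError, ValidationError
from .image import IntensityImage, Spacing

TABLE_COLUMNS = [
    "id",
    "cz",
    "cy",
    "cx",
    "cz_um",
    "cy_um",
    "cx_um",
    "volume_voxels",
    "volume_um3",
    "mean_intensity",
]


def _spacing_from_tiff(tif: tifffile.TiffFile) -> Spacing | None:
    """Best-effort spacing extraction from ImageJ metadata and resolution tags."""
    dz = dy = dx = None
    meta = tif.imagej_metadata
    if meta and "spacing" in meta:
        dz = float(meta["spacing"])
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None:
        num, den = xres.value
        if num:
            dx = den / num
    if yres is not None:
        num, den = yres.value
        if num:
            dy = den / num
    if dz is None and dy is None and dx is None:
        return None
    return (dz or 1.0, dy or 1.0, dx or 1.0)


def read_stack(path: os.PathLike | str, spacing: Spacing | None = None) -> IntensityImage:
    """Read a single- or multi-page TIFF as a (z, y, x) intensity image.

    A 2D image is promoted to shape ``(1, Y, X)``.  ``spacing`` overrides any
    spacing found in file metadata; when neither is available the spacing is
    ``(1, 1, 1)``.
    """
    try:
        with tifffile.TiffFile(os.fspath(path)) as tif:
            vox = tif.asarray()
            file_spacing = _spacing_from_tiff(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise InputFormatError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    if vox.ndim == 2:
        vox = vox[np.newaxis]
    if vox.ndim != 3:
        raise InputFormatError(
            f"{path!r}: expected 2 or 3 dimensions, got shape {vox.shape}"
        )
    if not (np.issubdtype(vox.dtype, np.integer) or np.issubdtype(vox.dtype, np.floating)):
        raise InputFormatError(f"{path!r}: unsupported sample format {vox.dtype}")
    if spacing is None:
        spacing = file_spacing or (1.0, 1.0, 1.0)
    return IntensityImage(vox, spacing)


def write_stack(path: os.PathLike | str, img: IntensityImage | np.ndarray) -> None:
    """Write a 3D grayscale stack as a multi-page TIFF, one page per z-slice."""
    vox = img.voxels if isinstance(img, IntensityImage) else np.asarray(img)
    tifffile.imwrite(os.fspath(path), vox, photometric="minisblack")


def write_labels(path: os.PathLike | str, labels: np.ndarray) -> None:
    """Write a component matrix as a multi-page TIFF.

    Output is 16-bit when the largest label fits, otherwise 32-bit; labels
    above 32-bit unsigned are rejected.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValidationError(f"label grid must be 3D, got ndim={labels.ndim}")
    maxlab = int(labels.max()) if labels.size else 0
    if maxlab >= 2**32:
        raise ValidationError(f"max label {maxlab} exceeds 32-bit unsigned range")
    dtype = np.uint16 if maxlab < 65536 else np.uint32
    tifffile.imwrite(os.fspath(path), labels.astype(dtype), photometric="minisblack")


def read_labels(path: os.PathLike | str) -> np.ndarray:
    """Read a label volume written by :func:`write_labels`."""
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return arr.astype(np.int64)


def export_table(records: Sequence, path: os.PathLike | str) -> None:
    """Write per-nucleus features as CSV, one row per record, sorted by id."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "cz": r.centroid[0],
                "cy": r.centroid[1],
                "cx": r.centroid[2],
                "cz_um": r.centroid_um[0],
                "cy_um": r.centroid_um[1],
                "cx_um": r.centroid_um[2],
                "volume_voxels": r.volume_voxels,
                "volume_um3": r.volume_um3,
                "mean_intensity": r.mean_intensity,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValidationError(f"duplicate record ids: {dupes}")
    df = df.sort_values("id")
    df.to_csv(os.fspath(path), index=False)


def read_centroids(path: os.PathLike | str) -> np.ndarray:
    """Read a centroid CSV (columns id, cz, cy, cx) into an (n, 3) array."""
    df = pd.read_csv(os.fspath(path))
    missing = {"cz", "cy", "cx"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path!r}: missing centroid columns {sorted(missing)}")
    return df[["cz", "cy", "cx"]].to_numpy(float)
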