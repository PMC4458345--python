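"""Core voxel-grid containers and conventions.

Every array in the package is indexed ``(z, y, x)``, 0-based, with voxel
centers at integer coordinates.  Physical spacing ``(dz, dy, dx)`` in
micrometres per voxel is carried as metadata and used only when reporting
physical volumes and centroids; all geometry (distances, neighborhoods,
visibility sampling) operates in voxel units.

Binary masks are plain ``bool`` ndarrays and label grids ("component
matrices") are plain non-negative integer ndarrays with 0 as background —
the scikit-image convention — rather than wrapper classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

Spacing = tuple[float, float, float]


@dataclass(frozen=True)
class IntensityImage:
    """A 3D grayscale stack with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Non-negative, finite scalar intensities.
    spacing : (dz, dy, dx), optional
        Micrometres per voxel along each axis, all strictly positive.
        Defaults to isotropic unit spacing.
    """

    voxels: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValidationError(f"voxels must be 3D (z, y, x), got ndim={vox.ndim}")
        if vox.size == 0:
            raise ValidationError("voxels must be non-empty")
        if np.issubdtype(vox.dtype, np.floating):
            if not np.isfinite(vox).all():
                raise ValidationError("voxels contain non-finite values")
        elif not np.issubdtype(vox.dtype, np.integer):
            raise ValidationError(f"unsupported voxel dtype {vox.dtype}")
        if (vox < 0).any():
            raise ValidationError("voxels contain negative values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


def as_voxels(img) -> np.ndarray:
    """Return the raw (z, y, x) array of an IntensityImage or pass an array through."""
    if isinstance(img, IntensityImage):
        return img.voxels
    vox = np.asarray(img)
    if vox.ndim != 3:
        raise ValidationError(f"expected a 3D array, got ndim={vox.ndim}")
    return vox


def check_binary(mask) -> np.ndarray:
    """Validate and return a 3D boolean mask."""
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise ValidationError(f"binary mask must be 3D, got ndim={arr.ndim}")
    if arr.dtype != bool:
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("binary mask has values outside {0, 1}")
        arr = arr.astype(bool)
    return arr
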