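"""Voxel-grid containers, TIFF stack I/O and image preprocessing.

Everything downstream (seeding, ellipsoid fitting, EF maps, SMI meshes)
operates on the two containers defined here: a grayscale :class:`VoxelVolume`
and a boolean :class:`BinaryVolume`, both on an isotropic grid indexed
``(z, y, x)`` with voxel centres at integer coordinates.  Out-of-grid space
is treated as background throughout the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "BinaryVolume",
    "read_stack",
    "write_stack",
    "median_filter_3d",
    "threshold",
    "bone_volume_fraction",
    "distance_transform",
]

_SPACING_RTOL = 1e-6


def _as_isotropic_spacing(spacing) -> float:
    """Validate spacing: a positive scalar, or a length-3 sequence of equal values.

    Anisotropic voxels are not supported; mixed spacings raise instead of
    silently mis-scaling the geometry.
    """
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size not in (1, 3):
        raise ValueError(f"spacing must be a scalar or length-3, got {arr.size} values")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"spacing must be positive and finite, got {spacing!r}")
    if arr.size == 3 and (arr.max() - arr.min()) > _SPACING_RTOL * arr.max():
        raise ValueError(
            f"anisotropic voxels are not supported (spacing {arr.tolist()}); "
            "resample to an isotropic grid first"
        )
    return float(arr[0])


@dataclasses.dataclass(frozen=True)
class VoxelVolume:
    """A 3D grid of scalar intensities with isotropic voxel spacing.

    ``data`` is indexed ``(z, y, x)``; ``spacing`` is the voxel edge length
    (same unit on all axes, e.g. mm).  All geometry in the package works in
    voxel units; ``spacing`` scales reported lengths/volumes only.
    """

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ValueError(f"every axis must have length >= 1, got {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _as_isotropic_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass(frozen=True)
class BinaryVolume:
    """A 3D boolean grid (True = bone foreground) with isotropic spacing."""

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ValueError(f"every axis must have length >= 1, got {data.shape}")
        if data.dtype != bool:
            if not np.isin(np.unique(data), (0, 1)).all():
                raise ValueError("binary volume data must be boolean or 0/1-valued")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _as_isotropic_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


def read_stack(path) -> VoxelVolume:
    """Read a multi-page (or single 3D) TIFF as a :class:`VoxelVolume`.

    Pages are stacked along the z axis.  Spacing is taken from ImageJ-style
    metadata when present (and isotropic), else 1.0.  Pages of differing
    dimensions raise a ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"pages of differing dimensions in {path}: {sorted(shapes)}")
        data = tif.asarray()
        spacing = 1.0
        meta = tif.imagej_metadata or {}
        z_spacing = meta.get("spacing")
        xy = None
        page0 = tif.pages[0]
        res = page0.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                xy = den / num
        if z_spacing is not None and xy is not None:
            spacing = _as_isotropic_spacing([z_spacing, xy, xy])
        elif z_spacing is not None:
            spacing = float(z_spacing)
        elif xy is not None:
            spacing = float(xy)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D/3D grayscale TIFF, got shape {data.shape}")
    return VoxelVolume(data=data, spacing=spacing)


def write_stack(vol, path) -> None:
    """Write a volume (or raw 3D array) as a multi-page TIFF.

    Boolean data is written as 8-bit (0/255); floating-point data as 32-bit
    float with NaN encoding uncovered voxels.  Spacing is stored as ImageJ
    metadata so round-trips through :func:`read_stack` preserve it.
    """
    if isinstance(vol, (VoxelVolume, BinaryVolume)):
        data, spacing = vol.data, vol.spacing
    else:
        data, spacing = np.asarray(vol), 1.0
    if data.dtype == bool:
        data = (data * np.uint8(255))
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / spacing, 1.0 / spacing),
        metadata={"spacing": spacing, "unit": "pixel", "axes": "ZYX"},
    )


def _ball_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz**2 + yy**2 + xx**2) <= radius**2 + 1e-9


def median_filter_3d(vol: VoxelVolume, radius: int) -> VoxelVolume:
    """Median-denoise with a spherical (ball) neighbourhood of the given radius.

    Radius 0 is the identity.  A ball footprint matches the radius phrasing
    of the denoising step; a cube would over-smooth along diagonals.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return VoxelVolume(vol.data.copy(), vol.spacing)
    out = ndimage.median_filter(vol.data, footprint=_ball_footprint(radius), mode="nearest")
    return VoxelVolume(out, vol.spacing)


def threshold(vol: VoxelVolume, level) -> BinaryVolume:
    """Binarize: foreground where intensity is strictly greater than ``level``.

    Pixels exactly at the level are background (strict ``>`` convention,
    applied consistently across the package).
    """
    return BinaryVolume(vol.data > level, vol.spacing)


def bone_volume_fraction(bin_vol: BinaryVolume, mask: BinaryVolume | None = None) -> float:
    """BV/TV: fraction of (masked) voxels that are bone foreground."""
    if mask is None:
        return float(bin_vol.data.mean())
    if mask.shape != bin_vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {bin_vol.shape}")
    denom = mask.data.sum()
    if denom == 0:
        raise ValueError("mask is empty")
    return float((bin_vol.data & mask.data).sum() / denom)


def distance_transform(bin_vol: BinaryVolume) -> np.ndarray:
    """Euclidean distance (voxel units) from each foreground voxel to background.

    The image border counts as background: the volume is zero-padded by one
    voxel before the transform so foreground touching the border gets
    distance 1 there.  Background voxels carry 0.
    """
    padded = np.pad(bin_vol.data, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1, 1:-1]
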