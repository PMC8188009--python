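"""Synthetic binary phantoms with known geometry.

These stand in for micro-CT scans of trabecular bone: reference shapes with
analytic surface/volume (sphere, rod, plate, ellipsoid), a gyroid lattice as
a trabecular-like hyperbolic-surface texture, and a rod/plate lattice with
per-voxel ground-truth labels for validating plate/rod classification.

Inclusion is tested at voxel centres (integer coordinates, no antialiasing),
matching the binary input assumption of the ellipsoid-factor pipeline.  All
generators are deterministic given their parameters (and seed, where one
applies).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume import BinaryVolume

__all__ = [
    "PhantomSpec",
    "make_sphere",
    "make_ellipsoid",
    "make_rod",
    "make_plate",
    "make_gyroid",
    "make_rod_plate_lattice",
    "LABEL_BACKGROUND",
    "LABEL_ROD",
    "LABEL_PLATE",
    "LABEL_JUNCTION",
]

LABEL_BACKGROUND = 0
LABEL_ROD = 1
LABEL_PLATE = 2
LABEL_JUNCTION = 3


def _dims3(dims) -> tuple[int, int, int]:
    if np.isscalar(dims):
        dims = (int(dims),) * 3
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or min(dims) < 1:
        raise ValueError(f"dims must be three positive integers, got {dims!r}")
    return dims


def _centre(dims):
    return (np.asarray(dims, dtype=float) - 1.0) / 2.0


def _grid(dims):
    return np.ogrid[0 : dims[0], 0 : dims[1], 0 : dims[2]]


def make_sphere(radius: float, dims) -> BinaryVolume:
    """Solid sphere of the given radius (voxels) centred in the grid."""
    dims = _dims3(dims)
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if 2 * radius + 4 > min(dims):
        raise ValueError(f"sphere radius {radius} does not fit dims {dims} (needs 2r+4)")
    c = _centre(dims)
    zz, yy, xx = _grid(dims)
    r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    return BinaryVolume(r2 <= radius**2)


def make_ellipsoid(half_axes, dims) -> BinaryVolume:
    """Solid axis-aligned ellipsoid with half-axes ``(hz, hy, hx)`` in voxels."""
    dims = _dims3(dims)
    h = np.asarray(half_axes, dtype=float)
    if h.shape != (3,) or np.any(h <= 0):
        raise ValueError(f"half_axes must be three positive lengths, got {half_axes!r}")
    if np.any(2 * h + 4 > np.asarray(dims)):
        raise ValueError(f"ellipsoid half-axes {h.tolist()} do not fit dims {dims}")
    c = _centre(dims)
    zz, yy, xx = _grid(dims)
    q = ((zz - c[0]) / h[0]) ** 2 + ((yy - c[1]) / h[1]) ** 2 + ((xx - c[2]) / h[2]) ** 2
    return BinaryVolume(q <= 1.0)


def make_rod(radius: float, axis: int = 0, dims=64) -> BinaryVolume:
    """Circular cylinder spanning the full grid along ``axis`` (0=z, 1=y, 2=x)."""
    dims = _dims3(dims)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    cross = [dims[i] for i in range(3) if i != axis]
    if 2 * radius + 4 > min(cross):
        raise ValueError(f"rod radius {radius} does not fit cross-section {cross}")
    c = _centre(dims)
    grids = _grid(dims)
    i, j = [k for k in range(3) if k != axis]
    r2 = (grids[i] - c[i]) ** 2 + (grids[j] - c[j]) ** 2
    mask = np.broadcast_to(r2 <= radius**2, dims)
    return BinaryVolume(mask.copy())


def make_plate(thickness: float, normal: int = 0, dims=64) -> BinaryVolume:
    """Slab of given thickness spanning the grid transverse to ``normal``, centred.

    Integer thicknesses produce exactly ``thickness`` full slices.
    """
    dims = _dims3(dims)
    if normal not in (0, 1, 2):
        raise ValueError(f"normal must be 0, 1 or 2, got {normal}")
    d = dims[normal]
    if thickness <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    if thickness > d:
        raise ValueError(f"thickness {thickness} exceeds grid extent {d}")
    data = np.zeros(dims, dtype=bool)
    if float(thickness).is_integer():
        t = int(thickness)
        lo = (d - t) // 2
        sl = [slice(None)] * 3
        sl[normal] = slice(lo, lo + t)
        data[tuple(sl)] = True
    else:
        coord = np.arange(d, dtype=float)
        inside = np.abs(coord - (d - 1) / 2.0) <= thickness / 2.0
        sl = [np.newaxis] * 3
        sl[normal] = slice(None)
        data[...] = inside[tuple(sl)]
    return BinaryVolume(data)


def make_gyroid(period: float, level: float, dims=64) -> BinaryVolume:
    """Gyroid solid: foreground where sin x'·cos y' + sin y'·cos z' + sin z'·cos x' > level.

    Coordinates are scaled by 2*pi/period.  The result is a connected
    labyrinth bounded by a hyperbolic (saddle-shaped) surface — a convenient
    trabecular-like texture.  Its volume fraction decreases monotonically
    with ``level``; at level 0 it is 0.5 by symmetry of the implicit
    function.
    """
    dims = _dims3(dims)
    if period < 8:
        raise ValueError(f"period must be >= 8 voxels, got {period}")
    k = 2.0 * np.pi / period
    zz, yy, xx = _grid(dims)
    x, y, z = xx * k, yy * k, zz * k
    g = np.sin(x) * np.cos(y) + np.sin(y) * np.cos(z) + np.sin(z) * np.cos(x)
    return BinaryVolume(g > level)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters for a random rod/plate lattice.

    Members are finite (rods of ``rod_length``, square plates of extent
    ``plate_extent``) so a fully disjoint lattice is geometrically possible;
    grid-spanning members would always intersect each other.  With
    ``disjoint=True`` placements keep at least ``min_separation`` voxels of
    background between members (retrying up to ``max_tries`` times).
    """

    dims: tuple[int, int, int] = (64, 64, 64)
    n_rods: int = 3
    n_plates: int = 2
    rod_radius: float = 4.0
    rod_length: float = 44.0
    plate_thickness: float = 4.0
    plate_extent: float = 36.0
    seed: int = 0
    disjoint: bool = True
    min_separation: float = 2.0
    max_tries: int = 200

    def __post_init__(self):
        object.__setattr__(self, "dims", _dims3(self.dims))
        for name in ("rod_radius", "rod_length", "plate_thickness", "plate_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _member_mask(dims, kind: str, axis: int, centre, spec: PhantomSpec, margin: float):
    """Boolean mask for one lattice member; ``margin`` pads every dimension."""
    zz, yy, xx = _grid(dims)
    grids = (zz, yy, xx)
    i, j = [k for k in range(3) if k != axis]
    along = np.abs(grids[axis] - centre[axis])
    if kind == "rod":
        r2 = (grids[i] - centre[i]) ** 2 + (grids[j] - centre[j]) ** 2
        mask = (r2 <= (spec.rod_radius + margin) ** 2) & (
            along <= spec.rod_length / 2.0 + margin
        )
    else:
        mask = (
            (along <= spec.plate_thickness / 2.0 + margin)
            & (np.abs(grids[i] - centre[i]) <= spec.plate_extent / 2.0 + margin)
            & (np.abs(grids[j] - centre[j]) <= spec.plate_extent / 2.0 + margin)
        )
    return np.broadcast_to(mask, dims)


def make_rod_plate_lattice(spec: PhantomSpec) -> tuple[BinaryVolume, np.ndarray]:
    """Random lattice of axis-aligned rods and plates with ground-truth labels.

    Returns the binary volume and a label grid (uint8): 0 background, 1 rod,
    2 plate, 3 junction (claimed by both kinds).  Deterministic for a fixed
    spec (which includes the seed).
    """
    dims = spec.dims
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(dims, dtype=np.uint8)
    occupied = np.zeros(dims, dtype=bool)

    members = [("rod", LABEL_ROD)] * spec.n_rods + [("plate", LABEL_PLATE)] * spec.n_plates
    for kind, label in members:
        half = {
            "rod": lambda ax: np.array(
                [
                    spec.rod_length / 2.0 if k == ax else spec.rod_radius
                    for k in range(3)
                ]
            ),
            "plate": lambda ax: np.array(
                [
                    spec.plate_thickness / 2.0 if k == ax else spec.plate_extent / 2.0
                    for k in range(3)
                ]
            ),
        }[kind]
        placed = False
        for _ in range(spec.max_tries):
            axis = int(rng.integers(3))
            h = half(axis)
            lo = h + 1.0
            hi = np.asarray(dims, dtype=float) - 1.0 - h
            if np.any(hi < lo):
                raise ValueError(f"{kind} does not fit the grid {dims}")
            centre = rng.uniform(lo, hi)
            mask = _member_mask(dims, kind, axis, centre, spec, margin=0.0)
            if spec.disjoint:
                padded = _member_mask(
                    dims, kind, axis, centre, spec, margin=spec.min_separation
                )
                if (padded & occupied).any():
                    continue
            junction = mask & (labels != 0) & (labels != label)
            labels[mask] = np.where(
                junction[mask], LABEL_JUNCTION, label
            )
            occupied |= mask
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a disjoint {kind} after {spec.max_tries} tries; "
                "reduce member count/size or the separation"
            )
    return BinaryVolume(occupied), labels
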