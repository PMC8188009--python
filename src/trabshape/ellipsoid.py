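"""The ellipsoid primitive: sorted semi-axes, containment, uniform surface sampling.

An :class:`Ellipsoid` is the unit of local shape measurement: centre in
continuous voxel coordinates ``(z, y, x)``, semi-axis lengths sorted
``a <= b <= c``, and an orthonormal frame whose rows pair with the sorted
lengths.  The sorted invariant is restored on construction, so any mutation
performed by rebuilding the object (grow, contract, rotate, dilate) keeps it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Ellipsoid", "rotation_matrix"]

ORTHO_TOL = 1e-9


def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class Ellipsoid:
    """Ellipsoid with centre, sorted semi-axes ``a <= b <= c`` and orthonormal frame.

    ``axes`` is a 3x3 matrix whose row ``i`` is the unit direction of
    ``radii[i]``; a point ``p`` is inside iff
    ``sum(((p - centre) @ axes.T / radii)**2) <= 1``.
    """

    __slots__ = ("centre", "radii", "axes")

    def __init__(self, centre, radii, axes=None):
        centre = np.array(centre, dtype=float)
        radii = np.array(radii, dtype=float)
        axes = np.eye(3) if axes is None else np.array(axes, dtype=float)
        if centre.shape != (3,) or radii.shape != (3,) or axes.shape != (3, 3):
            raise ValueError("centre/radii must be length 3, axes 3x3")
        if not np.all(radii > 0):
            raise ValueError(f"semi-axes must be positive, got {radii.tolist()}")
        gram = axes @ axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("axes rows must be orthonormal")
        # restore exact orthonormality (guards against drift over many rotations)
        u, _, vt = np.linalg.svd(axes)
        axes = u @ vt
        order = np.argsort(radii, kind="stable")
        self.centre = centre
        self.radii = radii[order]
        self.axes = axes[order]

    # -- basic measures -------------------------------------------------
    @property
    def a(self) -> float:
        return float(self.radii[0])

    @property
    def b(self) -> float:
        return float(self.radii[1])

    @property
    def c(self) -> float:
        return float(self.radii[2])

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.radii))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Ellipsoid(centre={self.centre.round(2).tolist()}, "
            f"radii={self.radii.round(3).tolist()})"
        )

    # -- geometry -------------------------------------------------------
    def contains(self, points, tol: float = 1e-12):
        """Whether point(s) satisfy the quadratic form; vectorized over (..., 3)."""
        p = np.asarray(points, dtype=float)
        scalar = p.ndim == 1
        rel = np.atleast_2d(p) - self.centre
        q = rel @ self.axes.T
        inside = np.einsum("ij,ij->i", q / self.radii, q / self.radii) <= 1.0 + tol
        return bool(inside[0]) if scalar else inside

    def surface_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` points uniform with respect to surface area, shape (n, 3).

        Directions are drawn uniformly on the unit sphere, mapped to the
        ellipsoid, and rejection-corrected by the surface-area Jacobian;
        the plain mapping alone is measurably non-uniform on elongated
        ellipsoids.
        """
        if n < 1:
            raise ValueError(f"need n >= 1 surface points, got {n}")
        return sample_surface(self.centre, self.radii, self.axes, n, rng)


def sample_surface(centre, radii, axes, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-uniform surface sample of an ellipsoid given by raw arrays.

    Shared by :class:`Ellipsoid` and the fitting hot loop (which carries
    unsorted radii/axes); ``axes`` rows need only be orthonormal.
    """
    r0, r1, r2 = radii
    # area weight of direction u is |(r1*r2*u0, r0*r2*u1, r0*r1*u2)|; its max
    # over the sphere is the largest pairwise product
    p = np.array([r1 * r2, r0 * r2, r0 * r1])
    wmax = p.max()
    if wmax - p.min() <= 1e-12 * wmax:
        # sphere: every direction equally likely, no rejection needed
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return centre + (u * radii) @ axes
    out = np.empty((n, 3))
    got = 0
    while got < n:
        # typical acceptance is >1/2, so a modest oversample usually suffices
        k = 2 * (n - got) + 16
        u = rng.standard_normal((k, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        w2 = (u * u) @ (p * p)
        keep = (rng.random(k) * wmax) ** 2 <= w2
        sel = u[keep]
        take = min(n - got, sel.shape[0])
        out[got : got + take] = sel[:take]
        got += take
    return centre + (out * radii) @ axes
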