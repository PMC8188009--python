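"""Compiled hot loop for ellipsoid fitting.

The fitting procedure performs hundreds of contact checks per seed, each of
which samples ~100 area-uniform points on the ellipsoid surface and looks
them up in the binary grid.  Doing this in vectorized numpy costs ~100 us
per check in interpreter overhead alone; this module provides the same
computation as a numba kernel with an explicit counter-based RNG
(splitmix64) so results are bit-reproducible for a given 64-bit seed (drawn
per check from the caller's ``numpy.random.Generator``, which keeps the
whole fit a pure function of its RNG stream).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["contact_kernel"]

# contact points beyond this count are not needed by the caller (only the
# first few inform the constrained-direction estimate)
_MAX_KEPT = 64

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_TO_UNIT = 1.0 / 9007199254740992.0  # 2**-53
_TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def contact_kernel(centre, radii, axes, data, n, seed):
    """Sample ``n`` area-uniform surface points and count background hits.

    Returns ``(contacts, n_contacts, n_outside)`` where ``contacts`` holds
    the first (up to 64) contact points.  A point is a contact when the
    voxel containing it (nearest integer coordinates) is background or
    outside the grid.  Directions are drawn uniformly on the unit sphere
    and rejection-corrected by the surface-area Jacobian, so the accepted
    points are uniform with respect to ellipsoid surface area.
    """
    state = np.uint64(seed)
    r0, r1, r2 = radii[0], radii[1], radii[2]
    p0, p1, p2 = r1 * r2, r0 * r2, r0 * r1
    wmax = max(p0, max(p1, p2))
    wmax2 = wmax * wmax
    is_sphere = abs(p0 - p1) <= 1e-12 * wmax and abs(p1 - p2) <= 1e-12 * wmax
    nz, ny, nx = data.shape
    contacts = np.empty((_MAX_KEPT, 3), dtype=np.float64)
    m = 0
    n_out = 0
    got = 0
    guard = 0
    uni = np.empty(5, dtype=np.float64)
    while got < n and guard < 100000:
        guard += 1
        # five splitmix64 uniforms per attempt (four normals via Box-Muller
        # plus the rejection draw); a fixed count keeps the stream simple
        for k in range(5):
            state = state + _GOLDEN
            z = state
            z = (z ^ (z >> np.uint64(30))) * _MIX1
            z = (z ^ (z >> np.uint64(27))) * _MIX2
            z = z ^ (z >> np.uint64(31))
            uni[k] = (z >> np.uint64(11)) * _TO_UNIT
        rad1 = np.sqrt(-2.0 * np.log(uni[0] + 1e-300))
        rad2 = np.sqrt(-2.0 * np.log(uni[2] + 1e-300))
        a1 = _TWO_PI * uni[1]
        a2 = _TWO_PI * uni[3]
        g0 = rad1 * np.cos(a1)
        g1 = rad1 * np.sin(a1)
        g2 = rad2 * np.cos(a2)
        norm = np.sqrt(g0 * g0 + g1 * g1 + g2 * g2)
        if norm < 1e-12:
            continue
        g0 /= norm
        g1 /= norm
        g2 /= norm
        if not is_sphere:
            w2 = (g0 * p0) ** 2 + (g1 * p1) ** 2 + (g2 * p2) ** 2
            if uni[4] * uni[4] * wmax2 > w2:
                continue
        got += 1
        # body coords -> world: centre + (u * radii) @ axes (axes rows)
        b0 = g0 * r0
        b1 = g1 * r1
        b2 = g2 * r2
        z_ = centre[0] + b0 * axes[0, 0] + b1 * axes[1, 0] + b2 * axes[2, 0]
        y_ = centre[1] + b0 * axes[0, 1] + b1 * axes[1, 1] + b2 * axes[2, 1]
        x_ = centre[2] + b0 * axes[0, 2] + b1 * axes[1, 2] + b2 * axes[2, 2]
        iz = int(round(z_))
        iy = int(round(y_))
        ix = int(round(x_))
        if iz < 0 or iz >= nz or iy < 0 or iy >= ny or ix < 0 or ix >= nx:
            n_out += 1
            hit = True
        else:
            hit = not data[iz, iy, ix]
        if hit:
            if m < _MAX_KEPT:
                contacts[m, 0] = z_
                contacts[m, 1] = y_
                contacts[m, 2] = x_
            m += 1
    return contacts, m, n_out
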