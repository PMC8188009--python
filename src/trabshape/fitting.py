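"""Stochastic fitting of locally maximal ellipsoids in a binary volume.

From each seed a small sphere grows uniformly by a fixed increment until
surface sample points hit background ("contacts").  The dominant contact
direction defines the first (constrained) semi-axis; after a slight
contraction, growth continues in the plane orthogonal to it, then along the
freest in-plane direction.  A series of small random rotations, translations
and dilations then searches the neighbourhood for a larger ellipsoid; the
search stops after a set number of consecutive non-improvements (or ten times
that many total attempts).  Ellipsoids whose surface lies mostly outside the
image are invalid and discarded.

Everything is driven by an explicit ``numpy.random.Generator``, so a fit is
fully deterministic given (seed point, volume, parameters, RNG state).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._kernels import contact_kernel
from .ellipsoid import Ellipsoid, rotation_matrix, sample_surface
from .volume import BinaryVolume

__all__ = [
    "FitParams",
    "ContactSet",
    "detect_contacts",
    "grow_until_contact",
    "fit_maximal_ellipsoid",
]

# in-plane directions probed when searching for the remaining free axis
_N_DIRECTION_PROBES = 6


@dataclasses.dataclass(frozen=True)
class FitParams:
    """Tunable parameters of the ellipsoid fit.

    ``n_vectors``           surface sampling directions per contact check
    ``sampling_increment``  growth step in voxels
    ``contact_sensitivity`` background hits required to register a collision
    ``max_iterations``      consecutive non-improving attempts before stopping
    ``max_drift``           cap on centre displacement from the seed (voxels);
                            defaults to the unit pixel diagonal, sqrt(3)
    ``contraction``         semi-axis shrink factor applied after a collision
    ``max_rotation``        upper bound of the small random rotation angle (rad)
    """

    n_vectors: int = 100
    sampling_increment: float = 1.0 / 2.3
    contact_sensitivity: int = 1
    max_iterations: int = 50
    max_drift: float = math.sqrt(3.0)
    contraction: float = 0.95
    max_rotation: float = 0.1

    def __post_init__(self):
        if self.n_vectors < 4:
            raise ValueError("n_vectors must be >= 4")
        if self.sampling_increment <= 0:
            raise ValueError("sampling_increment must be > 0")
        if self.contact_sensitivity < 1:
            raise ValueError("contact_sensitivity must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.max_drift < 0:
            raise ValueError("max_drift must be >= 0")
        if not (0 < self.contraction < 1):
            raise ValueError("contraction must be in (0, 1)")


@dataclasses.dataclass(frozen=True)
class ContactSet:
    """Surface sample points that landed on background, plus bookkeeping."""

    points: np.ndarray  # (m, 3) contact points
    mean_contact_vector: np.ndarray  # (3,) mean of (point - centre); zeros if none
    n_samples: int
    n_outside: int  # samples falling outside the image grid

    @property
    def n_contacts(self) -> int:
        return self.points.shape[0]


def _contacts_raw(centre, radii, axes, data, n, rng):
    """Sample n surface points; return (points, bg_mask, n_outside).

    A point hits the boundary when the voxel containing it (nearest integer
    coordinate) is background; out-of-grid counts as background.
    """
    pts = sample_surface(centre, radii, axes, n, rng)
    idx = np.rint(pts).astype(np.intp)
    dims = data.shape
    outside = (
        (idx[:, 0] < 0)
        | (idx[:, 0] >= dims[0])
        | (idx[:, 1] < 0)
        | (idx[:, 1] >= dims[1])
        | (idx[:, 2] < 0)
        | (idx[:, 2] >= dims[2])
    )
    bg = outside.copy()
    inb = ~outside
    if inb.any():
        ii = idx[inb]
        bg[inb] = ~data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return pts, bg, int(outside.sum())


def detect_contacts(
    e: Ellipsoid, bin_vol: BinaryVolume, n_vectors: int, rng: np.random.Generator
) -> ContactSet:
    """Sample the ellipsoid surface and collect points lying on background."""
    pts, bg, n_out = _contacts_raw(
        e.centre, e.radii, e.axes, bin_vol.data, n_vectors, rng
    )
    contacts = pts[bg]
    mcv = (
        contacts.mean(axis=0) - e.centre if contacts.shape[0] else np.zeros(3)
    )
    return ContactSet(
        points=contacts, mean_contact_vector=mcv, n_samples=n_vectors, n_outside=n_out
    )


class _State:
    """Mutable fitting state; axes row 0 is the contact-constrained axis."""

    __slots__ = ("centre", "radii", "axes")

    def __init__(self, centre, radii, axes):
        self.centre = np.asarray(centre, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.axes = np.asarray(axes, dtype=float)

    def copy(self) -> "_State":
        return _State(self.centre.copy(), self.radii.copy(), self.axes.copy())

    @property
    def pseudo_volume(self) -> float:
        # ordering by radii product == ordering by volume (4/3*pi factor fixed)
        return float(np.prod(self.radii))


class _FitRng:
    """Thin wrapper over a Generator that batches the per-check seed draws.

    Contact checks need one fresh 64-bit kernel seed each; drawing them one
    at a time through ``Generator.integers`` costs more than the kernel
    itself, so seeds are drawn in blocks.  Everything still derives from
    the single wrapped generator, keeping fits deterministic.
    """

    __slots__ = ("rng", "_buf", "_i")

    def __init__(self, rng: np.random.Generator, block: int = 512):
        self.rng = rng
        self._buf = rng.integers(0, 2**63, size=block)
        self._i = 0

    def next_seed(self) -> int:
        if self._i >= self._buf.size:
            self._buf = self.rng.integers(0, 2**63, size=self._buf.size)
            self._i = 0
        seed = self._buf[self._i]
        self._i += 1
        return int(seed)


def _check(state: _State, data, params: FitParams, rng, want_points: bool = False):
    """One contact check: (collides, contact points, n_outside).

    Runs the compiled kernel with a fresh 64-bit seed drawn from the
    caller's generator, so the whole fit remains a deterministic function
    of its RNG stream.
    """
    if isinstance(rng, _FitRng):
        seed = rng.next_seed()
    else:
        seed = int(rng.integers(0, 2**63))
    contacts, m, n_out = contact_kernel(
        state.centre, state.radii, state.axes, data, params.n_vectors, seed
    )
    collides = m >= params.contact_sensitivity
    pts = None
    if want_points and m:
        pts = contacts[: min(m, contacts.shape[0])].copy()
    return collides, pts, n_out


def _grow_raw(state: _State, data, params: FitParams, rng, free, want_points=False):
    """Enlarge the free semi-axes step by step until a collision registers.

    Returns (state after the colliding step, contact points).  Always
    terminates because out-of-grid samples count as background.
    """
    max_steps = int(max(data.shape) / params.sampling_increment) + 4
    for _ in range(max_steps):
        state.radii[free] += params.sampling_increment
        collides, contacts, _ = _check(state, data, params, rng, want_points)
        if collides:
            return state, contacts
    return state, None  # pragma: no cover - unreachable for finite grids


def _contract_until_clear(
    state, data, params, rng, max_steps: int = 64, n_clean: int = 3
) -> bool:
    """Shrink after a collision until consecutive checks are contact-free.

    A single clean check can leave the surface grazing the boundary (the
    next random sample registers a contact again and stalls all further
    growth and refinement), so demand ``n_clean`` in a row for genuine
    clearance.
    """
    for _ in range(max_steps):
        state.radii *= params.contraction
        clear = True
        for _ in range(n_clean):
            collides, _, _ = _check(state, data, params, rng)
            if collides:
                clear = False
                break
        if clear:
            return True
    return False


def _principal_contact_direction(contacts, centre, rng) -> np.ndarray:
    """Dominant direction of the contact points as seen from the centre.

    The principal eigenvector of the contact-direction scatter matrix is a
    robust estimate of the constrained direction: averaging the vectors
    instead would cancel contacts spread around a ring (rods) or sitting on
    opposite faces (plates) and leave only noise.
    """
    if contacts is None or contacts.shape[0] == 0:
        d = rng.standard_normal(3)
        return d / np.linalg.norm(d)
    dirs = contacts - centre
    norms = np.linalg.norm(dirs, axis=1)
    dirs = dirs[norms > 1e-12] / norms[norms > 1e-12, None]
    if dirs.shape[0] == 0:
        d = rng.standard_normal(3)
        return d / np.linalg.norm(d)
    _, vecs = np.linalg.eigh(dirs.T @ dirs)
    return vecs[:, -1]


def _complement_frame(d0: np.ndarray) -> np.ndarray:
    """Orthonormal frame with row 0 = d0 (deterministic completion)."""
    helper = np.zeros(3)
    helper[np.argmin(np.abs(d0))] = 1.0
    e1 = np.cross(d0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)
    return np.vstack([d0, e1, e2])


def grow_until_contact(
    e: Ellipsoid,
    bin_vol: BinaryVolume,
    params: FitParams,
    rng: np.random.Generator,
    fixed_direction=None,
) -> Ellipsoid:
    """Grow an ellipsoid by the sampling increment until it first collides.

    With ``fixed_direction`` given, the semi-axis most parallel to it is held
    fixed and growth is confined to the orthogonal plane; otherwise all three
    axes grow uniformly.  Returns the state one step past the last
    collision-free one (the first colliding state).
    """
    state = _State(e.centre.copy(), e.radii.copy(), e.axes.copy())
    if fixed_direction is None:
        free = np.array([True, True, True])
    else:
        d = np.asarray(fixed_direction, dtype=float)
        d = d / np.linalg.norm(d)
        fixed = int(np.argmax(np.abs(state.axes @ d)))
        free = np.array([i != fixed for i in range(3)])
    collides, _, _ = _check(state, bin_vol.data, params, rng)
    if collides:
        raise ValueError("ellipsoid already registers a collision; contract it first")
    state, _ = _grow_raw(state, bin_vol.data, params, rng, free)
    return Ellipsoid(state.centre, state.radii, state.axes)


def _clip_drift(centre, seed, max_drift):
    delta = centre - seed
    d = np.linalg.norm(delta)
    if d > max_drift:
        centre = seed + delta * (max_drift / d) if d > 0 else seed.copy()
    return centre


def fit_maximal_ellipsoid(
    seed,
    bin_vol: BinaryVolume,
    params: FitParams | None = None,
    rng: np.random.Generator | None = None,
) -> Ellipsoid | None:
    """Fit a locally maximal ellipsoid starting from a foreground seed voxel.

    Returns the fitted :class:`Ellipsoid`, or ``None`` when the fit is
    invalid: the seed sits in sub-voxel structure (the initial sphere cannot
    avoid collisions even after contraction) or more than half of the final
    surface samples fall outside the image grid.

    Raises ``ValueError`` if the seed voxel is background (caller bug).
    """
    params = params or FitParams()
    rng = rng if rng is not None else np.random.default_rng()
    crng = _FitRng(rng)
    data = bin_vol.data
    seed = np.asarray(seed, dtype=float)
    seed_idx = np.rint(seed).astype(np.intp)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.array(data.shape)):
        raise ValueError(f"seed {seed.tolist()} outside the image grid")
    if not data[tuple(seed_idx)]:
        raise ValueError(f"seed {seed.tolist()} lies on background")

    inc = params.sampling_increment
    state = _State(seed.copy(), np.full(3, inc), np.eye(3))

    # a seed whose initial sphere already collides sits in (near) sub-voxel
    # structure: contract once, then give up
    collides, _, _ = _check(state, data, params, crng)
    if collides:
        state.radii[:] = inc / 2.0
        collides, _, _ = _check(state, data, params, crng)
        if collides:
            return None

    # phase 1: uniform spherical growth until first boundary contact
    state, contacts = _grow_raw(state, data, params, crng, np.array([True] * 3), want_points=True)
    d0 = _principal_contact_direction(contacts, state.centre, rng)
    state.axes = _complement_frame(d0)
    state.radii *= params.contraction

    # phase 2: growth confined to the plane orthogonal to the first semi-axis
    state, _ = _grow_raw(state, data, params, crng, np.array([False, True, True]))
    # contract clear of the boundary so single stray contacts do not stall
    # the directional growth that follows
    if not _contract_until_clear(state, data, params, crng):
        return None

    # phase 2b: the in-plane growth stopped at the second constraint; one
    # in-plane direction may still be free (the long axis of rods, the
    # second extent of plates).  Its orientation cannot be read reliably
    # off one or two contact points, so probe a handful of random in-plane
    # directions, grow each to contact, and keep the largest.  The two
    # in-plane radii are equal here, so re-labelling the in-plane frame
    # leaves the ellipsoid itself unchanged.
    phi0 = rng.uniform(0.0, np.pi)
    u, v = state.axes[1], state.axes[2]
    best_grown = None
    for g in range(_N_DIRECTION_PROBES):
        phi = phi0 + g * np.pi / _N_DIRECTION_PROBES
        e_free = np.cos(phi) * u + np.sin(phi) * v
        cand = state.copy()
        cand.axes = np.vstack([d0, np.cross(e_free, d0), e_free])
        cand, _ = _grow_raw(cand, data, params, crng, np.array([False, False, True]))
        if best_grown is None or cand.pseudo_volume > best_grown.pseudo_volume:
            best_grown = cand
    state = best_grown
    if not _contract_until_clear(state, data, params, crng):
        return None

    # phase 2c: the middle (in-plane, orthogonal to the probed direction)
    # axis may also still be free — the second extent of a plate; grow it
    # to contact as well
    state, _ = _grow_raw(state, data, params, crng, np.array([False, True, False]))
    if not _contract_until_clear(state, data, params, crng):
        return None

    # phase 3: stochastic refinement — single-increment dilations, and small
    # random rotations/translations followed by regrowth of one axis to
    # contact; a proposal is kept only when it is collision-free and
    # strictly larger, so recorded volume is non-decreasing
    best = state
    best_vol = best.pseudo_volume
    no_improve = 0
    attempts = 0
    max_attempts = 10 * params.max_iterations
    while no_improve < params.max_iterations and attempts < max_attempts:
        attempts += 1
        trial = best.copy()
        kind = int(rng.integers(4))
        if kind == 1:
            # small random rotation, then dilate
            rot = rotation_matrix(
                rng.standard_normal(3), rng.uniform(0.0, params.max_rotation)
            )
            trial.axes = trial.axes @ rot.T
        elif kind == 2:
            # small random translation within the drift cap, then dilate
            step = rng.standard_normal(3)
            step *= inc * rng.random() ** (1.0 / 3.0) / np.linalg.norm(step)
            trial.centre = _clip_drift(trial.centre + step, seed, params.max_drift)
        if kind == 3:
            # regrow one random semi-axis until the boundary is hit, then
            # contract back inside the foreground
            free = np.zeros(3, dtype=bool)
            free[int(rng.integers(3))] = True
            collides, _, _ = _check(trial, data, params, crng)
            if collides:
                # contraction could only shrink it below the incumbent
                no_improve += 1
                continue
            trial, _ = _grow_raw(trial, data, params, crng, free)
            if trial.pseudo_volume * params.contraction**3 <= best_vol:
                # even a single contraction step would lose to the incumbent
                no_improve += 1
                continue
            ok = _contract_until_clear(trial, data, params, crng, max_steps=8)
        else:
            # dilate one random semi-axis by one increment
            trial.radii[int(rng.integers(3))] += inc
            collides, _, _ = _check(trial, data, params, crng)
            ok = not collides
        if ok and trial.pseudo_volume > best_vol:
            best = trial
            best_vol = trial.pseudo_volume
            no_improve = 0
        else:
            no_improve += 1

    # final polish: refinement may leave the surface either grazing the
    # boundary (accepted on one lucky sample) or a fraction of a voxel
    # short of it; contract clear, then dilate each axis in turn (shortest
    # first) while two consecutive checks stay clean, so the result is
    # maximal in the contact-sensitivity sense without grazing
    grazing = False
    for _ in range(2):
        collides, _, _ = _check(best, data, params, crng)
        if collides:
            grazing = True
            break
    if grazing and not _contract_until_clear(best, data, params, crng, max_steps=8):
        return None
    for _ in range(4):
        improved = False
        for i in np.argsort(best.radii):
            trial = best.copy()
            trial.radii[i] += inc
            collides, _, _ = _check(trial, data, params, crng)
            if not collides:
                collides, _, _ = _check(trial, data, params, crng)
            if not collides:
                best = trial
                improved = True
        if not improved:
            break

    # validity: discard ellipsoids whose surface lies mostly outside the grid
    if _mostly_outside(best, data, params, crng):
        return None
    return Ellipsoid(best.centre, best.radii, best.axes)


def _mostly_outside(state: _State, data, params: FitParams, rng) -> bool:
    """Whether more than half of a fresh surface sample leaves the grid."""
    seed = rng.next_seed() if isinstance(rng, _FitRng) else int(rng.integers(0, 2**63))
    _, _, n_out = contact_kernel(
        state.centre, state.radii, state.axes, data, params.n_vectors, seed
    )
    return n_out > params.n_vectors / 2.0
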