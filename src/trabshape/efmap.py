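"""Per-voxel ellipsoid-factor maps, run averaging and reporting.

The ellipsoid factor of a fitted ellipsoid with sorted semi-axes
``a <= b <= c`` is ``EF = a/b - b/c``: -1 for extreme plates, +1 for extreme
rods, 0 for spheres and for intermediate shapes on the ``a/b = b/c``
diagonal.  Each foreground voxel receives the EF of the largest-volume
ellipsoid containing it (NaN when none does).  Because seeding and fitting
are stochastic, several runs can be averaged per voxel; convergence is
tracked through the filling percentage and the median/maximum change of the
running mean between consecutive runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ellipsoid import Ellipsoid
from .fitting import FitParams, fit_maximal_ellipsoid
from .seeding import (
    SeedSet,
    decimate_seeds,
    distance_ridge_seeds,
    merge_seed_strategies,
    skeleton_seeds,
)
from .volume import BinaryVolume

__all__ = [
    "ef_of_ellipsoid",
    "contains",
    "EFRun",
    "EFResult",
    "FlinnData",
    "assign_ef",
    "run_ef",
    "average_runs",
    "compute_ef",
    "summary_stats",
    "flinn_data",
    "secondary_images",
]


def ef_of_ellipsoid(e: Ellipsoid) -> float:
    """EF = a/b - b/c, in [-1, 1] by construction (0 < a <= b <= c)."""
    a, b, c = e.semi_axes
    return a / b - b / c


def contains(e: Ellipsoid, point) -> bool:
    """Whether the ellipsoid contains a point (quadratic-form test)."""
    return bool(e.contains(point))


@dataclasses.dataclass
class EFRun:
    """One seeding + fitting + assignment cycle.

    ``ef_grid`` holds per-voxel EF (float32, NaN on background and on
    foreground covered by no valid ellipsoid); ``claim_id`` the index of the
    claiming (largest containing) ellipsoid in the volume-sorted list, -1
    where unclaimed; ``ellipsoids`` that sorted list.
    """

    ef_grid: np.ndarray
    claim_id: np.ndarray
    ellipsoids: list[Ellipsoid]
    filling_percentage: float
    foreground_count: int
    n_seeds: int = 0


@dataclasses.dataclass
class EFResult:
    """EF averaged over runs, with convergence records.

    ``median_change[n]`` / ``maximum_change[n]`` are the median/maximum over
    voxels (covered by both running means) of the absolute change of the
    per-voxel running mean between run n-1 and run n, for n >= 2.
    ``filling_per_run`` is cumulative (covered in at least one run so far),
    hence non-decreasing.
    """

    ef_grid: np.ndarray
    n_runs: int
    filling_percentage: float
    filling_per_run: list[float]
    median_change: dict[int, float]
    maximum_change: dict[int, float]
    n_ellipsoids_found: int
    runs: list[EFRun] = dataclasses.field(default_factory=list, repr=False)


@dataclasses.dataclass(frozen=True)
class FlinnData:
    """Semi-axis ratio scatter: x = b/c, y = a/b; EF isolines are y - x = EF.

    ``peak_points``/``peak_weights`` describe locally maximal (voxel-claiming)
    ellipsoids weighted by the number of voxels claimed; ``all_points`` every
    fitted ellipsoid, unweighted.
    """

    peak_points: np.ndarray
    peak_weights: np.ndarray
    all_points: np.ndarray


def assign_ef(
    bin_vol: BinaryVolume,
    ellipsoids: list[Ellipsoid],
    average_over_largest_n: int = 1,
    n_seeds: int = 0,
) -> EFRun:
    """Assign each foreground voxel the EF of the largest ellipsoid containing it.

    Ellipsoids are sorted by volume descending (ties keep input order, so the
    lower ID wins); each voxel takes the EF of the first one containing it —
    equivalent to, but much faster than, a brute-force all-pairs scan thanks
    to per-ellipsoid bounding boxes.  With ``average_over_largest_n`` > 1 a
    voxel instead averages the EF of its n largest containing ellipsoids
    (the claim ID and secondary images still refer to the largest).
    """
    if average_over_largest_n < 1:
        raise ValueError("average_over_largest_n must be >= 1")
    data = bin_vol.data
    dims = data.shape
    order = sorted(
        range(len(ellipsoids)), key=lambda i: -ellipsoids[i].volume
    )
    sorted_ells = [ellipsoids[i] for i in order]

    claim_id = np.full(dims, -1, dtype=np.int32)
    ef_sum = np.zeros(dims, dtype=np.float64)
    n_claims = np.zeros(dims, dtype=np.int16)
    kmax = average_over_largest_n

    for eid, e in enumerate(sorted_ells):
        c = e.c
        lo = np.maximum(np.floor(e.centre - c).astype(int), 0)
        hi = np.minimum(np.ceil(e.centre + c).astype(int) + 1, dims)
        if np.any(hi <= lo):
            continue
        sub = tuple(slice(lo[i], hi[i]) for i in range(3))
        cand = data[sub] & (n_claims[sub] < kmax)
        if not cand.any():
            continue
        zz, yy, xx = np.nonzero(cand)
        pts = np.stack([zz + lo[0], yy + lo[1], xx + lo[2]], axis=1).astype(float)
        inside = e.contains(pts)
        if not inside.any():
            continue
        sel = (zz[inside], yy[inside], xx[inside])
        ef = ef_of_ellipsoid(e)
        ef_sum[sub][sel] += ef
        first = claim_id[sub][sel] == -1
        if first.any():
            cid = claim_id[sub]
            cid[tuple(s[first] for s in sel)] = eid
            claim_id[sub] = cid
        ncl = n_claims[sub]
        ncl[sel] += 1
        n_claims[sub] = ncl

    covered = n_claims > 0
    ef_grid = np.full(dims, np.nan, dtype=np.float32)
    ef_grid[covered] = (ef_sum[covered] / n_claims[covered]).astype(np.float32)
    fg = int(data.sum())
    filling = 100.0 * covered.sum() / fg if fg else 0.0
    return EFRun(
        ef_grid=ef_grid,
        claim_id=claim_id,
        ellipsoids=sorted_ells,
        filling_percentage=float(filling),
        foreground_count=fg,
        n_seeds=n_seeds,
    )


def _collect_seeds(bin_vol: BinaryVolume, config) -> SeedSet:
    sets = []
    if config.seed_distance_ridge:
        sets.append(distance_ridge_seeds(bin_vol))
    if config.seed_topology:
        sets.append(skeleton_seeds(bin_vol))
    if not sets:
        raise ValueError("at least one seeding strategy must be enabled")
    seeds = sets[0]
    for other in sets[1:]:
        seeds = merge_seed_strategies(seeds, other)
    return decimate_seeds(seeds, config.skeleton_points_per_ellipsoid)


def run_ef(bin_vol: BinaryVolume, config=None, rng_seed=None) -> EFRun:
    """One complete run: seed, fit an ellipsoid per seed, drop invalids, assign EF.

    ``config`` is a :class:`trabshape.config.RunConfig` (defaults used when
    omitted).  Each seed point fits with an independent RNG substream spawned
    from ``rng_seed``, so results are reproducible and independent of seed
    ordering.
    """
    from .config import RunConfig

    config = config or RunConfig()
    if bin_vol.foreground_count == 0:
        raise ValueError("foreground is empty")
    seeds = _collect_seeds(bin_vol, config)
    params = config.fit_params()
    if rng_seed is None:
        rng_seed = config.rng_seed
    entropy = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = entropy.spawn(len(seeds))
    ellipsoids = []
    for point, child in zip(seeds.points, children):
        e = fit_maximal_ellipsoid(point, bin_vol, params, np.random.default_rng(child))
        if e is not None:
            ellipsoids.append(e)
    return assign_ef(
        bin_vol,
        ellipsoids,
        average_over_largest_n=config.average_over_largest_n,
        n_seeds=len(seeds),
    )


def average_runs(runs: list[EFRun]) -> EFResult:
    """NaN-aware per-voxel mean over runs, with convergence records.

    A voxel covered in a subset of runs averages over that subset.  For each
    n >= 2 the median and maximum of the absolute running-mean change are
    recorded over voxels covered by both the (n-1)-run and n-run means.
    """
    if not runs:
        raise ValueError("need at least one run")
    dims = runs[0].ef_grid.shape
    for r in runs[1:]:
        if r.ef_grid.shape != dims:
            raise ValueError("runs have mismatched dimensions")
    total = np.zeros(dims, dtype=np.float64)
    count = np.zeros(dims, dtype=np.int32)
    prev_mean = None
    median_change: dict[int, float] = {}
    maximum_change: dict[int, float] = {}
    filling_per_run: list[float] = []
    fg = runs[0].foreground_count
    for n, run in enumerate(runs, start=1):
        m = ~np.isnan(run.ef_grid)
        total[m] += run.ef_grid[m]
        count[m] += 1
        covered = count > 0
        mean = np.full(dims, np.nan, dtype=np.float64)
        mean[covered] = total[covered] / count[covered]
        filling_per_run.append(100.0 * covered.sum() / fg if fg else 0.0)
        if prev_mean is not None:
            both = ~np.isnan(prev_mean) & covered
            if both.any():
                diff = np.abs(mean[both] - prev_mean[both])
                median_change[n] = float(np.median(diff))
                maximum_change[n] = float(diff.max())
            else:
                median_change[n] = float("nan")
                maximum_change[n] = float("nan")
        prev_mean = mean
    return EFResult(
        ef_grid=mean.astype(np.float32),
        n_runs=len(runs),
        filling_percentage=filling_per_run[-1],
        filling_per_run=filling_per_run,
        median_change=median_change,
        maximum_change=maximum_change,
        n_ellipsoids_found=sum(len(r.ellipsoids) for r in runs),
        runs=list(runs),
    )


def compute_ef(bin_vol: BinaryVolume, config=None) -> EFResult:
    """Run the EF pipeline ``config.repetitions`` times and average the runs."""
    from .config import RunConfig

    config = config or RunConfig()
    run_seeds = np.random.SeedSequence(config.rng_seed).spawn(config.repetitions)
    runs = [run_ef(bin_vol, config, rng_seed=s) for s in run_seeds]
    return average_runs(runs)


def summary_stats(res: EFResult, mode_bin_width: float = 0.05) -> dict[str, float]:
    """Descriptive statistics of the EF distribution over covered voxels.

    The mode is the centre of the most populated histogram bin of the stated
    width over [-1, 1] (ties take the lowest bin).
    """
    vals = res.ef_grid[~np.isnan(res.ef_grid)]
    if vals.size == 0:
        raise ValueError("no covered voxels")
    nbins = max(int(round(2.0 / mode_bin_width)), 1)
    hist, edges = np.histogram(vals, bins=nbins, range=(-1.0, 1.0))
    imax = int(np.argmax(hist))
    return {
        "min EF": float(vals.min()),
        "max EF": float(vals.max()),
        "median EF": float(np.median(vals)),
        "mode EF": float((edges[imax] + edges[imax + 1]) / 2.0),
        "number of ellipsoids found": res.n_ellipsoids_found,
    }


def flinn_data(run: EFRun) -> FlinnData:
    """Semi-axis-ratio scatter data for the Flinn and Flinn peak plots."""
    if not run.ellipsoids:
        raise ValueError("run contains no ellipsoids")
    ratios = np.array([[e.b / e.c, e.a / e.b] for e in run.ellipsoids])
    weights = np.bincount(
        run.claim_id[run.claim_id >= 0].ravel(), minlength=len(run.ellipsoids)
    ).astype(float)
    claimed = weights > 0
    return FlinnData(
        peak_points=ratios[claimed],
        peak_weights=weights[claimed],
        all_points=ratios,
    )


_SECONDARY_FIELDS = ("a", "b", "c", "a_b", "b_c", "volume", "id")


def secondary_images(run: EFRun) -> dict[str, np.ndarray]:
    """Aligned per-voxel grids describing the claiming ellipsoid.

    Keys: ``a``, ``b``, ``c`` (semi-axes), ``a_b``, ``b_c`` (ratios),
    ``volume`` and ``id`` (index in the volume-sorted ellipsoid list); NaN
    where no ellipsoid claims the voxel.  By construction
    ``ef_grid == a_b - b_c`` wherever covered (when EF averages a single
    largest ellipsoid).
    """
    n = len(run.ellipsoids)
    lut = {
        "a": np.array([e.a for e in run.ellipsoids] + [np.nan]),
        "b": np.array([e.b for e in run.ellipsoids] + [np.nan]),
        "c": np.array([e.c for e in run.ellipsoids] + [np.nan]),
        "volume": np.array([e.volume for e in run.ellipsoids] + [np.nan]),
        "id": np.array([float(i) for i in range(n)] + [np.nan]),
    }
    lut["a_b"] = lut["a"] / lut["b"]
    lut["b_c"] = lut["b"] / lut["c"]
    idx = np.where(run.claim_id >= 0, run.claim_id, n)
    return {
        name: lut[name][idx].astype(np.float32) for name in _SECONDARY_FIELDS
    }
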