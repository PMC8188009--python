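"""Run-to-run averaging, convergence reporting and Flinn peak data.

EF is stochastic: every run seeds and fits ellipsoids afresh, so per-voxel
values fluctuate between runs.  Averaging several runs smooths the map; the
median and maximum change of the running mean between consecutive runs
quantify how well it has converged.  The Flinn peak plot shows each
voxel-claiming ellipsoid at (b/c, a/b), weighted by the voxels it claims;
EF is constant along the plot's diagonals.
"""

import numpy as np

from trabshape import RunConfig, compute_ef, flinn_data, make_gyroid

volume = make_gyroid(16, 0.4, 48)
config = RunConfig.production(rng_seed=1)  # skeleton points 1, repetitions 6
result = compute_ef(volume, config)

print(f"gyroid 48^3, {result.n_runs} runs, filling {result.filling_percentage:.1f}%")
print("run  cumulative-filling  median-change  maximum-change")
for n in range(1, result.n_runs + 1):
    med = result.median_change.get(n)
    mx = result.maximum_change.get(n)
    print(
        f"{n:3d}  {result.filling_per_run[n - 1]:17.1f}%"
        + ("" if med is None else f"  {med:13.4f}  {mx:14.4f}")
    )

data = flinn_data(result.runs[-1])
print(
    f"\nFlinn peak plot: {len(data.peak_weights)} voxel-claiming ellipsoids; "
    f"mean (b/c, a/b) = ({np.average(data.peak_points[:, 0], weights=data.peak_weights):.2f}, "
    f"{np.average(data.peak_points[:, 1], weights=data.peak_weights):.2f})"
)
print(
    "A falling median change (typically < 0.15 by run 6) indicates the "
    "averaged EF map has stabilized; the maximum change tracks the most "
    "volatile voxels, usually sparsely covered boundary ones."
)
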