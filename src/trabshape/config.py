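"""Run configuration: the documented EF input parameters plus plumbing.

Parameter names and defaults follow the EF method's published documentation:
100 sampling vectors, sampling increment 1/2.3 voxel, 10 skeleton points
per ellipsoid, contact sensitivity 1, 50 maximum iterations, maximum drift
of one pixel diagonal, 1 repetition, distance-ridge seeding on and
topology-preserving seeding off.  The quick defaults give an overview run;
the :meth:`RunConfig.production` preset switches skeleton points per
ellipsoid to 1 and repetitions to 6, the recommended settings for final
result generation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

from .fitting import FitParams

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    number_of_sampling_vectors: int = 100
    sampling_increment: float = 1.0 / 2.3
    skeleton_points_per_ellipsoid: int = 10
    contact_sensitivity: int = 1
    maximum_iterations: int = 50
    # "unit pixel diagonal" read as the 3D diagonal of one voxel
    maximum_drift: float = math.sqrt(3.0)
    repetitions: int = 1
    seed_distance_ridge: bool = True
    seed_topology: bool = False
    show_secondary_images: bool = False
    show_convergence: bool = False
    average_over_largest_n: int = 1
    rng_seed: int = 0

    @classmethod
    def production(cls, **overrides) -> "RunConfig":
        """Recommended settings for final results: every skeleton point seeds
        an ellipsoid and EF is averaged over six runs."""
        base = {"skeleton_points_per_ellipsoid": 1, "repetitions": 6}
        base.update(overrides)
        return cls(**base)

    def fit_params(self) -> FitParams:
        return FitParams(
            n_vectors=self.number_of_sampling_vectors,
            sampling_increment=self.sampling_increment,
            contact_sensitivity=self.contact_sensitivity,
            max_iterations=self.maximum_iterations,
            max_drift=self.maximum_drift,
        )

    # -- plain-text key = value round-trip ------------------------------
    def to_text(self) -> str:
        lines = []
        for field in dataclasses.fields(self):
            lines.append(f"{field.name.replace('_', '-')} = {getattr(self, field.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a plain-text ``key = value`` configuration file.

        Keys are the kebab-cased parameter names; blank lines and ``#``
        comments are ignored.
        """
        values = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"expected 'key = value', got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            name = key.replace("-", "_")
            if name not in types:
                raise ValueError(f"unknown parameter {key!r}")
            kind = types[name]
            if kind == "bool":
                values[name] = val.lower() in ("1", "true", "yes", "on")
            elif kind == "int":
                values[name] = int(val)
            elif kind == "float":
                values[name] = float(val)
            else:
                values[name] = val
        return cls(**values)
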