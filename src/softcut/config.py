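"""Run configuration: a single YAML file describing a whole experiment.

Every knob of the demo scene lives here — geometry, material, time step,
tool trajectory, table layout, solver settings — so a run is reproducible
from one small text file.  Validation errors name the offending field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # torus geometry
    major_radius: float = 1.0        # R
    minor_radius: float = 0.3        # r
    grid_spacing: float = 0.15       # h
    surface_n_u: int = 48            # major subdivisions of the render mesh
    surface_n_v: int = 24            # minor subdivisions

    # material (soft-tissue-like defaults)
    young_modulus: float = 1.0e4     # Pa
    poisson_ratio: float = 0.45
    density: float = 1000.0          # kg/m^3

    # time integration
    dt: float = 1.0 / 60.0           # s
    n_frames: int = 200
    gravity: tuple[float, float, float] = (0.0, 0.0, -9.81)

    # tool trajectory: a blade sweeping the tube cross-section
    cut_start_frame: int = 20
    cut_n_frames: int = 60
    cut_margin: float = 0.5          # blade overshoot as a fraction of r

    # table layout
    batch_size: int = 64
    max_row_width: int = 16
    k_min: int = 8
    batching: bool = True

    # solver
    cg_tolerance: float = 1.0e-6
    cg_max_iterations: int = 0       # 0 -> 10 * n_nodes
    precision: str = "double"        # or "single"
    seed: int = 0

    # anchor: nodes with x < -(R - r/2) are Dirichlet-fixed
    fix_left: bool = True

    def validate(self) -> "RunConfig":
        def bad(name: str, why: str):
            raise ConfigError(f"config field {name!r} {why}", field=name)

        if not 0 < self.grid_spacing < self.minor_radius < self.major_radius:
            bad("grid_spacing", "must satisfy 0 < h < r < R")
        if self.surface_n_u < 3 or self.surface_n_v < 3:
            bad("surface_n_u", "surface subdivisions must be >= 3")
        if self.young_modulus <= 0:
            bad("young_modulus", "must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            bad("poisson_ratio", "must be in [0, 0.5)")
        if self.density <= 0:
            bad("density", "must be > 0")
        if self.dt <= 0:
            bad("dt", "must be > 0")
        if self.n_frames < 0:
            bad("n_frames", "must be >= 0")
        if len(tuple(self.gravity)) != 3:
            bad("gravity", "must be a 3-vector")
        if self.cut_n_frames > 0 and self.cut_n_frames < 2:
            bad("cut_n_frames", "must be 0 (no cut) or >= 2")
        if self.cut_start_frame < 0:
            bad("cut_start_frame", "must be >= 0")
        if self.batch_size < 1:
            bad("batch_size", "must be >= 1")
        if self.max_row_width < self.k_min:
            bad("max_row_width", "must be >= k_min")
        if self.k_min < 4:
            bad("k_min", "must be >= 4")
        if self.cg_tolerance <= 0:
            bad("cg_tolerance", "must be > 0")
        if self.cg_max_iterations < 0:
            bad("cg_max_iterations", "must be >= 0")
        if self.precision not in ("single", "double"):
            bad("precision", "must be 'single' or 'double'")
        return self

    # -- (de)serialization ----------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["gravity"] = list(self.gravity)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown config field(s): {sorted(unknown)}",
                field=sorted(unknown)[0],
            )
        if "gravity" in data:
            data = dict(data)
            data["gravity"] = tuple(float(g) for g in data["gravity"])
        return cls(**data).validate()
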