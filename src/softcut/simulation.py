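"""End-to-end simulation loop: cut, flush, deform, update surface.

Frame order follows the main loop of the underlying method: cut detection
-> cut application -> deformation computation -> surface position update,
with every mirrored table flushed exactly once per frame so the transfer
ledger reflects what a device copy of the tables would receive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .cutting import CutSurface, apply_cut, detect_cut_links, sweep_tool
from .dynamics import MaterialParams, SimState, StepInputs, lumped_mass, step
from .model import (
    SurfaceMesh,
    ToolTrajectory,
    VolumeModel,
    default_cut_trajectory,
    generate_torus_surface,
    generate_torus_volume,
)
from .surface import update_surface_positions
from .tables import SimTables, build_sim_tables


@dataclass
class FrameLog:
    frame: int
    cg_iterations: int
    cg_residual: float
    cg_converged: bool
    max_displacement: float


@dataclass
class CutLog:
    frame: int
    n_severed_volume_links: int
    n_severed_surface_links: int
    n_modified_elements: int
    n_overflow_warnings: int


@dataclass
class Scene:
    """Everything a run needs, generated deterministically from a config."""

    config: RunConfig
    model: VolumeModel
    surface: SurfaceMesh | None
    trajectory: ToolTrajectory | None
    tables: SimTables
    material: MaterialParams
    fixed_mask: np.ndarray


def build_scene(config: RunConfig, with_surface: bool = True) -> Scene:
    """Generate the torus demo scene described by a config."""
    config.validate()
    model = generate_torus_volume(
        config.major_radius, config.minor_radius, config.grid_spacing
    )
    surface = (
        generate_torus_surface(
            config.major_radius, config.minor_radius,
            config.surface_n_u, config.surface_n_v,
        )
        if with_surface
        else None
    )
    trajectory = (
        default_cut_trajectory(
            config.major_radius, config.minor_radius,
            config.cut_n_frames, margin=config.cut_margin,
        )
        if config.cut_n_frames >= 2
        else None
    )
    tables = build_sim_tables(
        model,
        surface,
        k_min=config.k_min,
        max_row_width=config.max_row_width,
        batch_size=config.batch_size,
        batched=config.batching,
    )
    material = MaterialParams(
        young_modulus=config.young_modulus,
        poisson_ratio=config.poisson_ratio,
        density=config.density,
    )
    fixed_mask = np.zeros(model.n_nodes, dtype=bool)
    if config.fix_left:
        threshold = -(config.major_radius - config.minor_radius / 2.0)
        fixed_mask = model.node_positions[:, 0] < threshold
    return Scene(
        config=config,
        model=model,
        surface=surface,
        trajectory=trajectory,
        tables=tables,
        material=material,
        fixed_mask=fixed_mask,
    )


class Simulation:
    """Runs the per-frame loop of a :class:`Scene` and collects logs."""

    def __init__(self, scene: Scene, out_dir: str | Path | None = None,
                 export_obj: bool = False) -> None:
        self.scene = scene
        cfg = scene.config
        self.dtype = np.float32 if cfg.precision == "single" else np.float64
        self.state = SimState.rest(
            scene.model.n_nodes, scene.fixed_mask.copy(), dtype=self.dtype
        )
        self.cut_surface = CutSurface(
            min_area=1e-12 * scene.model.grid_spacing**2
        )
        self.mass = self._compute_mass()
        self.frame_log: list[FrameLog] = []
        self.cut_log: list[CutLog] = []
        self.out_dir = Path(out_dir) if out_dir is not None else None
        self.export_obj = export_obj and scene.surface is not None
        if self.out_dir is not None:
            self.out_dir.mkdir(parents=True, exist_ok=True)
        self._frozen = np.zeros(scene.model.n_nodes, dtype=bool)

    # -- pieces ----------------------------------------------------------

    def _compute_mass(self) -> np.ndarray:
        t = self.scene.tables
        return lumped_mass(
            self.scene.model.element_volumes, t.connectivity, t.shapes.values,
            self.scene.material, self.scene.model.n_nodes,
        )

    def _gravity_force(self) -> np.ndarray:
        g = np.asarray(self.scene.config.gravity, dtype=float)
        f = self.mass[:, None] * g[None, :]
        f[self._frozen] = 0.0
        return f

    def _refresh_frozen(self) -> None:
        """Nodes no longer referenced by any element become inert debris:
        no gravity, velocity zeroed, they keep their current position."""
        t = self.scene.tables
        conn = t.connectivity
        mask = (
            np.arange(conn.max_row_width)[None, :] < conn.row_lengths[:, None]
        )
        referenced = np.zeros(self.scene.model.n_nodes, dtype=bool)
        referenced[conn.payload[mask].astype(np.int64)] = True
        self._frozen = ~referenced
        self.state.v[self._frozen] = 0.0

    def _tool_frames(self, frame: int) -> tuple[np.ndarray, np.ndarray] | None:
        traj = self.scene.trajectory
        if traj is None:
            return None
        start = self.scene.config.cut_start_frame
        i = frame - start
        if 0 <= i < traj.n_frames - 1:
            return traj.frames[i], traj.frames[i + 1]
        return None

    # -- main loop -------------------------------------------------------

    def run_frame(self, frame: int) -> None:
        scene = self.scene
        t = scene.tables

        # 1. cut detection
        n_sev_vol = n_sev_surf = n_modified = n_overflow = 0
        tool = self._tool_frames(frame)
        if tool is not None:
            new_tris = self.cut_surface.add(sweep_tool(*tool), frame)
            if new_tris.shape[0]:
                elem_pairs, vert_pairs = detect_cut_links(
                    scene.model, t.connectivity, t.surface,
                    t.vertex_positions, new_tris,
                )
                n_sev_vol = elem_pairs.shape[0]
                n_sev_surf = vert_pairs.shape[0]
                # 2. cut application
                if n_sev_vol or n_sev_surf:
                    result = apply_cut(
                        scene.model, t, self.cut_surface,
                        elem_pairs, vert_pairs, on_overflow="warn",
                    )
                    n_modified = len(result.modified_elements)
                    n_overflow = len(result.overflow_events)
                    if n_modified:
                        self.mass = self._compute_mass()
                        self._refresh_frozen()
        if tool is not None:
            self.cut_log.append(
                CutLog(frame, n_sev_vol, n_sev_surf, n_modified, n_overflow)
            )

        # 3. mirror update: one flush per table per frame
        t.flush(frame)

        # 4. deformation
        cfg = scene.config
        inputs = StepInputs(
            f_ext=self._gravity_force().astype(self.dtype),
            dt=cfg.dt,
            cg_tolerance=cfg.cg_tolerance,
            cg_max_iterations=(cfg.cg_max_iterations or None),
        )
        self.state, res = step(
            self.state, scene.model.element_volumes, t.connectivity,
            t.shapes.gradients, self.mass, scene.material, inputs,
        )
        self.state.v[self._frozen] = 0.0
        if self.dtype is not np.float64:
            self.state.u = self.state.u.astype(self.dtype)
            self.state.v = self.state.v.astype(self.dtype)

        # 5. surface position update
        if scene.surface is not None and t.surface is not None:
            positions = update_surface_positions(
                t.surface, scene.surface, self.state.u
            )
            if self.export_obj and self.out_dir is not None:
                from .io import write_obj_positions

                write_obj_positions(
                    positions, scene.surface.triangles,
                    self.out_dir / f"frame_{frame:05d}.obj",
                )

        self.frame_log.append(
            FrameLog(
                frame=frame,
                cg_iterations=res.iterations,
                cg_residual=res.residual_norm,
                cg_converged=res.converged,
                max_displacement=float(
                    np.linalg.norm(self.state.u, axis=1).max()
                ),
            )
        )

    def run(self, n_frames: int | None = None) -> None:
        if n_frames is None:
            n_frames = self.scene.config.n_frames
        for frame in range(n_frames):
            self.run_frame(frame)

    # -- outputs ---------------------------------------------------------

    def write_logs(self, out_dir: str | Path | None = None) -> None:
        from .io import write_csv

        out = Path(out_dir) if out_dir is not None else self.out_dir
        if out is None:
            raise ValueError("no output directory given")
        out.mkdir(parents=True, exist_ok=True)
        self.scene.tables.ledger.to_csv(out / "ledger.csv")
        write_csv(
            out / "frames.csv",
            ("frame", "cg_iterations", "cg_residual", "cg_converged",
             "max_displacement"),
            (
                {
                    "frame": r.frame,
                    "cg_iterations": r.cg_iterations,
                    "cg_residual": r.cg_residual,
                    "cg_converged": r.cg_converged,
                    "max_displacement": r.max_displacement,
                }
                for r in self.frame_log
            ),
        )
        write_csv(
            out / "cuts.csv",
            ("frame", "n_severed_volume_links", "n_severed_surface_links",
             "n_modified_elements", "n_overflow_warnings"),
            (
                {
                    "frame": r.frame,
                    "n_severed_volume_links": r.n_severed_volume_links,
                    "n_severed_surface_links": r.n_severed_surface_links,
                    "n_modified_elements": r.n_modified_elements,
                    "n_overflow_warnings": r.n_overflow_warnings,
                }
                for r in self.cut_log
            ),
        )
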