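"""Synthetic torus test scene: volume, surface, connectivity, tool path.

The benchmark object is a solid torus (axis z, major radius R, minor
radius r) discretized on a regular grid: simulation nodes at grid points
inside the solid, cubic integration elements at dual-grid cell centers
(offset h/2) with volume h^3 each.  A closed parametric triangle mesh of
the same torus provides the render surface, and a two-point blade segment
sweeping through the tube cross-section provides the cutting tool.
Everything is deterministic given the geometric parameters, so the whole
pipeline is testable without external model files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidGeometryError, RowOverflowError
from .mls import coplanarity_check


@dataclass
class VolumeModel:
    """Node cloud plus cubic integration elements of a volumetric object."""

    node_positions: np.ndarray      # (n_nodes, 3) rest coordinates
    element_centers: np.ndarray     # (n_elems, 3)
    element_volumes: np.ndarray     # (n_elems,), h^3 on a regular grid
    grid_spacing: float

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def n_elements(self) -> int:
        return self.element_centers.shape[0]

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.element_centers = np.asarray(self.element_centers, dtype=float)
        self.element_volumes = np.asarray(self.element_volumes, dtype=float)
        if self.n_nodes < 8 or self.n_elements < 1:
            raise InvalidGeometryError(
                f"degenerate model: {self.n_nodes} nodes, {self.n_elements} elements"
            )
        if np.any(self.element_volumes <= 0):
            raise InvalidGeometryError("element volumes must be positive")


@dataclass
class SurfaceMesh:
    """Triangulated render surface in rest configuration."""

    vertex_rest_positions: np.ndarray  # (n_verts, 3)
    triangles: np.ndarray              # (n_tris, 3) vertex indices, 0-based

    @property
    def n_vertices(self) -> int:
        return self.vertex_rest_positions.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def __post_init__(self) -> None:
        self.vertex_rest_positions = np.asarray(self.vertex_rest_positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices
        ):
            raise InvalidGeometryError("triangle index out of range")

    def edge_census(self) -> dict[tuple[int, int], int]:
        """Count of incident triangles per undirected edge."""
        census: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (int(min(a, b)), int(max(a, b)))
                census[key] = census.get(key, 0) + 1
        return census


@dataclass
class ToolTrajectory:
    """Per-frame polyline of the virtual cutting tool."""

    frames: list[np.ndarray] = field(default_factory=list)  # each (k, 3), k >= 2

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if len(self.frames) < 1:
            raise InvalidGeometryError("trajectory needs at least 1 frame")
        for f in self.frames:
            if f.shape[0] < 2:
                raise InvalidGeometryError("each tool frame needs >= 2 endpoints")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def torus_implicit(points: np.ndarray, R: float, r: float) -> np.ndarray:
    """(sqrt(x^2+y^2) - R)^2 + z^2 - r^2; <= 0 inside the solid torus."""
    pts = np.atleast_2d(points)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    return (rho - R) ** 2 + pts[:, 2] ** 2 - r * r


def inside_torus(points: np.ndarray, R: float, r: float) -> np.ndarray:
    return torus_implicit(points, R, r) <= 0.0


def _grid_coords(lo: float, hi: float, h: float, offset: float) -> np.ndarray:
    """Multiples of h (plus offset) covering [lo, hi]."""
    i0 = int(np.floor((lo - offset) / h)) - 1
    i1 = int(np.ceil((hi - offset) / h)) + 1
    return offset + h * np.arange(i0, i1 + 1)


def generate_torus_volume(R: float, r: float, h: float) -> VolumeModel:
    """Regular-grid node cloud and dual-grid elements of a solid torus.

    Nodes sit on the primal grid (integer multiples of h), element centers
    on the dual grid (offset h/2), both restricted to the solid
    ``(sqrt(x^2+y^2)-R)^2 + z^2 <= r^2``; every element has volume h^3.
    Deterministic given (R, r, h).  Raises
    :class:`InvalidGeometryError` unless ``0 < h < r < R`` and the grid
    yields at least 8 nodes and 1 element.
    """
    if not (0 < h < r < R):
        raise InvalidGeometryError(f"need 0 < h < r < R, got h={h}, r={r}, R={R}")

    def grid_points(offset: float) -> np.ndarray:
        xs = _grid_coords(-(R + r), R + r, h, offset)
        zs = _grid_coords(-r, r, h, offset)
        gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        return pts[inside_torus(pts, R, r)]

    nodes = grid_points(0.0)
    centers = grid_points(h / 2.0)
    if nodes.shape[0] < 8 or centers.shape[0] < 1:
        raise InvalidGeometryError(
            f"grid spacing h={h} produced {nodes.shape[0]} nodes and "
            f"{centers.shape[0]} elements"
        )
    return VolumeModel(
        node_positions=nodes,
        element_centers=centers,
        element_volumes=np.full(centers.shape[0], h**3),
        grid_spacing=h,
    )


def generate_torus_surface(R: float, r: float, n_u: int, n_v: int) -> SurfaceMesh:
    """Closed parametric torus triangulation: n_u*n_v vertices, 2*n_u*n_v
    triangles (two per parameter quad), every edge shared by 2 triangles."""
    if n_u < 3 or n_v < 3:
        raise InvalidGeometryError("need n_u >= 3 and n_v >= 3")
    iu = np.arange(n_u)
    iv = np.arange(n_v)
    theta = 2 * np.pi * iu / n_u          # around the main axis
    phi = 2 * np.pi * iv / n_v            # around the tube
    T, P = np.meshgrid(theta, phi, indexing="ij")
    x = (R + r * np.cos(P)) * np.cos(T)
    y = (R + r * np.cos(P)) * np.sin(T)
    z = r * np.sin(P)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    def vid(i: int, j: int) -> int:
        return (i % n_u) * n_v + (j % n_v)

    tris = []
    for i in range(n_u):
        for j in range(n_v):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    return SurfaceMesh(vertex_rest_positions=verts, triangles=np.array(tris))


def build_initial_connectivity(
    model: VolumeModel,
    k_min: int = 8,
    max_row_width: int = 16,
    coplanarity_tolerance: float = 0.05,
) -> list[np.ndarray]:
    """Per-element neighbor node lists: k_min nearest nodes, extended with
    next-nearest nodes until the set passes the coplanarity spread test.

    Raises :class:`RowOverflowError` for an element whose neighbor set
    cannot be made non-coplanar within ``max_row_width`` nodes (or within
    the model's node count).
    """
    if k_min < 4:
        raise InvalidGeometryError("k_min must be >= 4 for a 3D linear basis")
    tree = cKDTree(model.node_positions)
    h = model.grid_spacing
    k_query = min(model.n_nodes, max(max_row_width, k_min))
    _, nearest = tree.query(model.element_centers, k=k_query)
    nearest = np.atleast_2d(nearest)

    rows: list[np.ndarray] = []
    for e in range(model.n_elements):
        cand = nearest[e]
        k = min(k_min, len(cand))
        while True:
            row = cand[:k]
            if coplanarity_check(
                model.node_positions[row], h, coplanarity_tolerance
            ):
                break
            if k >= max_row_width or k >= len(cand):
                raise RowOverflowError(
                    f"element {e}: no non-coplanar neighbor set within "
                    f"max_row_width={max_row_width}",
                    row_index=e,
                )
            k += 1
        rows.append(np.array(row, dtype=np.int64))
    return rows


def default_cut_trajectory(
    R: float, r: float, n_frames: int, margin: float = 0.5
) -> ToolTrajectory:
    """Two-point blade sweeping through the tube cross-section at theta=0.

    The blade is a vertical segment in the plane y=0 with endpoints at
    z = +-(1+margin) r (always outside the solid); it translates along x
    from R - (1+margin) r to R + (1+margin) r over ``n_frames`` frames, so
    its swept surface bisects the tube.  First and last frames lie entirely
    outside the torus.
    """
    if n_frames < 2:
        raise InvalidGeometryError("a cut trajectory needs >= 2 frames")
    z_ext = (1.0 + margin) * r
    xs = np.linspace(R - z_ext, R + z_ext, n_frames)
    frames = [
        np.array([[x, 0.0, -z_ext], [x, 0.0, z_ext]]) for x in xs
    ]
    return ToolTrajectory(frames=frames)
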