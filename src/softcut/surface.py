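"""Surface-to-volume embedding: vertex weights and position updates.

The render surface is not simulated directly; each vertex carries a short
list of volume nodes with weights, and its deformed position is

    x_v = X_v + sum_i w_i^v u_i

Weights are MLS shape values evaluated at the vertex rest position over
the node set of the vertex's nearest element, so the surface interpolation
is consistent with the volume discretization: weights sum to one, rest
positions are reproduced exactly, and a rigid translation of the nodes
translates every vertex by the same amount.
"""

from __future__ import annotations

import numpy as np

from .errors import RankDeficiencyError
from .mls import effective_radii, mls_evaluate
from .model import SurfaceMesh, VolumeModel


def build_surface_mapping(
    model: VolumeModel, surface: SurfaceMesh, tables
) -> None:
    """Fill the surface-weight table: one row per vertex.

    Each vertex is mapped onto the neighbor node set of its nearest
    element; the weights are the MLS shape values at the vertex rest
    position.  Rank deficiency propagates with the vertex id attached.
    """
    surf_table = tables.surface
    _, nearest_elem = tables.element_tree.query(surface.vertex_rest_positions, k=1)
    nearest_elem = np.atleast_1d(nearest_elem)
    for v in range(surface.n_vertices):
        e = int(nearest_elem[v])
        nodes = tables.connectivity.read_row(e).astype(np.int64)
        x = surface.vertex_rest_positions[v]
        X = model.node_positions[nodes]
        r = effective_radii(x, X, tables.support_radii[nodes])
        try:
            values, _ = mls_evaluate(x, X, r, index=v)
        except RankDeficiencyError as err:
            raise RankDeficiencyError(
                f"surface vertex {v}: {err}", index=v
            ) from err
        row = np.zeros(nodes.size, dtype=surf_table.payload.dtype)
        row["node"] = nodes.astype(np.int32)
        row["weight"] = values
        surf_table.write_row(v, row)


def update_surface_positions(
    surface_table, surface: SurfaceMesh, u: np.ndarray
) -> np.ndarray:
    """Deformed vertex positions x_v = X_v + sum_i w_i^v u_i (vectorized)."""
    payload = surface_table.payload
    lengths = surface_table.row_lengths
    mask = np.arange(surface_table.max_row_width)[None, :] < lengths[:, None]
    w = np.where(mask, payload["weight"], 0.0)            # (V, W)
    nodes = np.where(mask, payload["node"], 0).astype(np.int64)
    disp = np.einsum("vw,vwa->va", w, u[nodes])
    return surface.vertex_rest_positions + disp
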