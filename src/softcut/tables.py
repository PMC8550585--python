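"""Assembly of the four mirrored tables for one simulated object.

The per-object state a device mirror would hold consists of four
fixed-width tables sharing one ledger:

* ``connectivity`` — element row -> neighbor node indices (int32),
* ``shape_values`` / ``shape_gradients`` — MLS data per element-node pair,
  row-aligned with the connectivity,
* ``surface_weights`` — vertex row -> (node index, weight) records.

Rest-configuration support radii and KD-trees over nodes and element
centers are built once and reused; they never change during a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mls import ShapeTables, node_support_radii, recompute_element_shapes
from .model import SurfaceMesh, VolumeModel, build_initial_connectivity
from .store import FixedWidthTable, TransferLedger

#: Structured item of the surface-weight table: node index + weight.
SURFACE_ITEM_DTYPE = np.dtype([("node", np.int32), ("weight", np.float64)])


@dataclass
class SimTables:
    """The mirrored tables plus the fixed precomputed context around them."""

    connectivity: FixedWidthTable
    shapes: ShapeTables
    surface: FixedWidthTable | None
    ledger: TransferLedger
    support_radii: np.ndarray
    node_tree: cKDTree
    element_tree: cKDTree
    vertex_positions: np.ndarray | None = None
    k_min: int = 8
    coplanarity_tolerance: float = 0.05

    def all_tables(self) -> list[FixedWidthTable]:
        out = [self.connectivity, self.shapes.values, self.shapes.gradients]
        if self.surface is not None:
            out.append(self.surface)
        return out

    def flush(self, frame: int | None = None) -> dict[str, list[tuple[int, int]]]:
        """Flush every table once; returns per-table transfer plans."""
        return {t.name: t.flush(frame) for t in self.all_tables()}


def build_sim_tables(
    model: VolumeModel,
    surface: SurfaceMesh | None = None,
    k_min: int = 8,
    max_row_width: int = 16,
    batch_size: int = 64,
    batched: bool = True,
    coplanarity_tolerance: float = 0.05,
) -> SimTables:
    """Build connectivity, shape and surface tables for a model.

    Connectivity rows are the k_min-nearest neighbor sets (extended to
    cure coplanarity); shape rows are MLS evaluations at element centers;
    surface rows (when a surface is given) are built by
    :func:`softcut.surface.build_surface_mapping`.
    """
    ledger = TransferLedger()
    batch_size = min(batch_size, model.n_elements)
    rows = build_initial_connectivity(
        model, k_min=k_min, max_row_width=max_row_width,
        coplanarity_tolerance=coplanarity_tolerance,
    )
    connectivity = FixedWidthTable(
        model.n_elements, max_row_width, dtype=np.int32,
        batch_size=batch_size, batched=batched,
        name="connectivity", ledger=ledger,
    )
    shapes = ShapeTables(
        model.n_elements, max_row_width, batch_size=batch_size,
        batched=batched, ledger=ledger,
    )
    support_radii = node_support_radii(
        model.node_positions, model.element_centers, k_min=k_min
    )
    for e, row in enumerate(rows):
        connectivity.write_row(e, row.astype(np.int32))
        recompute_element_shapes(
            model.node_positions, model.element_centers[e], row, e,
            shapes, support_radii,
        )

    tables = SimTables(
        connectivity=connectivity,
        shapes=shapes,
        surface=None,
        ledger=ledger,
        support_radii=support_radii,
        node_tree=cKDTree(model.node_positions),
        element_tree=cKDTree(model.element_centers),
        k_min=k_min,
        coplanarity_tolerance=coplanarity_tolerance,
    )
    if surface is not None:
        from .surface import build_surface_mapping

        tables.surface = FixedWidthTable(
            surface.n_vertices, max_row_width, dtype=SURFACE_ITEM_DTYPE,
            batch_size=min(batch_size, surface.n_vertices), batched=batched,
            name="surface_weights", ledger=ledger,
        )
        tables.vertex_positions = surface.vertex_rest_positions
        build_surface_mapping(model, surface, tables)
    # the initial upload is not a frame edit: start clean
    for t in tables.all_tables():
        t.flush(frame=None)
    return tables
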