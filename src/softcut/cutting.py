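"""Topology changes: swept-tool cut surface, link severing, reconnection.

A cut is represented by the surface the tool blade sweeps between two
frames: each blade segment contributes one quad (its positions at frames t
and t+1), split into two triangles.  An element-node or vertex-node link is
severed when the straight segment between the two rest positions crosses a
newly swept triangle; after severing, elements that fall below the minimum
neighbor count or fail the coplanarity spread test are topped up with their
nearest *visible* nodes — nodes whose connecting segment crosses none of
the accumulated cut surface — so material on opposite sides of a cut never
re-couples.

All link tests run in rest coordinates, consistent with the
total-Lagrangian shape functions.  Segment-triangle intersection uses
orientation (signed-volume) tests with ties counted as hits, so links that
merely graze the blade are severed conservatively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import RankDeficiencyError, RowOverflowError, SoftcutError
from .mls import coplanarity_check, recompute_element_shapes
from .model import VolumeModel

log = logging.getLogger(__name__)


class CutSurface:
    """Accumulated swept-tool triangles with per-triangle frame stamps.

    Triangles with area below ``min_area`` (degenerate sweeps, e.g. a
    stationary tool) are discarded on insertion.
    """

    def __init__(self, min_area: float = 0.0) -> None:
        self.min_area = float(min_area)
        self.triangles = np.zeros((0, 3, 3))
        self.frame_stamps = np.zeros(0, dtype=np.int64)

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def add(self, triangles: np.ndarray, frame: int) -> np.ndarray:
        """Append non-degenerate triangles; returns the ones kept."""
        tris = np.asarray(triangles, dtype=float).reshape(-1, 3, 3)
        if tris.shape[0]:
            ab = tris[:, 1] - tris[:, 0]
            ac = tris[:, 2] - tris[:, 0]
            area = 0.5 * np.linalg.norm(np.cross(ab, ac), axis=1)
            tris = tris[area > self.min_area]
        if tris.shape[0]:
            self.triangles = np.concatenate([self.triangles, tris])
            self.frame_stamps = np.concatenate(
                [self.frame_stamps, np.full(tris.shape[0], frame, dtype=np.int64)]
            )
        return tris


def sweep_tool(tool_prev: np.ndarray, tool_next: np.ndarray) -> np.ndarray:
    """Triangles swept by a polyline tool between two frames.

    For each segment the quad (a0, b0, b1, a1) — endpoints at the earlier
    and later frame — is split along one diagonal into (a0, b0, b1) and
    (a0, b1, a1).  Degenerate (zero-area) triangles are kept here and
    filtered by :class:`CutSurface.add`.  Raises :class:`SoftcutError` on
    mismatched endpoint counts.
    """
    prev = np.asarray(tool_prev, dtype=float)
    nxt = np.asarray(tool_next, dtype=float)
    if prev.shape != nxt.shape:
        raise SoftcutError(
            f"tool polylines differ in endpoint count: {prev.shape} vs {nxt.shape}"
        )
    a0, b0 = prev[:-1], prev[1:]
    a1, b1 = nxt[:-1], nxt[1:]
    t1 = np.stack([a0, b0, b1], axis=1)
    t2 = np.stack([a0, b1, a1], axis=1)
    return np.concatenate([t1, t2])


#: Relative tolerance for orientation signs: a signed volume below
#: ORIENT_EPS times the Hadamard bound of its edge lengths counts as zero
#: (a tie).  This makes tie classification immune to the rounding
#: differences between algebraically equivalent determinant formulas.
ORIENT_EPS = 1e-10


def _orient_sign(a, b, c, d):
    """Sign (-1/0/+1) of det(b-a, c-a, d-a), broadcastable, with ties
    snapped to zero below ``ORIENT_EPS`` times the edge-norm product."""
    u, v, w = b - a, c - a, d - a
    det = np.einsum("...i,...i->...", np.cross(u, v), w)
    scale = (
        np.linalg.norm(u, axis=-1)
        * np.linalg.norm(v, axis=-1)
        * np.linalg.norm(w, axis=-1)
    )
    return np.where(np.abs(det) <= ORIENT_EPS * scale, 0.0, np.sign(det))


def segments_cross_triangles(
    seg_start: np.ndarray, seg_end: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Boolean (L,) — does each segment hit *any* triangle (inclusive)?

    Orientation-test formulation: endpoints on opposite (or touching)
    sides of the triangle plane, and the three segment-edge orientations
    all share a sign (zeros allowed).  Ties — the segment touching an
    edge, vertex or the plane — count as intersections, which makes
    severing conservative.  The one exception is a segment lying entirely
    *in* the triangle's plane (both endpoint orientations zero): it grazes
    the blade rather than crossing it and is not counted.
    """
    P = np.asarray(seg_start, dtype=float)[:, None, :]   # (L, 1, 3)
    Q = np.asarray(seg_end, dtype=float)[:, None, :]
    tris = np.asarray(triangles, dtype=float)
    if tris.shape[0] == 0 or P.shape[0] == 0:
        return np.zeros(P.shape[0], dtype=bool)
    A = tris[None, :, 0, :]                              # (1, T, 3)
    B = tris[None, :, 1, :]
    C = tris[None, :, 2, :]
    s1 = _orient_sign(P, A, B, C)
    s2 = _orient_sign(Q, A, B, C)
    # opposite sides or touching, but not lying within the plane
    straddle = ~(s1 * s2 > 0) & ~((s1 == 0) & (s2 == 0))
    t1 = _orient_sign(P, Q, A, B)
    t2 = _orient_sign(P, Q, B, C)
    t3 = _orient_sign(P, Q, C, A)
    same_sign = ((t1 >= 0) & (t2 >= 0) & (t3 >= 0)) | (
        (t1 <= 0) & (t2 <= 0) & (t3 <= 0)
    )
    return np.any(straddle & same_sign, axis=1)


def _aabb_prefilter(
    seg_start: np.ndarray, seg_end: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Segments whose AABB overlaps the triangle set's AABB (candidates)."""
    tlo = triangles.min(axis=(0, 1))
    thi = triangles.max(axis=(0, 1))
    slo = np.minimum(seg_start, seg_end)
    shi = np.maximum(seg_start, seg_end)
    return np.all((shi >= tlo) & (slo <= thi), axis=1)


def segments_visible(
    seg_start: np.ndarray, seg_end: np.ndarray, cut_surface: CutSurface
) -> np.ndarray:
    """True where the segment crosses no accumulated cut triangle.

    An axis-aligned bounding-box prefilter skips segments that cannot
    possibly reach the cut surface; the exact test decides the rest.
    """
    seg_start = np.atleast_2d(np.asarray(seg_start, dtype=float))
    seg_end = np.atleast_2d(np.asarray(seg_end, dtype=float))
    out = np.ones(seg_start.shape[0], dtype=bool)
    if cut_surface.n_triangles == 0:
        return out
    cand = _aabb_prefilter(seg_start, seg_end, cut_surface.triangles)
    if cand.any():
        hit = segments_cross_triangles(
            seg_start[cand], seg_end[cand], cut_surface.triangles
        )
        out[np.flatnonzero(cand)] = ~hit
    return out


def _link_arrays(table) -> tuple[np.ndarray, np.ndarray]:
    """(row_index, node_index) pairs for the occupied slots of a table."""
    lengths = table.row_lengths
    width = table.max_row_width
    mask = np.arange(width)[None, :] < lengths[:, None]
    rows = np.repeat(np.arange(table.n_rows), lengths)
    payload = table.payload
    if payload.dtype.names:  # structured (node, weight) table
        nodes = payload["node"][mask].astype(np.int64)
    else:
        nodes = payload[mask].astype(np.int64)
    return rows, nodes


def detect_cut_links(
    model: VolumeModel,
    connectivity,
    surface_mapping,
    vertex_positions: np.ndarray | None,
    new_triangles: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Links crossed by newly swept triangles, in rest coordinates.

    Returns ``(element_node_pairs, vertex_node_pairs)`` as integer arrays
    of shape (k, 2).  A link is severed iff the straight segment from the
    element center (resp. surface-vertex rest position) to the node rest
    position intersects any of ``new_triangles`` (boundary inclusive).
    ``surface_mapping`` may be None when no surface is attached.
    """
    tris = np.asarray(new_triangles, dtype=float).reshape(-1, 3, 3)

    def severed(rows, nodes, origins):
        if tris.shape[0] == 0 or rows.size == 0:
            return np.zeros((0, 2), dtype=np.int64)
        starts = origins[rows]
        ends = model.node_positions[nodes]
        cand = _aabb_prefilter(starts, ends, tris)
        hit = np.zeros(rows.size, dtype=bool)
        if cand.any():
            hit[cand] = segments_cross_triangles(starts[cand], ends[cand], tris)
        return np.column_stack([rows[hit], nodes[hit]])

    e_rows, e_nodes = _link_arrays(connectivity)
    elem_pairs = severed(e_rows, e_nodes, model.element_centers)
    if surface_mapping is None or vertex_positions is None:
        vert_pairs = np.zeros((0, 2), dtype=np.int64)
    else:
        v_rows, v_nodes = _link_arrays(surface_mapping)
        vert_pairs = severed(v_rows, v_nodes, np.asarray(vertex_positions, dtype=float))
    return elem_pairs, vert_pairs


@dataclass
class CutApplyResult:
    """Bookkeeping from one frame's cut application."""

    modified_elements: list[int] = field(default_factory=list)
    modified_vertices: list[int] = field(default_factory=list)
    overflow_events: list[int] = field(default_factory=list)


def _select_replacements(
    model: VolumeModel,
    tables,
    element: int,
    row: list[int],
    banned: set[int],
    cut_surface: CutSurface,
    k_min: int,
) -> list[int] | None:
    """Extend ``row`` with nearest visible nodes until it has >= k_min
    members and passes the coplanarity test; None when impossible within
    the fixed row width."""
    h = model.grid_spacing
    center = model.element_centers[element]
    max_width = tables.connectivity.max_row_width

    def ok(cur: list[int]) -> bool:
        return len(cur) >= k_min and coplanarity_check(
            model.node_positions[cur], h, tables.coplanarity_tolerance
        )

    if len(row) >= 4 and ok(row):
        return row
    k_query = min(model.n_nodes, 4 * max_width)
    _, cand = tables.node_tree.query(center, k=k_query)
    cand = np.atleast_1d(cand)
    in_row = set(row)
    cand = [c for c in map(int, cand) if c not in in_row and c not in banned]
    if cand:
        starts = np.broadcast_to(center, (len(cand), 3))
        vis = segments_visible(starts, model.node_positions[cand], cut_surface)
        cand = [c for c, v in zip(cand, vis) if v]
    cur = list(row)
    for c in cand:
        if len(cur) >= max_width:
            break
        cur.append(c)
        if len(cur) >= k_min and ok(cur):
            return cur
    if len(cur) >= 4 and ok(cur):
        return cur
    return None


def apply_cut(
    model: VolumeModel,
    tables,
    cut_surface: CutSurface,
    severed_elem_pairs: np.ndarray,
    severed_vertex_pairs: np.ndarray,
    on_overflow: str = "raise",
) -> CutApplyResult:
    """Sever links, re-select neighbors, refresh shapes and vertex weights.

    Severed nodes are removed from their element rows; rows left short of
    ``k_min`` neighbors or coplanar are topped up with nearest visible
    nodes, and the shape rows of every modified element are re-evaluated.
    Vertex rows lose their severed nodes and have the remaining weights
    renormalized; a vertex whose weights collapse is remapped to the
    nearest visible element's node set.  Exactly the modified rows become
    dirty in their tables.

    ``on_overflow='raise'`` raises :class:`RowOverflowError` when an
    element cannot reach a non-coplanar neighbor set within the fixed row
    width; ``'warn'`` leaves that element's row unsevered (the cut locally
    fails) and records it in ``overflow_events``.
    """
    if on_overflow not in ("raise", "warn"):
        raise ValueError("on_overflow must be 'raise' or 'warn'")
    result = CutApplyResult()
    conn = tables.connectivity
    k_min = tables.k_min

    sev_by_elem: dict[int, set[int]] = {}
    for e, n in np.asarray(severed_elem_pairs, dtype=np.int64).reshape(-1, 2):
        sev_by_elem.setdefault(int(e), set()).add(int(n))

    for e, banned in sorted(sev_by_elem.items()):
        old_row = [int(i) for i in conn.read_row(e)]
        row = [i for i in old_row if i not in banned]
        if row == old_row:
            continue
        new_row = _select_replacements(
            model, tables, e, row, banned, cut_surface, k_min
        )
        if new_row is None:
            if on_overflow == "raise":
                raise RowOverflowError(
                    f"element {e}: cannot rebuild a non-coplanar neighbor set "
                    f"within max_row_width={conn.max_row_width} after cut",
                    row_index=e,
                )
            warnings.warn(
                f"element {e}: cut not applied (neighbor overflow)", stacklevel=2
            )
            result.overflow_events.append(e)
            continue
        try:
            # evaluate shapes before any write so errors leave tables intact
            conn_row = np.asarray(new_row, dtype=np.int64)
            recompute_element_shapes(
                model.node_positions,
                model.element_centers[e],
                conn_row,
                e,
                tables.shapes,
                tables.support_radii,
            )
        except RankDeficiencyError:
            if on_overflow == "raise":
                raise
            warnings.warn(
                f"element {e}: cut not applied (rank-deficient rebuild)",
                stacklevel=2,
            )
            result.overflow_events.append(e)
            continue
        conn.write_row(e, conn_row)
        result.modified_elements.append(e)

    if tables.surface is not None and np.asarray(severed_vertex_pairs).size:
        result.modified_vertices = _apply_surface_severing(
            model, tables, cut_surface, severed_vertex_pairs
        )
    return result


def _apply_surface_severing(
    model: VolumeModel,
    tables,
    cut_surface: CutSurface,
    severed_vertex_pairs: np.ndarray,
) -> list[int]:
    surf = tables.surface
    verts = tables.vertex_positions
    sev_by_vert: dict[int, set[int]] = {}
    for v, n in np.asarray(severed_vertex_pairs, dtype=np.int64).reshape(-1, 2):
        sev_by_vert.setdefault(int(v), set()).add(int(n))

    modified: list[int] = []
    for v, banned in sorted(sev_by_vert.items()):
        row = surf.read_row(v)
        keep = ~np.isin(row["node"].astype(np.int64), list(banned))
        if keep.all():
            continue
        kept = row[keep]
        wsum = float(kept["weight"].sum())
        if kept.size == 0 or wsum < 1e-9:
            new_row = _remap_vertex(model, tables, cut_surface, v)
            if new_row is None:
                # a vertex lying exactly in the cut surface sees no element;
                # it keeps its previous mapping
                log.debug("vertex %d: no visible element to remap to", v)
                continue
            surf.write_row(v, new_row)
        else:
            kept = kept.copy()
            kept["weight"] /= wsum
            surf.write_row(v, kept)
        modified.append(v)
    return modified


def _remap_vertex(model, tables, cut_surface, v: int):
    """Rebuild a vertex's mapping from the nearest visible element."""
    from .mls import effective_radii, mls_evaluate

    x = tables.vertex_positions[v]
    k = min(model.n_elements, 16)
    _, elems = tables.element_tree.query(x, k=k)
    for e in np.atleast_1d(elems):
        e = int(e)
        center = model.element_centers[e]
        if not segments_visible(x[None, :], center[None, :], cut_surface)[0]:
            continue
        nodes = tables.connectivity.read_row(e).astype(np.int64)
        if nodes.size < 4:
            continue
        vis = segments_visible(
            np.broadcast_to(x, (nodes.size, 3)), model.node_positions[nodes],
            cut_surface,
        )
        nodes = nodes[vis]
        if nodes.size < 4:
            continue
        X = model.node_positions[nodes]
        r = effective_radii(x, X, tables.support_radii[nodes])
        try:
            values, _ = mls_evaluate(x, X, r, index=v)
        except RankDeficiencyError:
            continue
        out = np.zeros(nodes.size, dtype=tables.surface.payload.dtype)
        out["node"] = nodes.astype(np.int32)
        out["weight"] = values
        return out
    return None
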