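"""Moving-least-squares shape functions for the meshless discretization.

Shape values and gradients are computed with a linear basis
``p(x) = (1, x, y, z)`` and the C2 cubic B-spline weight of normalized
distance ``q = |x - x_i| / r_i``:

    w(q) = 2/3 - 4 q^2 + 4 q^3          for q <= 1/2
    w(q) = 4/3 (1 - q)^3                for 1/2 < q <= 1
    w(q) = 0                            otherwise

With this construction the shape functions satisfy, exactly up to
round-off, partition of unity (sum phi = 1), gradient consistency
(sum grad phi = 0) and linear reproduction (sum phi_i x_i = x) — the
properties that make rigid translations strain-free.

Shape functions are evaluated at rest positions only (total-Lagrangian
small-strain setting) and stored row-aligned with the element-node
connectivity table, so a cut only forces a re-evaluation of the rows it
modified.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientPointsError, RankDeficiencyError, TableConsistencyError
from .store import FixedWidthTable, TransferLedger

#: Moment matrices with a condition number beyond this are treated as
#: singular — the discrete symptom of a (nearly) coplanar neighbor set.
CONDITION_LIMIT = 1e12


def cubic_bspline_weight(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weight ``w(q)`` and derivative ``dw/dq`` of the C2 cubic B-spline.

    Vectorized; returns zeros outside the unit support.
    """
    q = np.asarray(q, dtype=float)
    w = np.zeros_like(q)
    dw = np.zeros_like(q)
    inner = q <= 0.5
    outer = (q > 0.5) & (q <= 1.0)
    qi = q[inner]
    w[inner] = 2.0 / 3.0 - 4.0 * qi**2 + 4.0 * qi**3
    dw[inner] = -8.0 * qi + 12.0 * qi**2
    qo = q[outer]
    w[outer] = (4.0 / 3.0) * (1.0 - qo) ** 3
    dw[outer] = -4.0 * (1.0 - qo) ** 2
    return w, dw


def mls_evaluate(
    eval_point: np.ndarray,
    neighbor_positions: np.ndarray,
    support_radii: np.ndarray,
    *,
    index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shape values and spatial gradients at one evaluation point.

    Parameters
    ----------
    eval_point : (3,) array
    neighbor_positions : (k, 3) array, k >= 4, non-coplanar
    support_radii : (k,) array of per-neighbor support radii
    index : attached to the error when the moment matrix is singular

    Returns
    -------
    values : (k,) array — phi_i(x)
    gradients : (k, 3) array — grad phi_i(x)
    """
    x = np.asarray(eval_point, dtype=float)
    X = np.asarray(neighbor_positions, dtype=float)
    r = np.asarray(support_radii, dtype=float)
    k = X.shape[0]
    if k < 4:
        raise InsufficientPointsError(f"MLS needs >= 4 neighbors, got {k}")

    diff = x - X                       # (k, 3)
    d = np.linalg.norm(diff, axis=1)   # (k,)
    q = d / r
    w, dw_dq = cubic_bspline_weight(q)
    # dq/dx = (x - X_i) / (r_i d); the dw*dq/dx product tends to 0 as d -> 0
    safe = d > 1e-300
    dwdx = np.zeros_like(diff)
    dwdx[safe] = (dw_dq[safe] / (r[safe] * d[safe]))[:, None] * diff[safe]

    # linear basis at neighbors and at the evaluation point
    P = np.empty((k, 4))
    P[:, 0] = 1.0
    P[:, 1:] = X
    px = np.array([1.0, x[0], x[1], x[2]])
    dpx = np.zeros((3, 4))
    dpx[:, 1:] = np.eye(3)

    A = (w[:, None] * P).T @ P                         # (4, 4) moment matrix
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise RankDeficiencyError(
            f"MLS moment matrix is rank-deficient (cond={cond:.3g}); "
            "neighbor set is (nearly) coplanar",
            index=index,
        )
    gamma = np.linalg.solve(A, px)                     # (4,)
    values = w * (P @ gamma)                           # phi_i = gamma . b_i

    # gradients: d(phi_i) = dgamma_k . b_i + gamma . db_i/dx_k
    # dgamma_k = A^-1 (dp/dx_k - dA_k gamma),  dA_k = sum dw_j/dx_k p_j p_j^T
    Pg = P @ gamma                                     # (k,)
    dA_gamma = np.einsum("ka,k,kb->ab", P, Pg, dwdx)   # (4, 3): sum_j p_j (p_j.g) dw_j
    rhs = dpx.T - dA_gamma                             # (4, 3)
    dgamma = np.linalg.solve(A, rhs)                   # (4, 3)
    gradients = w[:, None] * (P @ dgamma) + dwdx * Pg[:, None]
    return values, gradients


def coplanarity_check(
    points: np.ndarray, h: float, tolerance_fraction: float = 0.05
) -> bool:
    """Spread test: does the point set span 3D well enough for MLS?

    True iff the smallest eigenvalue of the centered covariance (mean
    normalization) exceeds ``(tolerance_fraction * h)**2`` for grid
    spacing ``h``.  Raises :class:`InsufficientPointsError` below 4 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise InsufficientPointsError(
            f"coplanarity test needs >= 4 points, got {pts.shape[0]}"
        )
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    smallest = np.linalg.eigvalsh(cov)[0]
    return bool(smallest > (tolerance_fraction * h) ** 2)


def node_support_radii(
    node_positions: np.ndarray, element_centers: np.ndarray, k_min: int = 8
) -> np.ndarray:
    """Per-node support radius: 1.1x the distance to the k_min-th nearest
    element center at rest.  Fixed once; never recomputed during a run."""
    from scipy.spatial import cKDTree

    k = min(k_min, element_centers.shape[0])
    tree = cKDTree(element_centers)
    d, _ = tree.query(node_positions, k=k)
    if d.ndim == 1:  # k == 1
        d = d[:, None]
    return 1.1 * d[:, -1]


def effective_radii(
    eval_point: np.ndarray, neighbor_positions: np.ndarray, support_radii: np.ndarray
) -> np.ndarray:
    """Support radii guaranteed to cover the evaluation point.

    The fixed rest-configuration radii occasionally leave a far neighbor
    (appended to cure coplanarity, or a surface vertex near the boundary)
    just outside support, which would zero its weight and can starve the
    moment matrix.  Those radii — and only those — are expanded to 1.05x
    the actual distance so every stored pair carries a positive weight.
    """
    d = np.linalg.norm(np.asarray(eval_point) - np.asarray(neighbor_positions), axis=1)
    return np.maximum(np.asarray(support_radii, dtype=float), 1.05 * d)


class ShapeTables:
    """Row-aligned stores of shape values and gradients per element-node pair.

    Two fixed-width tables sharing the connectivity table's row layout:
    ``values`` holds phi (one float per pair), ``gradients`` holds grad phi
    (a 3-vector per pair).
    """

    def __init__(
        self,
        n_elements: int,
        max_row_width: int,
        batch_size: int = 64,
        batched: bool = True,
        ledger: TransferLedger | None = None,
    ) -> None:
        self.values = FixedWidthTable(
            n_elements, max_row_width, dtype=np.float64,
            batch_size=batch_size, batched=batched, name="shape_values", ledger=ledger,
        )
        self.gradients = FixedWidthTable(
            n_elements, max_row_width, dtype=np.float64, item_shape=(3,),
            batch_size=batch_size, batched=batched, name="shape_gradients", ledger=ledger,
        )

    def flush(self, frame: int | None = None):
        return self.values.flush(frame), self.gradients.flush(frame)


def recompute_element_shapes(
    node_positions: np.ndarray,
    element_center: np.ndarray,
    connectivity_row: np.ndarray,
    element_index: int,
    shapes: ShapeTables,
    support_radii: np.ndarray,
) -> None:
    """Refresh one element's shape rows after its neighbor set changed.

    Evaluates MLS at the element center over the nodes of the given
    connectivity row and writes the value/gradient rows, marking them dirty
    in their stores.  On rank deficiency the error propagates and the
    stores are left untouched (evaluation happens before any write).
    """
    idx = np.asarray(connectivity_row, dtype=np.int64)
    X = node_positions[idx]
    r = effective_radii(element_center, X, support_radii[idx])
    values, gradients = mls_evaluate(element_center, X, r, index=element_index)
    if shapes.values.row_lengths.shape[0] != shapes.gradients.row_lengths.shape[0]:
        raise TableConsistencyError("shape tables disagree on row count")
    shapes.values.write_row(element_index, values)
    shapes.gradients.write_row(element_index, gradients)
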