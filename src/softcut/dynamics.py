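"""Implicit dynamic elasticity: lumped mass, matrix-free stiffness, CG, step.

The semi-discrete equation of motion ``M u'' = K u + f`` (linear
elasticity, so the elastic force is exactly ``K u``) is integrated with
backward Euler, which leads to one linear solve per time step:

    (M - dt^2 K) dv = dt (K u0 + f_ext)
    v = v0 + dv,   u = u0 + dt v

``M`` is the diagonal lumped-mass vector; ``K`` is never assembled — it
exists only as the element-loop operator :func:`apply_stiffness`, and the
system is solved by unpreconditioned conjugate gradient, whose only
per-iteration global reductions are the two scalars r.r and p.Ap.
Backward Euler is unconditionally stable for this system, so the time step
is not limited by the smallest element size — the property that makes the
scheme usable when arbitrary cutting keeps changing the discretization.

Dirichlet constraints are enforced by projection: fixed-node components of
the operator input and output (and of the right-hand side) are zeroed,
which preserves operator symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergenceError, TableConsistencyError
from .store import FixedWidthTable


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear-elastic material.

    Defaults are soft-tissue-like: E = 10 kPa, nu = 0.45 (nearly
    incompressible), rho = 1000 kg/m^3.
    """

    young_modulus: float = 1.0e4   # Pa
    poisson_ratio: float = 0.45
    density: float = 1000.0        # kg/m^3

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def lame_mu(self) -> float:
        return self.young_modulus / (2 * (1 + self.poisson_ratio))


@dataclass
class SimState:
    """Nodal displacements and velocities, with a Dirichlet mask."""

    u: np.ndarray            # (n, 3) displacement
    v: np.ndarray            # (n, 3) velocity
    fixed_mask: np.ndarray   # (n,) bool

    @classmethod
    def rest(cls, n_nodes: int, fixed_mask: np.ndarray | None = None,
             dtype=np.float64) -> "SimState":
        if fixed_mask is None:
            fixed_mask = np.zeros(n_nodes, dtype=bool)
        return cls(
            u=np.zeros((n_nodes, 3), dtype=dtype),
            v=np.zeros((n_nodes, 3), dtype=dtype),
            fixed_mask=np.asarray(fixed_mask, dtype=bool),
        )


@dataclass(frozen=True)
class StepInputs:
    """Per-step external inputs and solver settings."""

    f_ext: np.ndarray                  # (n, 3) external nodal force
    dt: float = 1.0 / 60.0             # s; frame-coupled physics at 60 FPS
    cg_tolerance: float = 1.0e-6       # relative residual
    cg_max_iterations: int | None = None  # default 10 * n_nodes

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.cg_tolerance <= 0:
            raise ValueError("cg_tolerance must be > 0")


@dataclass(frozen=True)
class CGResult:
    x: np.ndarray
    iterations: int
    converged: bool
    residual_norm: float


def _table_arrays(
    connectivity: FixedWidthTable, gradients: FixedWidthTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if connectivity.n_rows != gradients.n_rows or not np.array_equal(
        connectivity.row_lengths, gradients.row_lengths
    ):
        raise TableConsistencyError(
            "connectivity and shape-gradient tables are not row-aligned"
        )
    return connectivity.payload, gradients.payload, connectivity.row_lengths


def lumped_mass(
    element_volumes: np.ndarray,
    connectivity: FixedWidthTable,
    values: FixedWidthTable,
    material: MaterialParams,
    n_nodes: int,
) -> np.ndarray:
    """Diagonal mass vector: m_i = sum_I rho V_I phi_i^I over incident
    elements.

    Because the shape values per element sum to one, the total equals
    rho * sum(V) exactly.  MLS shape values can dip below zero near the
    boundary; to keep every diagonal entry positive (the solve needs a
    positive-definite mass), negative values are clamped to zero and each
    element's lumping weights renormalized to unit sum — mass is conserved
    element by element, and elements with nonnegative shapes are lumped by
    the plain formula.  Isolated nodes (no incident element) get a floor
    mass of 1e-12x the mean so the system stays definite.
    """
    if connectivity.n_rows != values.n_rows or not np.array_equal(
        connectivity.row_lengths, values.row_lengths
    ):
        raise TableConsistencyError(
            "connectivity and shape-value tables are not row-aligned"
        )
    conn = connectivity.payload
    # zero-filled unused slots contribute nothing (phi = 0 there)
    phi = np.maximum(values.payload, 0.0)
    row_sums = phi.sum(axis=1)
    occupied = row_sums > 0
    scale = np.zeros_like(row_sums)
    scale[occupied] = (
        material.density * element_volumes[occupied] / row_sums[occupied]
    )
    weights = (scale[:, None] * phi).ravel()
    m = np.bincount(conn.ravel().astype(np.int64), weights=weights, minlength=n_nodes)
    isolated = m <= 0.0
    if isolated.any():
        m[isolated] = 1e-12 * m[~isolated].mean() if (~isolated).any() else 1e-12
    return m


class StiffnessOperator:
    """Precompiled matrix-free K: gathers the table state once, applies often.

    The per-element pass is: strain eps = sym(sum_i grad phi_i (x) p_i),
    stress sigma = lambda tr(eps) I + 2 mu eps, then the force density is
    distributed back, f_i -= V sigma grad phi_i.  K is symmetric negative
    semi-definite; rigid translations are in its nullspace.  Fixed-node
    components are projected out on input and output.

    The flattened scatter indices and gradient block are snapshots: rebuild
    the operator after any connectivity or shape edit (the tables change at
    most once per frame, while CG applies the operator hundreds of times).
    """

    def __init__(
        self,
        element_volumes: np.ndarray,
        connectivity: FixedWidthTable,
        gradients: FixedWidthTable,
        material: MaterialParams,
        fixed_mask: np.ndarray | None = None,
    ) -> None:
        conn, grad, _ = _table_arrays(connectivity, gradients)
        self.conn = conn.astype(np.int64)
        self.flat = self.conn.ravel()
        # unused slots have grad == 0, so padding never contributes
        self.grad = np.ascontiguousarray(grad)
        self.grad_t = np.ascontiguousarray(grad.transpose(0, 2, 1))
        self.volumes = element_volumes
        self.lam = material.lame_lambda
        self.mu = material.lame_mu
        self.fixed = fixed_mask if (fixed_mask is not None and fixed_mask.any()) else None

    def __call__(self, p: np.ndarray) -> np.ndarray:
        q = np.asarray(p, dtype=float)
        n_nodes = q.shape[0]
        if self.fixed is not None:
            q = q.copy()
            q[self.fixed] = 0.0
        pg = q[self.conn]                              # (E, W, 3)
        grad_u = self.grad_t @ pg                      # (E, 3, 3): sum grad outer p
        eps = 0.5 * (grad_u + grad_u.transpose(0, 2, 1))
        tr = np.trace(eps, axis1=1, axis2=2)
        sigma = 2.0 * self.mu * eps
        lam_tr = self.lam * tr
        sigma[:, 0, 0] += lam_tr
        sigma[:, 1, 1] += lam_tr
        sigma[:, 2, 2] += lam_tr
        sigma *= self.volumes[:, None, None]
        contrib = self.grad @ sigma                    # (E, W, 3); sigma symmetric
        out = np.empty((n_nodes, 3))
        for a in range(3):
            out[:, a] = np.bincount(
                self.flat, weights=contrib[..., a].ravel(), minlength=n_nodes
            )
        np.negative(out, out=out)
        if self.fixed is not None:
            out[self.fixed] = 0.0
        return out


def apply_stiffness(
    p: np.ndarray,
    element_volumes: np.ndarray,
    connectivity: FixedWidthTable,
    gradients: FixedWidthTable,
    material: MaterialParams,
    fixed_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Matrix-free product K p, by one pass over the elements.

    Convenience wrapper building a one-shot :class:`StiffnessOperator`;
    hot loops should build the operator once per frame instead.
    """
    return StiffnessOperator(
        element_volumes, connectivity, gradients, material, fixed_mask
    )(p)


def cg_solve(
    apply_A,
    b: np.ndarray,
    tol: float = 1.0e-6,
    max_iter: int | None = None,
) -> CGResult:
    """Unpreconditioned conjugate gradient for SPD operators.

    Stops when ||r||^2 <= tol^2 ||b||^2.  Each iteration needs exactly two
    scalar reductions (r.r and p.Ap) — the pair a device-side solver would
    ship back to the host to decide whether to keep iterating.  Reaching
    ``max_iter`` yields a flagged non-converged result, not an exception;
    non-finite values raise :class:`DivergenceError`.
    """
    b = np.asarray(b, dtype=float)
    if max_iter is None:
        max_iter = 10 * b.size
    x = np.zeros_like(b)
    b_norm2 = float(np.vdot(b, b).real)
    if b_norm2 == 0.0:
        return CGResult(x=x, iterations=0, converged=True, residual_norm=0.0)
    r = b.copy()
    p = r.copy()
    rr = b_norm2
    stop2 = tol * tol * b_norm2
    for it in range(1, max_iter + 1):
        Ap = apply_A(p)
        pAp = float(np.vdot(p, Ap).real)
        if not np.isfinite(pAp) or pAp <= 0.0:
            raise DivergenceError(
                f"CG breakdown at iteration {it}: p.Ap = {pAp}"
            )
        alpha = rr / pAp
        x += alpha * p
        r -= alpha * Ap
        rr_new = float(np.vdot(r, r).real)
        if not np.isfinite(rr_new):
            raise DivergenceError(f"CG residual non-finite at iteration {it}")
        if rr_new <= stop2:
            return CGResult(x=x, iterations=it, converged=True,
                            residual_norm=float(np.sqrt(rr_new)))
        p = r + (rr_new / rr) * p
        rr = rr_new
    return CGResult(x=x, iterations=max_iter, converged=False,
                    residual_norm=float(np.sqrt(rr)))


def step(
    state: SimState,
    element_volumes: np.ndarray,
    connectivity: FixedWidthTable,
    gradients: FixedWidthTable,
    mass: np.ndarray,
    material: MaterialParams,
    inputs: StepInputs,
) -> tuple[SimState, CGResult]:
    """One backward-Euler step; returns the new state and the CG result.

    Solves ``(M - dt^2 K) dv = dt (K u0 + f_ext)`` on the free nodes, then
    updates ``v = v0 + dv`` and ``u = u0 + dt v``.  Fixed nodes keep
    u = v = 0 throughout.
    """
    dt = inputs.dt
    fixed = state.fixed_mask

    apply_K = StiffnessOperator(
        element_volumes, connectivity, gradients, material, fixed
    )
    f0 = apply_K(state.u) + inputs.f_ext
    b = dt * f0
    b[fixed] = 0.0
    m_col = mass[:, None]
    dt2 = dt * dt

    def apply_A(p: np.ndarray) -> np.ndarray:
        return m_col * p - dt2 * apply_K(p)

    max_iter = inputs.cg_max_iterations
    if max_iter is None:
        max_iter = 10 * state.u.shape[0]
    res = cg_solve(apply_A, b, tol=inputs.cg_tolerance, max_iter=max_iter)
    dv = res.x
    v = state.v + dv
    u = state.u + dt * v
    v[fixed] = 0.0
    u[fixed] = 0.0
    return SimState(u=u, v=v, fixed_mask=fixed), res


def elastic_energy(
    u: np.ndarray,
    element_volumes: np.ndarray,
    connectivity: FixedWidthTable,
    gradients: FixedWidthTable,
    material: MaterialParams,
) -> float:
    """Strain energy 1/2 u.(-K)u via the matrix-free operator."""
    Ku = apply_stiffness(u, element_volumes, connectivity, gradients, material)
    return -0.5 * float(np.sum(u * Ku))
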