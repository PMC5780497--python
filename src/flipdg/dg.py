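"""Interior-penalty discontinuous Galerkin discretization and time stepping.

The div-grad operator is discretized by the symmetric interior penalty
method on discontinuous piecewise-linear elements: on every interior
edge the bilinear form receives the consistency, symmetry and sigma/h
penalty terms

    D(u, v) = int_Omega alpha grad(u).grad(v) dx
            - int_Gint {alpha grad v}.[[u]] ds - int_Gint {alpha grad u}.[[v]] ds
            + int_Gint (sigma/h) [[u]].[[v]] ds,

while membrane edges carry *only* the semipermeable coupling
p int_GM [[u]].[[v]] ds — the interface condition J = p[[u]] replaces
continuity there.  The outer boundary is zero-flux (natural).  Time is
advanced by a fully implicit backward Euler step of the coupled
(u, u_b) system with the two step matrices (bleach on / off)
factorized once and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AssemblyError, SolverError
from .geometry import (
    CYTOPLASM,
    EDGE_INTERIOR,
    EDGE_MEMBRANE,
    EDGE_OUTER,
    NUCLEUS,
    TriMesh,
    rectangle_mesh,
)
from .model import BleachSchedule, FieldState, ModelParameters, RateMaps

#: Default Nitsche penalty: sigma = SIGMA_FACTOR * alpha * (degree + 1)^2.
SIGMA_FACTOR = 20.0

_GAUSS2 = np.array([-1.0, 1.0]) / np.sqrt(3.0)  # 2-point Gauss on [-1, 1]


@dataclass
class DGSpace:
    """Fully discontinuous piecewise-linear space on a triangle mesh.

    Each element owns three coefficients located at its vertices; no
    degree of freedom is shared between elements.
    """

    mesh: TriMesh
    degree: int = 1

    def __post_init__(self) -> None:
        if self.degree != 1:
            raise AssemblyError("only degree-1 (linear) elements are implemented")
        T = self.mesh.n_elements
        self.dofmap = np.arange(3 * T, dtype=np.int64).reshape(T, 3)
        self.n_dofs = 3 * T
        # physical location of every dof (element-local vertex copies)
        self.node_coords = self.mesh.element_coords.reshape(-1, 2)
        # constant P1 gradients per element: grad phi_i
        coords = self.mesh.element_coords  # (T, 3, 2)
        v0, v1, v2 = coords[:, 0], coords[:, 1], coords[:, 2]
        det = (v1[:, 0] - v0[:, 0]) * (v2[:, 1] - v0[:, 1]) - (v2[:, 0] - v0[:, 0]) * (
            v1[:, 1] - v0[:, 1]
        )
        g = np.empty((T, 3, 2))
        g[:, 0, 0] = v1[:, 1] - v2[:, 1]
        g[:, 0, 1] = v2[:, 0] - v1[:, 0]
        g[:, 1, 0] = v2[:, 1] - v0[:, 1]
        g[:, 1, 1] = v0[:, 0] - v2[:, 0]
        g[:, 2, 0] = v0[:, 1] - v1[:, 1]
        g[:, 2, 1] = v1[:, 0] - v0[:, 0]
        self.gradients = g / det[:, None, None]

    def element_basis_at(self, elem: int, points: np.ndarray) -> np.ndarray:
        """Values of the three local basis functions at physical points."""
        coords = self.mesh.element_coords[elem]
        A = np.vstack([coords.T, np.ones(3)])
        rhs = np.vstack([np.atleast_2d(points).T, np.ones(len(np.atleast_2d(points)))])
        return np.linalg.solve(A, rhs).T  # (n_pts, 3) barycentric = P1 values

    def interpolate(self, f) -> np.ndarray:
        """Nodal interpolation of a callable f(x, y) onto the DG space."""
        return np.asarray(f(self.node_coords[:, 0], self.node_coords[:, 1]), dtype=float)


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

_M_REF = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
# edge-midpoint quadrature: midpoint q lies opposite local vertex q
_PHI_MID = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])


def mass_matrix(space: DGSpace) -> sp.csr_matrix:
    """Block-diagonal mass matrix (exact for P1)."""
    areas = space.mesh.areas
    blocks = areas[:, None, None] * _M_REF[None, :, :]
    return _scatter_blocks(space, blocks)


def weighted_mass_matrix(space: DGSpace, weight_nodal: np.ndarray) -> sp.csr_matrix:
    """Mass matrix weighted by a nodal field, by edge-midpoint quadrature.

    The 3-midpoint rule is exact for quadratic integrands and — being a
    pointwise rule — preserves nodewise identities between weighted
    integrals (used for the exact reaction equilibrium at t = 0).
    """
    w = np.asarray(weight_nodal, dtype=float)[space.dofmap]  # (T, 3)
    w_mid = w @ _PHI_MID.T  # weight at the three midpoints
    areas = space.mesh.areas
    blocks = np.einsum(
        "tq,qi,qj->tij", w_mid, _PHI_MID, _PHI_MID
    ) * (areas[:, None, None] / 3.0)
    return _scatter_blocks(space, blocks)


def bleach_matrix(space: DGSpace) -> sp.csr_matrix:
    """Unit-rate mass matrix restricted to bleach-flagged elements."""
    areas = np.where(space.mesh.element_bleach, space.mesh.areas, 0.0)
    blocks = areas[:, None, None] * _M_REF[None, :, :]
    return _scatter_blocks(space, blocks)


def _scatter_blocks(space: DGSpace, blocks: np.ndarray) -> sp.csr_matrix:
    T = space.mesh.n_elements
    rows = np.repeat(space.dofmap, 3, axis=1).ravel()
    cols = np.tile(space.dofmap, (1, 3)).ravel()
    return sp.csr_matrix(
        (blocks.ravel(), (rows, cols)), shape=(space.n_dofs, space.n_dofs)
    )


def _edge_geometry(mesh: TriMesh, e: int):
    """Endpoints, length, unit normal pointing out of the first element."""
    a, b = mesh.edges[e]
    pa, pb = mesh.vertices[a], mesh.vertices[b]
    tangent = pb - pa
    length = float(np.linalg.norm(tangent))
    n = np.array([tangent[1], -tangent[0]]) / length
    k1 = mesh.edge_tris[e, 0]
    if np.dot(n, mesh.centroids[k1] - 0.5 * (pa + pb)) > 0:
        n = -n
    return pa, pb, length, n


def _edge_quadrature(pa, pb):
    mid = 0.5 * (pa + pb)
    half = 0.5 * (pb - pa)
    return np.array([mid + t * half for t in _GAUSS2])  # weights L/2 each


def stiffness_matrix(
    space: DGSpace,
    alpha: float,
    sigma: float,
    dirichlet=None,
):
    """SIPG stiffness matrix D (and load vector if Dirichlet data given).

    Interior edges get consistency + symmetry + (sigma/h) penalty terms;
    membrane edges get nothing here (see :func:`membrane_matrix`); outer
    edges are natural (zero flux) unless ``dirichlet`` is a callable
    ``g(x, y)`` returning boundary values (weak Nitsche enforcement) or
    None per edge midpoint to keep that edge natural.
    """
    if sigma <= 0:
        raise AssemblyError("Nitsche parameter sigma must be positive")
    mesh = space.mesh
    grads = space.gradients
    areas = mesh.areas
    diam = mesh.diameters

    rows, cols, vals = [], [], []
    rhs = np.zeros(space.n_dofs)

    # volume terms
    vol_blocks = alpha * areas[:, None, None] * np.einsum(
        "tik,tjk->tij", grads, grads
    )
    rows.append(np.repeat(space.dofmap, 3, axis=1).ravel())
    cols.append(np.tile(space.dofmap, (1, 3)).ravel())
    vals.append(vol_blocks.ravel())

    for e in range(len(mesh.edges)):
        cls = mesh.edge_class[e]
        if cls == EDGE_MEMBRANE:
            continue
        pa, pb, length, n = _edge_geometry(mesh, e)
        qpts = _edge_quadrature(pa, pb)
        wq = length / 2.0
        k1, k2 = mesh.edge_tris[e]
        if cls == EDGE_INTERIOR:
            h_e = 0.5 * (diam[k1] + diam[k2])
            phi1 = space.element_basis_at(k1, qpts)  # (2, 3)
            phi2 = space.element_basis_at(k2, qpts)
            dofs = np.concatenate([space.dofmap[k1], space.dofmap[k2]])
            gn = np.concatenate([grads[k1] @ n, grads[k2] @ n])  # (6,)
            avg_gn = 0.5 * alpha * gn
            local = np.zeros((6, 6))
            for q in range(2):
                J = np.concatenate([phi1[q], -phi2[q]])  # [[phi]] . n factor
                local += wq * (sigma / h_e) * np.outer(J, J)
                local -= wq * (np.outer(J, avg_gn) + np.outer(avg_gn, J))
            rows.append(np.repeat(dofs, 6))
            cols.append(np.tile(dofs, 6))
            vals.append(local.ravel())
        elif cls == EDGE_OUTER and dirichlet is not None:
            mid = 0.5 * (pa + pb)
            g = dirichlet(mid[0], mid[1])
            if g is None:
                continue
            h_e = diam[k1]
            phi1 = space.element_basis_at(k1, qpts)
            dofs = space.dofmap[k1]
            gn = alpha * (grads[k1] @ n)
            local = np.zeros((3, 3))
            rloc = np.zeros(3)
            gvals = np.asarray(g(qpts[:, 0], qpts[:, 1])) if callable(g) else np.full(2, g)
            for q in range(2):
                v = phi1[q]
                local += wq * ((sigma / h_e) * np.outer(v, v) - np.outer(v, gn) - np.outer(gn, v))
                rloc += wq * gvals[q] * ((sigma / h_e) * v - gn)
            rows.append(np.repeat(dofs, 3))
            cols.append(np.tile(dofs, 3))
            vals.append(local.ravel())
            rhs[dofs] += rloc

    D = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(space.n_dofs, space.n_dofs),
    )
    if dirichlet is None:
        return D
    return D, rhs


def membrane_matrix(space: DGSpace) -> sp.csr_matrix:
    """Unit-permeability membrane coupling int_GM [[u]].[[v]] ds."""
    mesh = space.mesh
    rows, cols, vals = [], [], []
    for e in np.nonzero(mesh.edge_class == EDGE_MEMBRANE)[0]:
        pa, pb, length, _ = _edge_geometry(mesh, e)
        qpts = _edge_quadrature(pa, pb)
        wq = length / 2.0
        k1, k2 = mesh.edge_tris[e]
        phi1 = space.element_basis_at(k1, qpts)
        phi2 = space.element_basis_at(k2, qpts)
        dofs = np.concatenate([space.dofmap[k1], space.dofmap[k2]])
        local = np.zeros((6, 6))
        for q in range(2):
            J = np.concatenate([phi1[q], -phi2[q]])
            local += wq * np.outer(J, J)
        rows.append(np.repeat(dofs, 6))
        cols.append(np.tile(dofs, 6))
        vals.append(local.ravel())
    if not vals:
        return sp.csr_matrix((space.n_dofs, space.n_dofs))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(space.n_dofs, space.n_dofs),
    )


def jump_identity_check(q_plus, q_minus, u_plus, u_minus, n_plus) -> float:
    """Residual of the product rule [[qu]] = [[q]]{u} + {q}.[[u]].

    ``q_plus``/``q_minus`` are one-sided vector values, ``u_plus``/
    ``u_minus`` one-sided scalars and ``n_plus`` the unit normal of the
    plus side (the minus normal is its negative).  Returns a scalar
    residual, zero up to round-off.
    """
    qp, qm = np.asarray(q_plus, float), np.asarray(q_minus, float)
    n = np.asarray(n_plus, float)
    jump_qu = np.dot(qp, n) * u_plus + np.dot(qm, -n) * u_minus
    jump_q = np.dot(qp, n) + np.dot(qm, -n)
    avg_u = 0.5 * (u_plus + u_minus)
    avg_q = 0.5 * (qp + qm)
    jump_u = u_plus * n + u_minus * (-n)
    return float(jump_qu - (jump_q * avg_u + np.dot(avg_q, jump_u)))


# ---------------------------------------------------------------------------
# Assembled system and time stepping
# ---------------------------------------------------------------------------

@dataclass
class AssembledSystem:
    """Pre-assembled matrices of the coupled two-species system."""

    space: DGSpace
    params: ModelParameters
    M: sp.csr_matrix
    D: sp.csr_matrix
    P_unit: sp.csr_matrix
    Kp: sp.csr_matrix
    Km: sp.csr_matrix
    B_unit: sp.csr_matrix
    sigma: float
    h_edge: np.ndarray
    _lu_cache: dict = field(default_factory=dict, repr=False)

    @property
    def P(self) -> sp.csr_matrix:
        """Membrane coupling scaled by the permeability p."""
        return self.params.p * self.P_unit

    @property
    def B(self) -> sp.csr_matrix:
        """Bleach sink scaled by the effective bleach rate beta."""
        return self.params.beta * self.B_unit

    def step_operator(self, dt: float, bleaching: bool):
        key = (round(float(dt), 12), bool(bleaching))
        if key not in self._lu_cache:
            A11 = self.M / dt + self.D + self.P + self.Kp
            A22 = self.M / dt + self.Km
            if bleaching:
                A11 = A11 + self.B
                A22 = A22 + self.B
            A = sp.bmat([[A11, -self.Km], [-self.Kp, A22]], format="csc")
            try:
                self._lu_cache[key] = spla.splu(A)
            except RuntimeError as exc:  # pragma: no cover - defensive
                raise SolverError(f"step matrix factorization failed: {exc}") from exc
        return self._lu_cache[key]

    def total_mass(self, state: FieldState) -> float:
        return float(np.ones(self.space.n_dofs) @ (self.M @ state.c))

    def region_mass(self, state: FieldState, region: int) -> float:
        mask = np.zeros(self.space.n_dofs)
        sel = self.space.dofmap[self.space.mesh.element_region == region].ravel()
        mask[sel] = 1.0
        return float(mask @ (self.M @ state.c))

    def l2_norm(self, coeffs: np.ndarray) -> float:
        return float(np.sqrt(np.abs(coeffs @ (self.M @ coeffs))))


def default_sigma(alpha: float, degree: int = 1) -> float:
    return SIGMA_FACTOR * alpha * (degree + 1) ** 2


@lru_cache(maxsize=8)
def _coercivity_ok(sigma_over_alpha: float) -> bool:
    """Probe coercivity of the SIPG form on a small structured mesh."""
    probe = DGSpace(rectangle_mesh(4, 4))
    D = stiffness_matrix(probe, alpha=1.0, sigma=sigma_over_alpha)
    lam = np.linalg.eigvalsh(D.toarray())
    return bool(lam.min() >= -1e-10)


def assemble(
    space: DGSpace,
    params: ModelParameters,
    rates: RateMaps | None,
    sigma: float | None = None,
    check_coercivity: bool = True,
) -> AssembledSystem:
    """Assemble all matrices of the semi-discrete FLIP system.

    ``rates=None`` disables the reaction coupling (pure diffusion runs,
    used for verification).  ``sigma`` defaults to
    ``20 * alpha * (degree + 1)**2``; coercivity of the resulting form
    is verified on a coarse probe mesh unless disabled.
    """
    if sigma is None:
        sigma = default_sigma(params.alpha, space.degree)
    if sigma <= 0:
        raise AssemblyError("sigma must be positive")
    if check_coercivity and not _coercivity_ok(round(sigma / params.alpha, 9)):
        raise AssemblyError(
            f"sigma = {sigma} fails the coercivity probe; increase the Nitsche parameter"
        )
    mesh = space.mesh
    M = mass_matrix(space)
    D = stiffness_matrix(space, alpha=params.alpha, sigma=sigma)
    P_unit = membrane_matrix(space)
    if rates is None:
        n = space.n_dofs
        Kp = sp.csr_matrix((n, n))
        Km = sp.csr_matrix((n, n))
    else:
        Kp = weighted_mass_matrix(space, rates.k_plus)
        Km = rates.k_minus * M
    B_unit = bleach_matrix(space)
    diam = mesh.diameters
    tris = mesh.edge_tris
    h_edge = np.where(
        tris[:, 1] >= 0, 0.5 * (diam[tris[:, 0]] + diam[np.maximum(tris[:, 1], 0)]),
        diam[tris[:, 0]],
    )
    return AssembledSystem(
        space=space, params=params, M=M, D=D, P_unit=P_unit,
        Kp=Kp, Km=Km, B_unit=B_unit, sigma=sigma, h_edge=h_edge,
    )


def step_backward_euler(
    state: FieldState,
    system: AssembledSystem,
    dt: float,
    bleaching: bool,
    source=None,
) -> FieldState:
    """One fully implicit backward Euler step of the coupled system.

    ``source`` is an optional callable ``f(x, y, t_new)`` adding a
    volume source to the u equation (manufactured-solution harness).
    """
    if dt <= 0:
        raise SolverError("dt must be positive")
    lu = system.step_operator(dt, bleaching)
    t_new = state.t + dt
    rhs_u = system.M @ (state.u / dt)
    if source is not None:
        xy = system.space.node_coords
        rhs_u = rhs_u + system.M @ np.asarray(source(xy[:, 0], xy[:, 1], t_new), float)
    rhs = np.concatenate([rhs_u, system.M @ (state.u_b / dt)])
    sol = lu.solve(rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("linear solve produced non-finite values (singular system?)")
    n = system.space.n_dofs
    return FieldState(u=sol[:n], u_b=sol[n:], t=t_new)


@dataclass
class FlipTrajectory:
    """Snapshots at the frame times t_i plus the per-step mass series."""

    snapshots: list[FieldState]
    times: np.ndarray
    mass: np.ndarray  # columns: t, total, nucleus, cytoplasm

    MASS_COLUMNS = ("t", "total", "nucleus", "cytoplasm")

    def mass_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.mass, columns=list(self.MASS_COLUMNS))


def run_flip(
    state: FieldState,
    system: AssembledSystem,
    schedule: BleachSchedule,
    bleaching_enabled: bool = True,
) -> FlipTrajectory:
    """Advance the FLIP protocol and record snapshots at t_i.

    Each frame consists of ``schedule.m`` bleaching steps followed by
    recovery steps; the snapshot is taken ``schedule.t_offset`` into the
    frame (on the step grid).
    """
    dt = schedule.dt
    snapshots: list[FieldState] = []
    mass_rows = [[state.t,
                  system.total_mass(state),
                  system.region_mass(state, NUCLEUS),
                  system.region_mass(state, CYTOPLASM)]]
    current = state
    step_count = 0
    for _ in range(schedule.n_frames):
        for k in range(schedule.steps_per_frame):
            bleaching = bleaching_enabled and (k < schedule.m)
            current = step_backward_euler(current, system, dt, bleaching)
            step_count += 1
            current.t = step_count * dt  # avoid accumulation drift
            mass_rows.append([current.t,
                              system.total_mass(current),
                              system.region_mass(current, NUCLEUS),
                              system.region_mass(current, CYTOPLASM)])
            if k + 1 == schedule.snapshot_step:
                snapshots.append(current.copy())
    return FlipTrajectory(
        snapshots=snapshots,
        times=schedule.snapshot_times.copy(),
        mass=np.asarray(mass_rows),
    )
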