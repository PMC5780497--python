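"""IPDG assembly, membrane coupling and backward-Euler stepping.

The two-triangle hand-assembly oracle integrates the bilinear form
symbolically with sympy, entirely independent of the assembly code
(symbolic plane basis functions, parameterized edge integrals).
"""

import numpy as np
import pytest
import sympy as sym
from hypothesis import given, settings
from hypothesis import strategies as st

from flipdg.dg import (
    DGSpace,
    assemble,
    jump_identity_check,
    membrane_matrix,
    run_flip,
    step_backward_euler,
    stiffness_matrix,
)
from flipdg.errors import AssemblyError
from flipdg.geometry import NUCLEUS, TriMesh, rectangle_mesh
from flipdg.model import (
    BleachSchedule,
    FieldState,
    ModelParameters,
    RateMaps,
    build_rate_maps,
    init_fields_from_frame,
)

ALPHA, SIGMA = 2.1, 7.3


def _sym_basis(vertices):
    """Symbolic plane functions with phi_i(v_j) = delta_ij."""
    x, y = sym.symbols("x y")
    basis = []
    for i in range(3):
        a, b, c = sym.symbols(f"a{i} b{i} c{i}")
        f = a * x + b * y + c
        eqs = [
            sym.Eq(f.subs({x: vx, y: vy}), 1 if j == i else 0)
            for j, (vx, vy) in enumerate(vertices)
        ]
        sol = sym.solve(eqs, [a, b, c])
        basis.append(sym.expand(f.subs(sol)))
    return basis, (x, y)


def _hand_assembled_two_triangle_forms(mesh, alpha, sigma):
    """6x6 SIPG stiffness and unit membrane matrices by symbolic integration."""
    x, y = sym.symbols("x y")
    tri_verts = [
        [tuple(sym.Rational(int(v * 2), 2) for v in mesh.vertices[k])
         for k in mesh.triangles[t]]
        for t in range(2)
    ]
    bases = [_sym_basis(v)[0] for v in tri_verts]
    al, sg = sym.Rational(21, 10), sym.Rational(73, 10)

    D = sym.zeros(6, 6)
    # volume: alpha * grad phi_i . grad phi_j over each triangle
    for t in range(2):
        (x0, y0), (x1, y1), (x2, y2) = tri_verts[t]
        area = sym.Rational(1, 2) * sym.Abs(
            (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        )
        for i in range(3):
            for j in range(3):
                gi = sym.Matrix([sym.diff(bases[t][i], x), sym.diff(bases[t][i], y)])
                gj = sym.Matrix([sym.diff(bases[t][j], x), sym.diff(bases[t][j], y)])
                D[3 * t + i, 3 * t + j] += al * area * (gi.T * gj)[0]

    # shared diagonal from (0,0) to (1,1); triangle 0 lies below it
    t_par = sym.symbols("t", nonnegative=True)
    ds = sym.sqrt(2)
    n1 = sym.Matrix([-1, 1]) / sym.sqrt(2)  # outward from triangle 0
    h_edge = sym.sqrt(2)  # both diameters are sqrt(2)

    def edge_val(expr):
        return expr.subs({x: t_par, y: t_par})

    P = sym.zeros(6, 6)
    traces, grads_n = [], []
    for t in range(2):
        for i in range(3):
            traces.append(edge_val(bases[t][i]))
            g = sym.Matrix([sym.diff(bases[t][i], x), sym.diff(bases[t][i], y)])
            grads_n.append((g.T * n1)[0])
    side = [1, 1, 1, -1, -1, -1]  # sign of the scalar jump (u1 - u2)

    for i in range(6):
        for j in range(6):
            jump_i = side[i] * traces[i]
            jump_j = side[j] * traces[j]
            avg_i = sym.Rational(1, 2) * grads_n[i]
            avg_j = sym.Rational(1, 2) * grads_n[j]
            penalty = (sg / h_edge) * jump_i * jump_j
            consistency = -al * (avg_j * jump_i + avg_i * jump_j)
            D[i, j] += sym.integrate((penalty + consistency) * ds, (t_par, 0, 1))
            P[i, j] = sym.integrate(jump_i * jump_j * ds, (t_par, 0, 1))
    return (
        np.array(D.evalf(), dtype=float),
        np.array(P.evalf(), dtype=float),
    )


class TestAssemblyOracle:
    def test_two_triangle_hand_assembly(self):
        """Assembled SIPG matrix matches the symbolic oracle entrywise."""
        mesh = rectangle_mesh(1, 1)
        space = DGSpace(mesh)
        D = stiffness_matrix(space, alpha=ALPHA, sigma=SIGMA).toarray()
        D_hand, _ = _hand_assembled_two_triangle_forms(mesh, ALPHA, SIGMA)
        assert np.max(np.abs(D - D_hand)) < 1e-12

    def test_two_triangle_membrane_oracle(self):
        base = rectangle_mesh(1, 1)
        region = base.element_region.copy()
        region[0] = NUCLEUS
        mesh = TriMesh(base.vertices, base.triangles, region, base.element_bleach)
        P = membrane_matrix(DGSpace(mesh)).toarray()
        _, P_hand = _hand_assembled_two_triangle_forms(mesh, ALPHA, SIGMA)
        assert np.max(np.abs(P - P_hand)) < 1e-12


@pytest.fixture(scope="module")
def system(coarse_mesh, two_level_c0):
    space = DGSpace(coarse_mesh)
    params = ModelParameters(16.1, 35.6, 0.319, 0.111)
    rates = build_rate_maps(two_level_c0, params.gamma)
    return assemble(space, params, rates)


class TestAssembledMatrices:
    def test_constant_in_kernel(self, system):
        ones = np.ones(system.space.n_dofs)
        assert np.abs(system.D @ ones).max() < 1e-10
        assert np.abs(system.P_unit @ ones).max() < 1e-12

    def test_symmetry(self, system):
        assert abs(system.D - system.D.T).max() < 1e-12
        assert abs(system.P_unit - system.P_unit.T).max() < 1e-14
        assert abs(system.M - system.M.T).max() == 0.0

    def test_mass_spd_and_membrane_psd(self, system, rng):
        for _ in range(5):
            v = rng.standard_normal(system.space.n_dofs)
            assert v @ (system.M @ v) > 0
            assert v @ (system.P_unit @ v) >= -1e-12

    def test_membrane_zero_on_continuous_fields(self, system):
        """P annihilates any globally continuous nodal field."""
        mesh = system.space.mesh
        f = mesh.vertices[:, 0] + 2.0 * mesh.vertices[:, 1]
        coeffs = f[mesh.triangles].ravel()  # continuous interpolant
        assert np.abs(system.P_unit @ coeffs).max() < 1e-12

    def test_penalty_energy_zero_on_continuous(self, system):
        """(sigma/h) jump energy vanishes for continuous interpolants and
        is positive for genuinely discontinuous coefficient vectors."""
        mesh = system.space.mesh
        # alpha ~ 0 removes volume+consistency terms, leaving the penalty
        D_pen = stiffness_matrix(system.space, alpha=1e-300, sigma=1.0)
        f = np.sin(mesh.vertices[:, 0]) * mesh.vertices[:, 1]
        continuous = f[mesh.triangles].ravel()
        assert continuous @ (D_pen @ continuous) < 1e-10
        jumpy = np.repeat(np.arange(mesh.n_elements, dtype=float), 3)
        assert jumpy @ (D_pen @ jumpy) > 1.0

    def test_bleach_matrix_support(self, system):
        B = system.B_unit
        outside = ~np.repeat(system.space.mesh.element_bleach, 3)
        assert abs(B[outside][:, outside]).max() == 0.0
        assert B[~outside][:, ~outside].sum() > 0

    def test_nonpositive_sigma_rejected(self, system):
        with pytest.raises(AssemblyError):
            stiffness_matrix(system.space, alpha=1.0, sigma=-1.0)


class TestJumpIdentity:
    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_product_rule_residual_vanishes(self, data):
        """[[qu]] = [[q]]{u} + {q}.[[u]] for random one-sided values."""
        vals = data.draw(
            st.lists(st.floats(-10, 10, allow_nan=False), min_size=6, max_size=6)
        )
        angle = data.draw(st.floats(0, 2 * np.pi))
        n = np.array([np.cos(angle), np.sin(angle)])
        res = jump_identity_check(vals[0:2], vals[2:4], vals[4], vals[5], n)
        assert abs(res) < 1e-12

    def test_continuous_field_no_jump(self):
        q = np.array([1.3, -0.4])
        assert jump_identity_check(q, q, 2.0, 2.0, np.array([1.0, 0.0])) == 0.0


class TestTimeStepping:
    def test_scalar_bleach_decay(self):
        """alpha-free uniform field on an all-bleach mesh: u <- u/(1+beta*dt)."""
        mesh = rectangle_mesh(2, 2)
        mesh.element_bleach[:] = True
        space = DGSpace(mesh)
        params = ModelParameters(alpha=1.0, beta=3.0, gamma=0.0, p=0.0)
        system = assemble(space, params, rates=None, check_coercivity=False)
        state = FieldState(np.ones(space.n_dofs), 0.5 * np.ones(space.n_dofs))
        dt = 0.1
        new = step_backward_euler(state, system, dt, bleaching=True)
        assert np.allclose(new.u, 1.0 / (1.0 + 3.0 * dt), rtol=1e-12)
        assert np.allclose(new.u_b, 0.5 / (1.0 + 3.0 * dt), rtol=1e-12)

    def test_reaction_matches_two_by_two_recurrence(self):
        """Uniform fields follow the exact per-node backward-Euler recurrence
        of the 2x2 reaction ODE (independent dense linear-algebra oracle)."""
        mesh = rectangle_mesh(2, 2)
        space = DGSpace(mesh)
        kp, km = 0.3, 0.1
        params = ModelParameters(alpha=1.0, beta=0.0, gamma=1.0, p=0.0)
        rates = RateMaps(k_plus=np.full(space.n_dofs, kp), k_minus=km)
        system = assemble(space, params, rates, check_coercivity=False)
        dt, n_steps = 0.05, 400
        state = FieldState(0.8 * np.ones(space.n_dofs), 0.1 * np.ones(space.n_dofs))
        xs = np.array([0.8, 0.1])
        A = np.array([[kp, -km], [-kp, km]])
        step_mat = np.linalg.inv(np.eye(2) + dt * A)
        for _ in range(n_steps):
            state = step_backward_euler(state, system, dt, bleaching=False)
            xs = step_mat @ xs
        assert np.allclose(state.u, xs[0], rtol=1e-10)
        assert np.allclose(state.u_b, xs[1], rtol=1e-10)
        # and the recurrence itself approaches the analytic equilibrium
        eq = (0.9) * np.array([km, kp]) / (kp + km)
        assert np.allclose(xs, eq, atol=5e-3)

    def test_mass_conserved_without_bleaching(self, coarse_mesh, two_level_c0):
        space = DGSpace(coarse_mesh)
        params = ModelParameters(16.1, 35.6, 0.319, 0.111)
        rates = build_rate_maps(two_level_c0, params.gamma)
        system = assemble(space, params, rates)
        state = init_fields_from_frame(two_level_c0)
        m0 = system.total_mass(state)
        for _ in range(120):
            state = step_backward_euler(state, system, 0.2, bleaching=False)
        assert abs(system.total_mass(state) - m0) / m0 < 1e-10

    def test_sealed_membrane_conserves_nuclear_mass(self, coarse_mesh, two_level_c0):
        space = DGSpace(coarse_mesh)
        params = ModelParameters(16.1, 35.6, 0.319, p=0.0)
        rates = build_rate_maps(two_level_c0, params.gamma)
        system = assemble(space, params, rates)
        state = init_fields_from_frame(two_level_c0)
        m0 = system.region_mass(state, NUCLEUS)
        for _ in range(60):
            state = step_backward_euler(state, system, 0.2, bleaching=False)
        assert abs(system.region_mass(state, NUCLEUS) - m0) / m0 < 1e-10

    def test_continuity_limit_large_permeability(self, coarse_mesh):
        """Membrane jump energy decreases monotonically to ~0 as p grows."""
        space = DGSpace(coarse_mesh)
        region = np.repeat(coarse_mesh.element_region, 3)
        u0 = np.where(region == NUCLEUS, 1.0, 0.2).astype(float)
        energies = []
        for p in (1.0, 10.0, 100.0, 1000.0):
            params = ModelParameters(alpha=16.1, beta=0.0, gamma=0.0, p=p)
            system = assemble(space, params, rates=None)
            state = FieldState(u0.copy(), np.zeros(space.n_dofs))
            for _ in range(10):
                state = step_backward_euler(state, system, 0.2, bleaching=False)
            energies.append(state.u @ (system.P_unit @ state.u))
        assert np.all(np.diff(energies) < 0)
        assert energies[-1] < 1e-3 * energies[0]


class TestRunFlip:
    def test_frame_structure_of_protocol(self, schedule):
        assert schedule.m == 4
        assert schedule.steps_per_frame - schedule.m == 9
        assert schedule.snapshot_step == 10

    def test_steady_state_without_laser(self, coarse_mesh, two_level_c0):
        """theta = 0 keeps every snapshot at the initial equilibrium."""
        space = DGSpace(coarse_mesh)
        params = ModelParameters(16.1, 35.6, 0.319, 0.111)
        rates = build_rate_maps(two_level_c0, params.gamma)
        system = assemble(space, params, rates)
        state = init_fields_from_frame(two_level_c0)
        traj = run_flip(state, system, BleachSchedule(n_frames=5),
                        bleaching_enabled=False)
        ref = system.l2_norm(state.c)
        for snap in traj.snapshots:
            assert system.l2_norm(snap.c - state.c) / ref < 1e-10

    def test_bleaching_mass_non_increasing(self, coarse_mesh, two_level_c0):
        space = DGSpace(coarse_mesh)
        params = ModelParameters(16.1, 35.6, 0.319, 0.111)
        rates = build_rate_maps(two_level_c0, params.gamma)
        system = assemble(space, params, rates)
        state = init_fields_from_frame(two_level_c0)
        traj = run_flip(state, system, BleachSchedule(n_frames=5))
        total = traj.mass[:, 1]
        assert np.all(np.diff(total) <= 1e-12)
        assert total[-1] < total[0]
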