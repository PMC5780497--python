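"""Verification harness: manufactured solutions and analytic benchmarks.

Three independent checks of the discretization:

* manufactured smooth solution u = exp(-t) cos(pi x) cos(pi y) on the
  unit square (zero-flux boundary) with matching volume source, giving
  the expected L2 orders — 2 in mesh size for linear elements, 1 in dt
  for backward Euler;
* a two-slab steady diffusion problem whose exact solution is piecewise
  linear with the concentration jump J/p across the membrane — linear
  elements reproduce it to solver tolerance at any resolution;
* the well-mixed (large alpha) limit in which the compartment-mean
  difference decays exponentially at the two-compartment ODE rate
  p * |Gamma_M| * (1/|Omega_N| + 1/|Omega_C|).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse.linalg as spla

from .dg import (
    DGSpace,
    assemble,
    default_sigma,
    membrane_matrix,
    run_flip,
    step_backward_euler,
    stiffness_matrix,
)
from .geometry import NUCLEUS, TriMesh, rectangle_mesh, region_measures
from .model import BleachSchedule, FieldState, ModelParameters


def _run_heat(space: DGSpace, alpha: float, u0, source, t_end: float, dt: float) -> np.ndarray:
    """Advance the pure-diffusion u equation (u_b inert) to t_end."""
    params = ModelParameters(alpha=alpha, beta=0.0, gamma=0.0, p=0.0)
    system = assemble(space, params, rates=None, check_coercivity=False)
    state = FieldState(u=space.interpolate(u0), u_b=np.zeros(space.n_dofs))
    n_steps = int(round(t_end / dt))
    for k in range(n_steps):
        state = step_backward_euler(state, system, dt, bleaching=False, source=source)
        state.t = (k + 1) * dt
    return state.u


def manufactured_spatial_order(
    alpha: float = 1.0,
    resolutions=(8, 16, 32),
    t_end: float = 0.2,
) -> tuple[float, np.ndarray]:
    """Observed spatial L2 order for the manufactured cosine solution.

    The time step is refined as h^2 so the first-order temporal error
    does not pollute the second-order spatial slope.  Returns the fitted
    slope and the error sequence.
    """
    c = 2.0 * alpha * np.pi**2 - 1.0

    def exact(x, y, t):
        return np.exp(-t) * np.cos(np.pi * x) * np.cos(np.pi * y)

    def source(x, y, t):
        return c * exact(x, y, t)

    errors, hs = [], []
    for n in resolutions:
        space = DGSpace(rectangle_mesh(n, n))
        dt = t_end / 4.0 * (resolutions[0] / n) ** 2
        u = _run_heat(space, alpha, lambda x, y: exact(x, y, 0.0), source, t_end, dt)
        diff = u - space.interpolate(lambda x, y: exact(x, y, t_end))
        from .dg import mass_matrix

        M = mass_matrix(space)
        errors.append(float(np.sqrt(diff @ (M @ diff))))
        hs.append(1.0 / n)
    slope = np.polyfit(np.log(hs), np.log(errors), 1)[0]
    return float(slope), np.asarray(errors)


def manufactured_temporal_order(
    alpha: float = 1.0,
    n: int = 8,
    t_end: float = 0.2,
    dts=(0.02, 0.01, 0.005),
) -> tuple[float, np.ndarray]:
    """Observed temporal order by Richardson differences on a fixed mesh.

    Successive-solution differences cancel the fixed spatial error, so
    the slope isolates the backward Euler O(dt) contribution.
    """
    c = 2.0 * alpha * np.pi**2 - 1.0

    def exact(x, y, t):
        return np.exp(-t) * np.cos(np.pi * x) * np.cos(np.pi * y)

    def source(x, y, t):
        return c * exact(x, y, t)

    space = DGSpace(rectangle_mesh(n, n))
    from .dg import mass_matrix

    M = mass_matrix(space)
    sols = [
        _run_heat(space, alpha, lambda x, y: exact(x, y, 0.0), source, t_end, dt)
        for dt in list(dts) + [dts[-1] / 2.0]
    ]
    diffs = np.array(
        [np.sqrt((a - b) @ (M @ (a - b))) for a, b in zip(sols[:-1], sols[1:])]
    )
    slope = np.polyfit(np.log(dts), np.log(diffs), 1)[0]
    return float(slope), diffs


def two_slab_error(
    nx: int = 8,
    ny: int = 4,
    alpha: float = 2.0,
    p: float = 0.5,
    interface_x: float = 0.5,
) -> float:
    """Max nodal error of the steady two-slab membrane problem.

    Unit square, membrane on the vertical line x = interface_x, Dirichlet
    u(0, y) = 1 and u(1, y) = 0 (weak Nitsche), zero flux top/bottom.
    The exact solution has constant flux J = alpha*s and concentration
    jump J/p at the membrane:

        u(x) = 1 - s*x  (left),   u(x) = s*(1 - x)  (right),
        s = 1 / (1 + alpha/p)  for interface_x = 0.5 geometry with
        general split handled below.

    Piecewise-linear, hence representable exactly by the DG space; the
    discrete solution matches to linear-solver tolerance.
    """
    mesh = rectangle_mesh(nx, ny, interface_x=interface_x)
    space = DGSpace(mesh)
    sigma = default_sigma(alpha)

    def dirichlet(x, y):
        if np.isclose(x, 0.0):
            return 1.0
        if np.isclose(x, 1.0):
            return 0.0
        return None  # natural (zero flux) on horizontal boundaries

    D, rhs = stiffness_matrix(space, alpha=alpha, sigma=sigma, dirichlet=dirichlet)
    A = (D + p * membrane_matrix(space)).tocsc()
    u = spla.spsolve(A, rhs)

    # exact: slope s both sides, total drop 1 = s*1 + jump = s + alpha*s/p
    s = 1.0 / (1.0 + alpha / p)
    x = space.node_coords[:, 0]
    region = np.repeat(mesh.element_region, 3)
    u_exact = np.where(region == NUCLEUS, 1.0 - s * x, s * (1.0 - x))
    return float(np.max(np.abs(u - u_exact)))


def well_mixed_decay_rate(
    mesh: TriMesh,
    p: float = 0.1,
    alpha: float = 1e3,
    dt: float = 0.05,
    t_end: float = 20.0,
) -> tuple[float, float]:
    """Fitted and analytic decay rates of the compartment-mean difference.

    With very fast diffusion, no bleaching and no reaction, each
    compartment is well mixed and exchange across the membrane follows
    the two-compartment ODE whose contrast decays at rate
    p * |Gamma_M| * (1/|Omega_N| + 1/|Omega_C|).
    """
    space = DGSpace(mesh)
    params = ModelParameters(alpha=alpha, beta=0.0, gamma=0.0, p=p)
    system = assemble(space, params, rates=None, check_coercivity=False)
    region = np.repeat(mesh.element_region, 3)
    u0 = np.where(region == NUCLEUS, 1.0, 0.2)
    state = FieldState(u=u0.astype(float), u_b=np.zeros(space.n_dofs))

    meas = region_measures(mesh)
    area_n, area_c = meas["nucleus_area"], meas["cytoplasm_area"]
    rate_exact = p * meas["membrane_length"] * (1.0 / area_n + 1.0 / area_c)

    times, contrast = [], []
    n_steps = int(round(t_end / dt))
    for k in range(n_steps):
        state = step_backward_euler(state, system, dt, bleaching=False)
        mean_n = system.region_mass(state, NUCLEUS) / area_n
        mean_c = system.region_mass(state, 1) / area_c
        times.append((k + 1) * dt)
        contrast.append(mean_n - mean_c)
    times, contrast = np.asarray(times), np.asarray(contrast)
    keep = contrast > 1e-12 * contrast[0]
    rate_fit = -np.polyfit(times[keep], np.log(contrast[keep]), 1)[0]
    return float(rate_fit), float(rate_exact)


def verify_convergence(resolutions=(8, 16, 32), alpha: float = 1.0) -> dict[str, float]:
    """Observed spatial and temporal orders plus the two-slab error."""
    spatial, _ = manufactured_spatial_order(alpha=alpha, resolutions=resolutions)
    temporal, _ = manufactured_temporal_order(alpha=alpha)
    return {
        "spatial_order": spatial,
        "temporal_order": temporal,
        "two_slab_max_error": two_slab_error(),
    }
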