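"""Misfit functional and Nelder-Mead parameter estimation.

The misfit is the frame-averaged squared L2 distance between the
simulated total intensity and the goal functions,

    E = sum_i w_i int_Omega |u(t_i) + u_b(t_i) - c_g(t_i)|^2 dx,

with uniform weights 1/N by default.  The four parameters
(alpha, beta, gamma, p) are estimated by the Nelder-Mead downhill
simplex in log-parameter space, which enforces positivity by
construction.  Each function evaluation is a full forward FLIP solve;
geometry-dependent matrices are assembled once and the parameter
dependence (D linear in alpha with the default Nitsche scaling, P in p,
B in beta, reaction matrices in gamma) is applied by cheap rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from .dg import (
    AssembledSystem,
    DGSpace,
    bleach_matrix,
    default_sigma,
    mass_matrix,
    membrane_matrix,
    run_flip,
    stiffness_matrix,
    weighted_mass_matrix,
)
from .errors import FieldMismatchError, ParameterError
from .geometry import TriMesh
from .imaging import GoalSeries
from .model import (
    DEFAULT_INITIAL_GUESS,
    BleachSchedule,
    FieldState,
    ModelParameters,
    RateMaps,
    init_fields_from_frame,
)

#: Default Nelder-Mead convergence tolerances (both x and f).
DEFAULT_TOLERANCE = 1e-4
#: Relative log-space perturbation generating the initial simplex.
INITIAL_SIMPLEX_STEP = 0.05


@dataclass
class MisfitConfig:
    """Frame selection and weighting of the misfit functional."""

    frame_indices: np.ndarray | None = None  # default: all frames
    weights: np.ndarray | None = None        # default: uniform, sum to 1

    def resolve(self, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
        idx = (np.arange(n_frames) if self.frame_indices is None
               else np.asarray(self.frame_indices, dtype=int))
        if np.any(idx < 0) or np.any(idx >= n_frames):
            raise ParameterError("frame index out of range")
        if self.weights is None:
            w = np.full(len(idx), 1.0 / len(idx))
        else:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(idx):
                raise ParameterError("one weight per selected frame required")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ParameterError("weights must sum to 1")
        return idx, w


def misfit(trajectory, goals: GoalSeries, M: sp.csr_matrix,
           config: MisfitConfig | None = None) -> float:
    """Weighted mean of squared L2 differences between snapshots and goals."""
    config = config or MisfitConfig()
    if len(trajectory.snapshots) != len(goals.coefficients):
        raise FieldMismatchError("trajectory and goals must have matching frames")
    if not np.allclose(trajectory.times, goals.times):
        raise FieldMismatchError("trajectory and goal times differ")
    idx, w = config.resolve(len(goals.coefficients))
    E = 0.0
    for i, wi in zip(idx, w):
        d = trajectory.snapshots[i].c - goals.coefficients[i]
        E += wi * float(d @ (M @ d))
    return E


@dataclass
class CalibrationSetup:
    """Cached geometry factors for repeated forward solves.

    ``c0`` is the initial (preconditioned, t = 0) total intensity as a
    DG coefficient vector; rate maps are rebuilt from it per candidate
    gamma, which amounts to rescaling cached unit matrices.
    """

    mesh: TriMesh
    schedule: BleachSchedule
    c0: np.ndarray

    def __post_init__(self) -> None:
        self.space = DGSpace(self.mesh)
        self.c0 = np.asarray(self.c0, dtype=float)
        self.M = mass_matrix(self.space)
        # D is linear in alpha when sigma keeps the default alpha scaling
        self.D_unit = stiffness_matrix(self.space, alpha=1.0, sigma=default_sigma(1.0))
        self.P_unit = membrane_matrix(self.space)
        self.B_unit = bleach_matrix(self.space)
        u0 = float(self.c0.min())
        if u0 <= 0:
            raise ParameterError("c0 must have a positive uniform background")
        self.u0 = u0
        self.Kp_unit = weighted_mass_matrix(self.space, self.c0 - u0)  # per unit gamma
        diam = self.mesh.diameters
        tris = self.mesh.edge_tris
        self.h_edge = np.where(
            tris[:, 1] >= 0,
            0.5 * (diam[tris[:, 0]] + diam[np.maximum(tris[:, 1], 0)]),
            diam[tris[:, 0]],
        )
        self.initial_state = init_fields_from_frame(self.c0)

    def system_for(self, params: ModelParameters) -> AssembledSystem:
        rates = RateMaps(k_plus=params.gamma * (self.c0 - self.u0),
                         k_minus=params.gamma * self.u0) if params.gamma > 0 else None
        return AssembledSystem(
            space=self.space,
            params=params,
            M=self.M,
            D=params.alpha * self.D_unit,
            P_unit=self.P_unit,
            Kp=params.gamma * self.Kp_unit,
            Km=(params.gamma * self.u0) * self.M if rates is not None
               else sp.csr_matrix(self.M.shape),
            B_unit=self.B_unit,
            sigma=default_sigma(params.alpha),
            h_edge=self.h_edge,
        )

    def forward(self, params: ModelParameters):
        return run_flip(self.initial_state.copy(), self.system_for(params), self.schedule)


@dataclass
class CalibrationResult:
    """Outcome of a Nelder-Mead calibration run."""

    best_params: ModelParameters
    best_E: float
    trace: list[dict] = field(default_factory=list)
    n_iterations: int = 0
    n_evaluations: int = 0
    converged: bool = False

    def trace_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.trace)

    def to_dict(self) -> dict:
        p = self.best_params
        return {
            "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma, "p": p.p,
            "best_E": self.best_E, "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations, "converged": self.converged,
        }


def calibrate(
    goals: GoalSeries,
    setup: CalibrationSetup,
    initial_guess: ModelParameters = DEFAULT_INITIAL_GUESS,
    x_tol: float = DEFAULT_TOLERANCE,
    f_tol: float = DEFAULT_TOLERANCE,
    config: MisfitConfig | None = None,
    max_iterations: int = 2000,
) -> CalibrationResult:
    """Estimate (alpha, beta, gamma, p) by Nelder-Mead on the misfit.

    The search runs in log-parameter space (positivity by construction);
    the initial simplex perturbs each log-coordinate by 5%.  A forward
    solve that fails yields E = +inf for that vertex and the search
    continues; a non-finite misfit at the initial guess aborts.
    """
    if np.any(initial_guess.as_array() <= 0):
        raise ParameterError("initial guess must be strictly positive")
    if not np.allclose(goals.times, setup.schedule.snapshot_times[: len(goals.times)]):
        raise FieldMismatchError("goal times do not match the schedule snapshot times")

    n_eval = 0
    cache: dict[bytes, float] = {}

    def objective(log_xi: np.ndarray) -> float:
        nonlocal n_eval
        key = np.asarray(log_xi, float).tobytes()
        if key in cache:
            return cache[key]
        n_eval += 1
        try:
            params = ModelParameters(*np.exp(log_xi))
            traj = setup.forward(params)
            E = misfit(traj, goals, setup.M, config)
        except Exception:
            E = np.inf
        cache[key] = E
        return E

    x0 = np.log(initial_guess.as_array())
    E0 = objective(x0)
    if not np.isfinite(E0):
        raise ParameterError("misfit is not finite at the initial guess")

    simplex = np.vstack([x0] + [x0 + INITIAL_SIMPLEX_STEP * e for e in np.eye(4)])

    trace: list[dict] = []

    def callback(xk):
        # xk is the current best simplex vertex; its misfit is cached
        params = np.exp(xk)
        trace.append({
            "iteration": len(trace) + 1,
            "alpha": params[0], "beta": params[1],
            "gamma": params[2], "p": params[3],
            "E_best": cache.get(np.asarray(xk, float).tobytes(), np.nan),
        })

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        callback=callback,
        options={
            "initial_simplex": simplex,
            "xatol": x_tol,
            "fatol": f_tol,
            "maxiter": max_iterations,
            "disp": False,
        },
    )
    best = ModelParameters(*np.exp(res.x))
    best_E = objective(res.x)  # cached re-evaluation at the optimum
    return CalibrationResult(
        best_params=best,
        best_E=float(best_E),
        trace=trace,
        n_iterations=int(res.nit),
        n_evaluations=n_eval,
        converged=bool(res.success),
    )
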