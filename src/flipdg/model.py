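"""Model parameters, initial conditions, rate maps and the bleach schedule.

The observed fluorescence c = u + u_b is split into freely diffusing
molecules u and reversibly hindered molecules u_b coupled by first-order
mass-action kinetics  u <-> u_b  with rates k+(x) (binding) and k-
(release).  Before bleaching the system is in equilibrium with u uniform,
so the spatial structure of the first image is carried entirely by u_b:

    u0 = min_x c0(x),    u_b0(x) = c0(x) - u0,
    k+(x) = gamma * u_b0(x),    k- = gamma * u0.

Bleaching acts as a linear sink with effective rate beta = b*q/(1+q)
inside the bleach region while the laser indicator theta(t) is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NormalizationError, ParameterError, ScheduleError

#: Stokes radii (nm) of permeation probes; diffusion scales as 1/R.
PROBE_STOKES_RADII_NM = {
    "Fl-Cys": 0.67,
    "Ubq": 1.69,
    "GFP": 2.42,
    "MBP": 2.85,
}


@dataclass(frozen=True)
class ModelParameters:
    """The four calibrated transport parameters.

    alpha : diffusion coefficient of free molecules (um^2/s)
    beta  : effective bleach rate b*q/(1+q) (1/s)
    gamma : rate-map proportionality constant (1/(intensity*s))
    p     : nuclear membrane permeability (um/s)
    """

    alpha: float
    beta: float
    gamma: float
    p: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ParameterError(f"alpha must be strictly positive, got {self.alpha!r}")
        # beta, gamma, p may be zero: no-bleach, no-reaction and
        # impermeable-membrane limits are legitimate model states.
        for name in ("beta", "gamma", "p"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be nonnegative, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.p])


#: Nelder-Mead starting point used for calibration when none is given.
DEFAULT_INITIAL_GUESS = ModelParameters(alpha=25.0, beta=20.0, gamma=0.5, p=0.05)


@dataclass
class RateMaps:
    """Spatially varying binding rate k+ and constant release rate k-."""

    k_plus: np.ndarray  # per-DG-node field, 1/s
    k_minus: float      # scalar, 1/s

    def __post_init__(self) -> None:
        self.k_plus = np.asarray(self.k_plus, dtype=float)
        if np.any(self.k_plus < 0):
            raise ParameterError("k_plus must be nonnegative everywhere")
        if self.k_minus <= 0:
            raise ParameterError("k_minus must be strictly positive")


@dataclass
class FieldState:
    """DG coefficient vectors of the two species at time t."""

    u: np.ndarray
    u_b: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.u_b = np.asarray(self.u_b, dtype=float)
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.u_b))):
            raise ParameterError("field coefficients must be finite")

    @property
    def c(self) -> np.ndarray:
        """Total observed intensity c = u + u_b."""
        return self.u + self.u_b

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.u_b.copy(), self.t)


@dataclass(frozen=True)
class BleachSchedule:
    """Bleach/recovery timing of the FLIP protocol.

    Defaults follow the imaging protocol: 0.8 s bleach + 1.8 s recovery
    per 2.6 s frame, 50 frames, solver step 0.2 s, snapshots recorded at
    t_i = 2.6*(i-1) + 2.0 s (offset 2.0 s into each frame).
    """

    t_bleach: float = 0.8
    t_recover: float = 1.8
    n_frames: int = 50
    dt: float = 0.2
    t_offset: float = 2.0

    def __post_init__(self) -> None:
        if min(self.t_bleach, self.t_recover, self.dt) <= 0 or self.n_frames < 1:
            raise ScheduleError("schedule intervals must be positive, n_frames >= 1")
        for name, value in (("t_bleach", self.t_bleach),
                            ("t_recover", self.t_recover),
                            ("t_offset", self.t_offset)):
            k = value / self.dt
            if abs(k - round(k)) > 1e-9:
                raise ScheduleError(f"{name} = {value} is not a multiple of dt = {self.dt}")
        if not (0 < self.t_offset <= self.frame_period):
            raise ScheduleError("t_offset must lie within the frame period")

    @property
    def frame_period(self) -> float:
        return self.t_bleach + self.t_recover

    @property
    def m(self) -> int:
        """Number of bleaching steps per frame (t_bleach = m*dt)."""
        return int(round(self.t_bleach / self.dt))

    @property
    def steps_per_frame(self) -> int:
        return int(round(self.frame_period / self.dt))

    @property
    def snapshot_step(self) -> int:
        """Step index within a frame at which the snapshot is recorded."""
        return int(round(self.t_offset / self.dt))

    @property
    def snapshot_times(self) -> np.ndarray:
        i = np.arange(1, self.n_frames + 1)
        return self.frame_period * (i - 1) + self.t_offset


def theta(t, schedule: BleachSchedule):
    """Laser indicator: 1 during the bleach interval of each frame, else 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("theta is defined for t >= 0")
    phase = np.mod(t, schedule.frame_period)
    out = (phase < schedule.t_bleach - 1e-12).astype(int)
    return out if out.ndim else int(out)


def init_fields_from_frame(c0: np.ndarray) -> FieldState:
    """Initialize (u, u_b) from the first preconditioned frame.

    Free molecules start at the uniform background u0 = min(c0); any
    excess intensity is hindered, so c0 is reproduced exactly.
    """
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0) or np.any(c0 > 1):
        raise NormalizationError(
            "c0 must lie in [0, 1]; run imaging.precondition() on the stack first"
        )
    u0 = float(c0.min())
    return FieldState(u=np.full_like(c0, u0), u_b=c0 - u0, t=0.0)


def build_rate_maps(c0: np.ndarray, gamma: float) -> RateMaps:
    """Rate maps k+(x) = gamma*(c0 - min c0), k- = gamma*min(c0).

    With this choice the initialization of :func:`init_fields_from_frame`
    satisfies the nodewise equilibrium k+ * u0 = k- * u_b0 exactly.
    """
    if gamma <= 0:
        raise ParameterError("gamma must be strictly positive")
    c0 = np.asarray(c0, dtype=float)
    u0 = float(c0.min())
    if u0 <= 0:
        raise ParameterError("c0 must have a positive uniform background (min(c0) > 0)")
    return RateMaps(k_plus=gamma * (c0 - u0), k_minus=gamma * u0)


def probe_parameters(base: ModelParameters, probe: str,
                     R_ref_nm: float = PROBE_STOKES_RADII_NM["GFP"]) -> ModelParameters:
    """Rescale calibrated parameters to a different inert permeation probe.

    Diffusion follows Stokes-Einstein (alpha ~ 1/R).  Passive nuclear
    pore permeability falls much faster than 1/R with probe size; a
    cubic scaling p ~ 1/R^3 is used as a smooth interpolant of that
    strongly nonlinear size dependence.  Bleach and binding rates are
    kept from the reference probe.
    """
    if probe not in PROBE_STOKES_RADII_NM:
        raise ParameterError(
            f"unknown probe {probe!r}; choose from {sorted(PROBE_STOKES_RADII_NM)}"
        )
    R = PROBE_STOKES_RADII_NM[probe]
    return ModelParameters(
        alpha=scale_by_stokes_radius(base.alpha, R_ref_nm, R),
        beta=base.beta,
        gamma=base.gamma,
        p=base.p * (R_ref_nm / R) ** 3,
    )


def permeability_from_influx(k_influx: float, V: float, A: float) -> float:
    """Permeability p = k * V / A from a first-order influx rate constant.

    ``V`` is the nuclear volume (um^3) and ``A`` the nuclear surface area
    (um^2); typical reference values are V = 1130 um^3, A = 540 um^2.
    """
    if min(k_influx, V, A) <= 0:
        raise ParameterError("k_influx, V and A must all be positive")
    return k_influx * V / A


def scale_by_stokes_radius(alpha_ref: float, R_ref: float, R_new: float) -> float:
    """Rescale a diffusion coefficient to a different Stokes radius.

    By the Stokes-Einstein relation D is inversely proportional to the
    hydrodynamic radius, so alpha_new = alpha_ref * R_ref / R_new.
    """
    if R_ref <= 0 or R_new <= 0:
        raise ParameterError("Stokes radii must be positive")
    if alpha_ref <= 0:
        raise ParameterError("alpha_ref must be positive")
    return alpha_ref * R_ref / R_new
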