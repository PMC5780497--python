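# flipdg

Quantitative modelling of **fluorescence loss in photobleaching (FLIP)**
microscopy.  In a FLIP experiment a small cytoplasmic spot is bleached
repeatedly while the whole cell is imaged; because transport keeps
feeding fluorophore into the spot, fluorescence falls everywhere, and
the shape of that loss encodes how molecules move.  `flipdg` turns a
FLIP image series (or a fully synthetic one) into estimates of

- **α** — the diffusion coefficient of the free probe (μm²/s),
- **β** — the effective bleach rate inside the spot (1/s),
- **γ** — the strength of local, reversible hindrance to diffusion
  (binding/release proportionality, 1/(intensity·s)),
- **p** — the passive permeability of the nuclear membrane (μm/s).

## Model and method

The observed intensity c = u + u_b splits into free (diffusing) and
hindered (immobile) pools coupled by mass-action exchange, with a
bleach sink acting in the spot while the laser indicator θ(t) is on:

    u_t     = ∇·(α∇u) + k⁻u_b − k⁺(x)u − χ_B θ β u
    (u_b)_t =           k⁺(x)u − k⁻u_b − χ_B θ β u_b

The rate maps come from the first (pre-bleach) image:
k⁺(x) = γ·u_b⁰(x), k⁻ = γ·u⁰ with u⁰ = min c⁰, so the start is an exact
equilibrium.  The nuclear membrane Γ_M is a *semipermeable interface*
across which the solution jumps, with flux J = p⟦u⟧.  The domain is
discretized by a symmetric interior-penalty discontinuous Galerkin
(SIPG) method on ~10³ triangles whose skeleton contains Γ_M; membrane
edges carry only the p-coupling, so the jump costs nothing to resolve.
Time stepping is backward Euler with pre-factorized bleach-on/off
matrices.  Parameters are estimated by Nelder-Mead on the misfit

    E = (1/N) Σ_i ∫_Ω |u(t_i)+u_b(t_i) − c_g(t_i)|² dx

against goal functions interpolated from the blurred, normalized
images.  A pixel-wise stretched-exponential
(I₀·exp[−(t/τ)^(1/h)] + I_b) fitting module provides an independent,
model-free description of the same data for validation.  See
`docs/methods.md` for the full account.

## Worked example

Recover the generating parameters of a synthetic FLIP experiment,
starting the search from the standard distant guess (25, 20, 0.5, 0.05):

```python
import numpy as np
from flipdg import (build_synthetic_geometry, triangulate, BleachSchedule,
                    ModelParameters, CalibrationSetup, calibrate, GoalSeries)

geometry = build_synthetic_geometry(
    cell_ellipse=((7.5, 7.5), (6.0, 5.0)),      # 12 x 10 um cell
    nucleus_ellipse=((7.5, 7.5), (2.5, 2.0)),
    bleach_center=(11.5, 7.5),                  # 1.64 um disk in the cytoplasm
)
mesh = triangulate(geometry, target_edge_length=0.72)
print(f"mesh: {mesh.n_elements} triangles "
      f"({int((mesh.element_region == 2).sum())} nucleus, "
      f"{int(mesh.element_bleach.sum())} bleach)")

schedule = BleachSchedule(n_frames=20)          # 0.8 s bleach + 1.8 s recovery
region = np.repeat(mesh.element_region, 3)
c0 = np.where(region == 2, 0.9, 0.4).astype(float)
setup = CalibrationSetup(mesh, schedule, c0)

truth = ModelParameters(alpha=16.1, beta=35.6, gamma=0.319, p=0.111)
traj = setup.forward(truth)
goals = GoalSeries([s.c.copy() for s in traj.snapshots], traj.times)

result = calibrate(goals, setup)                # starts from (25, 20, 0.5, 0.05)
est = result.best_params
print(f"recovered: alpha={est.alpha:.2f} beta={est.beta:.2f} "
      f"gamma={est.gamma:.4f} p={est.p:.4f}")
print(f"misfit E = {result.best_E:.3g} after {result.n_iterations} iterations "
      f"({result.n_evaluations} forward solves)")
```

Output (about half a minute on one core):

```
mesh: 393 triangles (60 nucleus, 8 bleach)
recovered: alpha=16.10 beta=35.60 gamma=0.3190 p=0.1110
misfit E = 6.34e-12 after 187 iterations (318 forward solves)
```

All four transport parameters come back at their generating values: the
diffusion coefficient and bleach rate to five significant figures, the
hindrance constant and membrane permeability to better than 0.01%.
The misfit trace (`result.trace`) is monotone non-increasing, mirroring
how the optimizer walks the calibration surface.

## Command line

The same pipelines are available as commands, each driven by a flat
YAML config with `-O key=value` overrides and writing a config echo for
reproducibility:

```sh
flipdg make-synthetic -o out/syn -O seed=7 -O noise_sd=0.01
flipdg simulate       -o out/sim -O probe=MBP
flipdg calibrate      -o out/cal --stack out/syn/stack.tif --labels out/syn/labels.tif
flipdg strexp         -o out/maps --stack out/syn/stack.tif --labels out/syn/labels.tif
```

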