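# Methods

## Model

Fluorescence loss in photobleaching (FLIP) repeatedly bleaches a fixed
cytoplasmic spot while imaging the whole cell; transport toward the spot
drains fluorescence everywhere, so the spatiotemporal loss profile
carries information about diffusion, local hindrance and nuclear
membrane permeability.  `flipdg` models the observed intensity
c = u + u_b as two species on the segmented cell domain
Ω = Ω_N ∪ Ω_C:

    u_t     = ∇·(α∇u) + k⁻ u_b − k⁺(x) u − χ_B θ(t) β u
    (u_b)_t =           k⁺(x) u − k⁻ u_b − χ_B θ(t) β u_b

Only the free species u diffuses.  Hindrance (crowding, transient
non-specific binding, partitioning into nuclear subdomains) is modelled
by first-order mass-action exchange with spatially varying binding rate
k⁺ and constant release rate k⁻.  Bleaching is a linear sink with
effective rate β acting inside the bleach disk Ω_B whenever the laser
indicator θ(t) is on (the ground/excited-state photophysics underlying β
is not resolved; β is the only identifiable combination from FLIP data).

Before bleaching the system is in equilibrium with u spatially uniform,
so the structure of the first (preconditioned) image c⁰ is carried by
the hindered pool:

    u⁰ = min_x c⁰(x),   u_b⁰ = c⁰ − u⁰,
    k⁺(x) = γ u_b⁰(x),  k⁻ = γ u⁰.

This makes the initialization an exact discrete steady state (verified
to 1e-10 over a full 50-frame no-laser protocol), and leaves four free
parameters: α (μm²/s), β (1/s), γ (1/(intensity·s)) and the membrane
permeability p (μm/s).

At the nuclear membrane Γ_M the concentration may jump; the diffusive
flux is proportional to the jump (semipermeable interface):

    J·n⁻ = −α ∂u⁻/∂n⁻ = p ⟦u⟧·n⁻   on Γ_M,

with zero flux on the outer cell boundary.

## Discretization

The spatial discretization is a symmetric interior-penalty
discontinuous Galerkin (SIPG) method on triangles with discontinuous
piecewise-linear elements.  (Descriptions of this family of schemes
sometimes say "piecewise bilinear"; on triangles the standard space is
affine per element, which is what all second-order convergence
statements here refer to.)  Interior edges carry the usual consistency,
symmetry and (σ/h) penalty terms; h on an edge is the mean of the two
adjacent element diameters.  Membrane edges carry *only* the coupling
p∫⟦u⟧·⟦v⟧ ds — the interface condition is the physics there and
replaces the continuity penalty, so the jump across Γ_M is resolved on
meshes of ~10³ elements rather than the ~10⁵ a conforming method needs
to resolve the same layer.

Numerical choices:

- **Nitsche parameter.** σ = 20·α·(degree+1)² by default, configurable.
  Coercivity is probed at assembly by checking the smallest eigenvalue
  of the stiffness form on a small structured mesh (threshold −1e-10).
  Because σ scales with α, the stiffness matrix is linear in α, which
  the calibrator exploits.
- **Quadrature.** Element integrals use the 3-point edge-midpoint rule
  (exact for the quadratic integrands of P1 mass/stiffness terms); edge
  integrals use 2-point Gauss (exact through cubics).  The weighted
  reaction matrix uses the same pointwise rule as the mass matrix, so
  the nodewise equilibrium identity k⁺u⁰ = k⁻u_b⁰ transfers exactly to
  the discrete system.
- **Time stepping.** Backward Euler, fully implicit and monolithic in
  (u, u_b): one sparse 2n×2n solve per step.  The two step matrices
  (laser on / off) are factorized once (SuperLU) and reused across all
  steps of a run.  The bleach interval must be a whole number of steps
  (Δt_b = mΔt); the protocol default 0.8 s + 1.8 s per frame with
  Δt = 0.2 s gives m = 4, 13 steps per frame and snapshots at
  t_i = 2.6(i−1) + 2.0 s.
- **Degenerate inputs.** Meshes with a minimum angle below 20° are
  rejected (the penalty scaling assumes shape regularity); singular step
  matrices raise a solver error rather than returning NaNs.

Verification (all recomputed by `scripts/acceptance.py` and the test
suite): manufactured smooth solution gives observed L² orders ≈ 2 in h
and ≈ 1 in Δt; a two-slab steady problem whose exact solution is
piecewise linear with jump J/p at the membrane is reproduced to solver
tolerance at any resolution; in the fast-diffusion limit the
compartment-mean contrast decays at the two-compartment ODE rate
p·|Γ_M|·(1/|Ω_N|+1/|Ω_C|) to within a fraction of a percent.

## Meshing

Meshes are generated in-package: outlines (analytic ellipses or
polygons traced from label masks) are resampled at the target edge
length, the nucleus and the cytoplasmic annulus are triangulated
separately by Delaunay triangulation of boundary plus hexagonal
interior points, boundary segments are verified to be triangulation
edges (interior points blocking a segment's diametral circle are
removed and the triangulation rebuilt), and a few Laplacian smoothing
passes improve element quality.  Because both submeshes share the
identical nucleus-outline vertices, the membrane is exactly a subset of
the mesh skeleton and every membrane edge separates a nucleus element
from a cytoplasm element.  The bleach disk is represented by flagging
elements whose centroid lies inside it — the bleach term is a volume
source, so no interface needs to conform to its boundary.  At the
imaging-protocol scale this yields ~1.5·10³ triangles with a few tens
in the bleach spot.

## Imaging pipeline

Stacks are single-channel multi-page TIFFs (float32, with a JSON
sidecar for times/pixel size; integer input is scaled by the dtype
maximum).  Preconditioning mirrors the experimental pipeline: Gaussian
blur with σ = 1 pixel ("radius of one pixel", interpreted as the
standard deviation) restricted to the cell mask by normalized
convolution and rescaled to conserve total masked intensity, then the
whole stack is normalized by the maximum of the first blurred frame.
Goal functions c_g(t_i) are built by nodal interpolation of the
preconditioned frames (per-element least squares would differ at second
order in pixel size); pixels outside the mask are first replaced by
their nearest inside value so boundary nodes never interpolate against
background zeros.  Rasterization evaluates each pixel center in its
containing element, so membrane jumps remain visible in rendered
images.  The raster row axis points down while mesh y points up;
y = (n_rows − row − 0.5)·pixel_size throughout.

## Calibration

The misfit is the frame-averaged squared L² distance between simulated
total intensity and the goals,
E = (1/N) Σ_i ∫_Ω |u(t_i)+u_b(t_i) − c_g(t_i)|² dx, evaluated exactly
through the mass matrix.  The four parameters are estimated by
Nelder-Mead in log-parameter space (positivity holds by construction;
the search space is smooth and unbounded), starting from
(α, β, γ, p) = (25, 20, 0.5, 0.05) with x- and f-tolerances 1e-4 and an
initial simplex perturbing each log-coordinate by 5% (the simplex
construction is a package choice; no standard prescription exists).
Each evaluation is a full forward solve; geometry factors are assembled
once and the parameter dependence applied by rescaling (D ∝ α with the
default σ, P ∝ p, B ∝ β, reaction matrices ∝ γ), so a 20-frame forward
solve on a ~400-element mesh costs ~0.1 s and a full calibration
~300 evaluations.  A forward failure at a vertex yields E = +∞ and the
search continues; a single search is run (no multi-start).

On self-consistent synthetic goals (20 frames, ~400 elements) all four
parameters are recovered to well under 1% from the standard distant
start; with additive Gaussian noise of 0.01 on the goal coefficients
recovery stays within ~1%.  Against stacks that pass through the full
imaging pipeline (different mesh, blur, rasterization) α and β remain
well identified while γ and p acquire visible bias at short protocols —
p is weakly identified when the membrane jump is small, and is reported
rather than trusted to tight tolerance.

## Synthetic data

The generator forward-simulates the imaging protocol: 15×15 μm field at
0.05467326 μm/pixel, a 30-pixel (1.64 μm) diameter bleach disk in the
cytoplasm, 0.8 s bleach + 1.8 s recovery per 2.6 s frame, 50 frames,
snapshots at t_i = 2.6(i−1)+2.0 s, with a pre-bleach frame at t = 0.
The default initial pattern is 0.4 in the cytoplasm and 0.9 in the
nucleus (nuclear accumulation of the probe); the default operating
point is (α, β, γ, p) = (16.1, 35.6, 0.319, 0.111), a realistic set for
a GFP-sized probe.  Noise is additive Gaussian (default sd 0.01),
seeded and clipped at zero; a Poisson model is deliberately not the
default.  The generator does not emulate scan-time integration (frames
are instantaneous snapshots), detector offset/gain drift, cell
movement, or segmentation error — so passing recovery tests shows the
estimator is correct and well conditioned under the stated protocol,
not that real acquisitions are free of those systematic effects.

## StrExp analysis

As an independent, model-free description of the loss kinetics, each
pixel trace is fitted with the stretched/compressed exponential
I(t) = I₀·exp[−(t/τ)^(1/h)] + I_b (bounded least squares, 0 < h ≤ 2;
initialization: I_b from the last 10% of frames, τ from the 1/e
crossing, h = 1).  h < 1 is a delayed (compressed) decay with a rate
coefficient k(t) = (1/(hτ))(t/τ)^(1/h−1) that increases in time; h > 1
a stretched decay with decreasing rate; h = 1 mono-exponential.  The
integral identity exp(−∫₀ᵗ k ds) = exp(−(t/τ)^(1/h)) is verified
numerically.  On simulated FLIP runs with a tight membrane the τ map
steps abruptly across the nuclear outline — the membrane is visible as
a kinetic barrier without being imposed on the fitting model.

## Probe presets

Calibrated GFP parameters can be rescaled to other inert probes by
Stokes radius (Fl-Cys 0.67 nm, ubiquitin 1.69 nm, GFP 2.42 nm, MBP
2.85 nm): diffusion by Stokes-Einstein (α ∝ 1/R) and permeability by
p ∝ 1/R³, a smooth interpolant chosen here for the much steeper size
dependence of passive nuclear-pore permeation reported for inert
probes; it preserves the experimentally observed ordering (larger
probes show strongly delayed nuclear loss) without claiming a
mechanistic pore model.

## Problem sizes used in the shipped checks

Equilibrium/conservation run on a ~1450-element mesh (50 frames, 650
steps); convergence studies on structured meshes up to 32×32×2
elements; calibration benchmarks on a ~400-element mesh with 20 frames;
StrExp round trips on 50-point traces.  These sizes reproduce the
asymptotics cleanly while keeping a full acceptance run around a
minute on one core.

## Known limitations

Single cell, single 2-D slice; passive (not receptor-mediated) membrane
transport; no diffusion of the hindered pool; no anomalous/fractal
diffusion; Chan-Vese-style segmentation is out of scope (label masks
are taken as given, including which frame they were drawn from);
snapshot (not scan-integrated) image formation; first-order time
stepping (L-stable, but Δt = 0.2 s is dictated by the bleach pulse
structure rather than accuracy).
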