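# Methods

## Model

A giant unilamellar vesicle (GUV) of undeformed radius `a` sediments under
gravity through a viscous fluid toward a flat, rigid, no-slip wall at
`z = 0`. Both the membrane and the wall carry like charges, so a screened
electrostatic repulsion opposes the descent; the vesicle settles into an
equilibrium shape and gap where the buoyant weight, the wall repulsion and
the membrane's elastic resistance balance. The Reynolds number of the
experimental system is of order 1e-6, so inertia is neglected entirely
(Stokes flow).

The model has four ingredients:

1. **Hydrodynamics.** Creeping flow bounded by a plane wall, solved with a
   boundary-integral (single-layer) formulation. Because the interior and
   exterior fluids have the same viscosity (viscosity ratio 1, as in the
   sucrose/glucose experiments), the double-layer term cancels and the
   interfacial velocity is

       u(x0) = (1/8π) ∮ G(x, x0) · q(x) dS(x),

   with `G` the Blake tensor — the free-space Stokeslet plus its image
   system (image Stokeslet, potential dipole, Stokeslet doublet), which
   enforces `u = 0` exactly on the wall plane — and `q` the traction jump
   across the membrane.

2. **Membrane mechanics.** The traction jump carries the shape gradient of
   the Helfrich bending energy plus an isotropic tension:

       E = (κ_b/2) ∮ (2H)² dS + σ A,
       q_H = κ_b [2 Δ_s H + 4 H (H² − K)] n̂ − 2 σ H n̂,

   with `H` the mean curvature (H = +1 on the unit sphere with outward
   normals), `K` the Gaussian curvature and `Δ_s` the surface Laplacian.
   The tension σ is a single global value tied to the instantaneous area
   strain α = (A − A₀)/A₀ by the Evans–Rawicz law

       α(σ) = [k_BT/(8π κ_b)] ln(1 + c σ a²/κ_b) + σ/K_A,   c = 1/(24π),

   which superposes the entropic smoothing of thermal undulations
   (logarithmic) and direct area-per-lipid dilation (linear). At the
   tensions arising here (σ̄ up to a few 1e4 in units of κ_b/a²) more than
   99% of the strain is undulation smoothing. The law is inverted for σ(α)
   with a bracketed root find each time step; negative strain means a slack
   membrane and maps to σ = 0.

3. **Gravity.** The density contrast Δρ between interior and exterior
   solutions enters as a normal traction `−Δρ g z n̂`, whose closed-surface
   integral is exactly the buoyant weight `−Δρ g V ê_z`.

4. **Electrostatics.** In the Derjaguin (parallel-plate) and linearized
   Poisson–Boltzmann approximations, each membrane element at height `h`
   feels a vertical repulsion per unit area

       q_el = (2 ε ψ_g ψ_v / λ_D²) e^(−h/λ_D) ê_z,

   where λ_D = sqrt(ε k_BT / 2 e² n) is the Debye length of the (1:1)
   electrolyte of number density `n`, ψ_g = σ_g λ_D/ε is the glass
   potential in the linear (low-charge) regime, and the highly charged
   membrane's potential is replaced by the saturated (charge-renormalized)
   value ψ_v = ±4 k_BT/e ≈ ±102 mV, which carries the sign of the membrane
   charge but is independent of its magnitude.

### Nondimensionalization

Lengths are scaled by `a`, tractions by κ_b/a³, time by μa³/κ_b, velocity
by κ_b/(μa²). Four dimensionless groups govern a run:

| group | definition | meaning | typical value |
|---|---|---|---|
| Bg | Δρ g a⁴ / κ_b | buoyant weight vs bending | 2e1–5e3 |
| B_el | 2 ε ψ_g ψ_v a³ / (λ_D² κ_b) | repulsion strength | 1e7–1e9 |
| λ̄ | λ_D / a | screening length | 3e-4–3e-2 |
| c̃ | K_A a² / κ_b | direct-dilation stiffness | 1e8–1e9 |

plus κ_b/k_BT = 40 (enters the undulation term) and the viscosity ratio,
fixed at 1.

## Default physical parameters

The presets describe POPC GUVs in 1 M sucrose (inside) / glucose (outside)
over plain glass:

| parameter | default | rationale |
|---|---|---|
| κ_b | 40 k_BT | fluid-phase PC bilayer |
| Δρ | 35 kg/m³ | sucrose/glucose contrast |
| K_A | 0.2 N/m | micropipette value for PC membranes |
| T | 296 K | room temperature |
| ε | 78.5 ε₀ | aqueous solution |
| μ | 2.0 mPa·s | ~1 M sugar solution |
| σ_glass | −2 mC/m² | plain glass at pH ≈ 7.5 |
| σ_vesicle | −2 mC/m² | ~1 mol% charged dye-lipid; only its sign matters after renormalization |
| n_ion | preset | `no-salt` 1.02 µM (λ_D ≈ 300 nm), `calcein` 2 µM (214 nm), `salt-3mM` 3 mM (5.5 nm) |

μ and K_A affect only the mapping to physical time and to strain,
respectively; no dimensionless result depends on μ at all.

## Numerical method

- **Mesh.** Recursively subdivided icosahedron projected to the unit
  sphere; refinement `k` has 10·4^k + 2 vertices (642 at the default
  k = 3). Surface integrals use the vertex "trapezoidal" rule: one third of
  each flat triangle's area is assigned to each of its corners.
- **Discrete operators** (Meyer et al. mixed-area formulation): cotangent
  Laplacian with Voronoi areas and an obtuse-triangle fallback; mean
  curvature from the magnitude of the discrete Laplace–Beltrami of the
  positions; Gaussian curvature from the angle deficit, which makes the
  Gauss–Bonnet sum exactly 4π on any closed genus-0 mesh; Δ_s H by applying
  the same Laplacian to the H field.
- **Singular quadrature.** The Blake kernel's 1/r singularity at the
  evaluation vertex is removed by subtracting the field
  `(q(x0)·n̂(x0)) n̂(x)` before summing and dropping the self term; the
  subtracted field integrates to exactly zero velocity by the
  incompressibility identity ∮ G_ij(x, x0) n_j(x) dS = 0, so no residual
  is discarded. A side effect is that uniform-pressure tractions `c n̂` are
  annihilated exactly by the discrete operator, as they are in the
  continuum.
- **Time stepping.** Explicit midpoint (RK2) on vertex positions with an
  adaptive step `dt = safety / Σ rates`, combining the advective CFL limit
  (C = 0.2 on the minimum edge) with explicit-stability caps for the three
  stiffest membrane modes at the edge scale: bending (∝ q³ with
  q = π/h_min), tension (∝ σ̄ q) and the electrostatic spring (∝ local
  traction gradient). The 0.085 coefficients were calibrated against the
  measured blow-up threshold and keep a ~2x margin at `safety = 1`.
- **Mesh stabilization.** Advecting vertices with the full physical
  velocity lets them drift tangentially and degrades the triangulation.
  Only the normal component moves the shape, so the tangential motion is
  replaced by the field `w` minimizing Σ_edges (d|x_i − x_j|²/dt)² subject
  to `w·n̂ = 0` (Zinchenko's passive stabilization), solved as a sparse
  linear least-squares problem once per RK2 step (warm-started conjugate
  gradients) and reused in the midpoint stage.
- **Equilibrium detection.** max |u·n̂| below a tolerance for 10
  consecutive samples. The library default is 1e-6; see below for what the
  shipped runs use.

## Problem sizes and budgets

Default runs use refinement 3 (642 vertices), matching the physical
regime's resolution needs; the test suite's sedimentation fixtures use
refinement 2 (162 vertices) with an equilibrium tolerance of 1e-2, and the
acceptance script uses refinement 3 with a per-run step budget.

Two deliberate consequences of those budgets:

- **Slow terminal relaxation.** Near equilibrium the slowest shape mode
  decays at a dimensionless rate of order 1 while the explicit stability
  limit forces dt ~ 1.5e-4 at refinement 3, i.e. thousands of steps per
  e-fold of velocity decay; driving max |u·n̂| to 1e-6 is an hours-scale
  run. The observables asserted on are insensitive to this: the gap is
  converged to well under a percent at tolerance 1e-2, and the strain
  decays monotonically from above toward its equilibrium value, so a
  budget-stopped run reports a slight over-estimate — conservative for an
  upper-bound claim.
- **Volume drift near the wall.** The continuum single layer of a closed
  surface carries no volume flux, and far from the wall the discrete drift
  rate is below 1e-3 per unit time at refinement 2. In the near-wall film
  the flow is under-resolved at refinement 2 and a long settled run loses
  a few percent of enclosed volume (reduced-volume drift ≈ 0.08 over a
  t = 8 run); the drift is dt-independent (a spatial discretization error)
  and shrinks rapidly with refinement (reduced-volume drift 1.2e-2 over a
  comparable refinement-3 run). Passive stabilization is essential here:
  without it the same run loses several times more.

## Limitations

- **Uniform tension.** Area incompressibility is enforced globally, not
  locally; tension gradients (Marangoni stresses) are absent. One visible
  consequence: the vertical electrostatic traction has a tangential
  component on the sloped flanks that uniform tension cannot balance, so
  the steady state carries a persistent tangential surface circulation and
  the integrated repulsion slightly exceeds the weight, the excess being
  carried by the circulation's drag. In the experimental regime (λ̄ of
  order 1e-2) the repulsion acts almost entirely on the flat bottom cap
  and the effect is negligible.
- **Resolution floor on the gap.** Equilibrium gaps are reliable only when
  they and the loaded cap (lateral width ~ sqrt(2 a λ_D)) are resolved by
  the near-wall mesh; the 5.5 nm salt branch at experimental radii
  (gap ~ 1e-3 a) is below that floor at any affordable refinement.
- **No thermal fluctuations, no shear, single vesicle**; viscosity ratio
  fixed at 1; genus-0 closed membranes only.
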