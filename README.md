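# vesised

Boundary-integral simulation of a charged giant unilamellar vesicle (GUV)
sedimenting through a viscous fluid onto a charged flat wall.

A cell-sized lipid vesicle filled with sucrose solution and suspended in
glucose solution is a few percent denser than its surroundings, so it sinks.
Near a glass surface, the electrostatic double-layer repulsion between the
(negatively charged) membrane and the (negatively charged) glass stops the
descent at a gap of a few screening lengths, where the vesicle rests,
slightly flattened, on an electrostatic cushion. `vesised` simulates this
process end to end:

- **Stokes flow** bounded by a no-slip wall, via a single-layer boundary
  integral with the Blake image-system Green's function (viscosity ratio 1);
- **membrane mechanics**: Helfrich bending elasticity on a triangulated
  surface (Meyer et al. discrete curvature operators) with a global tension
  tied to area strain by the Evans–Rawicz law (thermal-undulation smoothing
  plus direct dilation);
- **electrostatics**: linearized Poisson–Boltzmann / Derjaguin wall
  repulsion with charge renormalization of the membrane potential;
- **dynamics**: explicit midpoint (RK2) time stepping with an adaptive
  stability-limited step and Zinchenko passive mesh stabilization.

Observables are the ones measurable in a sedimentation experiment: the
velocity–distance curve, the equilibrium gap, and the equilibrium membrane
area strain. Everything is deterministic; no external data is needed.

See [docs/methods.md](docs/methods.md) for the model, the
nondimensionalization, all default parameters, numerical choices and known
limitations.

## Worked example

A 20 µm-radius vesicle (the `calcein` preset: bending modulus 40 k_BT,
density contrast 35 kg/m³, Debye length 214 nm) released 2.5 radii above
the wall, on the 162-vertex mesh — about a minute on one core:

```python
import numpy as np
from vesised import preset_params, nondimensionalize, simulate

params = nondimensionalize(preset_params("calcein", {"a": "20 um"}))
print(f"Bg = {params.Bg:.0f}, B_el = {params.B_el:.2e}, "
      f"lambda_bar = {params.lambda_bar:.4f}")

traj = simulate(params, refinement=2, initial_height=2.5, equil_tol=1e-2)
print(traj.status)
print(f"equilibrium gap    = {traj.gap[-1]:.3f} radii "
      f"({traj.gap[-1] / params.lambda_bar:.0f} Debye lengths)")
print(f"equilibrium strain = {traj.strain[-1]:.2e}")
print(f"reduced tension    = {traj.tension[-1]:.0f}")
```

prints

```
Bg = 336, B_el = 9.32e+07, lambda_bar = 0.0107
equilibrated
equilibrium gap    = 0.122 radii (11 Debye lengths)
equilibrium strain = 1.47e-03
reduced tension    = 255
```

`traj.to_dataframe()` gives the full time series (centroid height,
sedimentation rate, gap, area, strain, tension, reduced volume);
`traj.final_mesh` is the equilibrium shape.

The same run from the command line, with CSV/PLY/YAML outputs:

```sh
cat > run.yaml <<'YAML'
preset: calcein
physical:
  a: 20 um
run:
  refinement: 2
  initial_height: 2.5
  equil_tol: 1e-2
YAML
vesised simulate --config run.yaml --out out/
```

`vesised sweep` varies one group (`Bg` or `lambda_bar`) and tabulates the
equilibrium gap and strain; `vesised convert` translates mesh snapshots
between PLY and legacy-ASCII VTK for viewing.

Parameter files take either a `physical` block (unit-annotated strings,
optionally on top of a named preset: `no-salt`, `calcein`, `salt-3mM`,
`uncharged`) or a `dimensionless` block giving the groups directly.

## References

- J. R. Blake, *A note on the image system for a stokeslet in a no-slip
  boundary*, Proc. Camb. Phil. Soc. 70, 303 (1971).
- M. Meyer, M. Desbrun, P. Schröder, A. H. Barr, *Discrete
  differential-geometry operators for triangulated 2-manifolds*, Visualization
  and Mathematics III (2003).
- E. Evans, W. Rawicz, *Entropy-driven tension and bending elasticity in
  condensed-fluid membranes*, Phys. Rev. Lett. 64, 2094 (1990).
- A. Z. Zinchenko, M. A. Rother, R. H. Davis, *A novel boundary-integral
  algorithm for viscous interaction of deformable drops*, Phys. Fluids 9,
  1493 (1997).
- C. Pozrikidis, *Boundary Integral and Singularity Methods for Linearized
  Viscous Flow* (Cambridge, 1992).
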