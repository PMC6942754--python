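# nspefsim

2D finite-element simulation of nanosecond pulsed-electric-field (nsPEF)
electroporation of a single biological cell, with optional randomly placed
conductive carbon-nanotube (CNT) capsules that locally intensify the field.

## Who this is for

Researchers in computational bioelectromagnetics and membrane biophysics who
want a self-contained, reproducible desk-scale model of how sub-microsecond
high-intensity pulses permeabilize the plasma membrane and nuclear envelope,
and how nearby high-aspect-ratio conductors (the "lightning-rod" effect)
enhance that permeabilization — without a commercial FEM package.

## The model

A five-layer dielectric cell — extracellular medium, plasma membrane,
cytoplasm, nuclear envelope, nucleoplasm — sits centered in a 200 µm square
between plate electrodes driven by a trapezoidal pulse (6 kV/cm, 300 ns,
2 ns rise). The potential obeys the quasi-static conduction + displacement
law

    −∇·(σ∇ψ) − ∇·(ε₀ε_r ∂t∇ψ) = 0,

and each membrane is a zero-thickness distributed-impedance interface whose
normal current is

    J = (σ_mem0/d) V_m + (ε₀ε_mem/d) ∂t V_m + J_EP,   V_m = ψ_in − ψ_out.

Electroporation closes the loop: the pore density N follows the asymptotic
Smoluchowski-derived law dN/dt = α e^{(V_m/U_ep)²}(1 − (N/N₀)e^{−q(V_m/U_ep)²}),
a representative pore radius drifts down the pore-energy gradient
dr/dt = −(D/kT)∂W/∂r, and the pores feed back as an areal conductance
g_ep = N/(R_interior + R_access) that clamps V_m near 1 V. CNTs are 2D
stadium capsules (σ = 10⁸ S/m) placed by seeded Monte Carlo rejection
sampling near the cell. Derived outputs: field-strength area histograms, the
electroporated area S = ∮ π r² N ds along each membrane, and its time
integral, the permeabilized flux. See `docs/methods.md` for assumptions,
parameter provenance (including the corrections ledger), and limitations.

## Worked example

```python
import warnings, numpy as np
import nspefsim as ns
from nspefsim import postprocess, solver

params = ns.default_params()
params.mesh.h_membrane = 0.5e-6   # coarse demo resolution
scene = ns.build_scene(params, [])           # CNT-free five-layer cell
mesh = ns.build_mesh(scene, h_far=params.mesh.h_far,
                     h_membrane=params.mesh.h_membrane)
res = solver.run_simulation(params, mesh, snapshot_times=(152e-9,))
ctx = solver.assemble(mesh, params)
E, e_max = solver.field_magnitude(ctx, res.snapshots[0].psi)
cell = solver.cell_interior_mask(mesh)
outer = postprocess.electroporated_area(res, "outer_membrane")
vm = res.membranes["outer_membrane"]["V_m"]
print(f"mesh: {mesh.n_triangles} triangles, {res.n_steps} implicit steps")
print(f"plateau max |E|: {e_max/1e5:.1f} kV/cm (domain), "
      f"{E[cell].max()/1e5:.1f} kV/cm (cell interior)")
print(f"peak outer-membrane TMV: {np.abs(vm).max():.2f} V")
print(f"electroporated area S_outer: peak {outer.S.max()*1e6:.3f} um^2/um, "
      f"end {outer.S[-1]*1e6:.3f} um^2/um")
print(f"permeabilized flux at 400 ns: {outer.flux[-1]:.3e} m*s")
```

prints

```
mesh: 4776 triangles, 483 implicit steps
plateau max |E|: 15.0 kV/cm (domain), 15.0 kV/cm (cell interior)
peak outer-membrane TMV: 1.01 V
electroporated area S_outer: peak 0.979 um^2/um, end 0.946 um^2/um
permeabilized flux at 400 ns: 3.018e-13 m*s
```

Reading this: the applied 6 kV/cm concentrates on the membranes as they
charge; pores form where |V_m| crosses ~1 V and their conductance pins the
TMV there (1.01 V). The domain maximum at the plateau sits at the porated
nuclear envelope's poles, where the conductive nucleoplasm concentrates the
cytoplasmic field (a feature only a resolved mesh shows — see
`docs/methods.md` on how this compares with coarse-mesh map readings). The
electroporated area grows until the pulse ends at 302 ns and then shrinks as
pores reseal toward their resting radius.

The same pipeline is scriptable from the shell:

```bash
nspefsim run --seed 1 --out out/            # full run with 5 random CNTs
nspefsim run --no-cnts --out out_free/      # CNT-free reference
nspefsim compare --seed 1 --out compare.csv # matched with/without-CNT table
nspefsim sweep --parameter cnt_aspect --values 10,30,100 --seeds 0,1 --out sweep.csv
nspefsim show-ledger                        # parameter corrections ledger
```

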