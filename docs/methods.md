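# Methods

`nspefsim` simulates the electroporation of a single spherical cell — modeled
as its 2D cross-section — exposed to a nanosecond pulsed electric field
(nsPEF), with optional randomly placed, highly conductive carbon-nanotube
(CNT) capsules near the cell. This note records the model, its assumptions,
the numerical choices, and what the synthetic scenes do and do not capture.

## Electromagnetic model

The domain is a 200 µm square with plate electrodes spanning the left
(driven) and right (grounded) edges; the top and bottom edges carry no normal
current. On the quasi-static time scale of interest the potential ψ obeys the
conduction + displacement current law

    −∇·(σ∇ψ) − ∇·(ε₀ε_r ∂t ∇ψ) = 0,

with piecewise-constant (σ, ε_r) per region: extracellular medium (1 S/m,
80), cytoplasm (0.3 S/m, 154.4), nucleoplasm (1.35 S/m, 52), and CNT
(10⁸ S/m, 10⁴). The drive is a trapezoidal pulse: 6 kV/cm plateau (field =
electrode voltage / 200 µm), 2 ns rise, 300 ns width; the unspecified fall
time defaults to the rise time, and simulations run to 400 ns so post-pulse
resealing is visible.

The two membranes (plasma membrane, 5 nm; nuclear envelope, 40 nm) are *not*
meshed as thin layers — at 5 nm in a 200 µm domain that is intractable and
unnecessary. Each membrane is a zero-thickness interface carrying the
distributed-impedance current law

    J_n = (σ_mem0/d) V_m + (ε₀ε_mem/d) dV_m/dt + J_EP,

where V_m = ψ_inner − ψ_outer is the transmembrane voltage (TMV). V_m is
bookkept *relative to rest*: the −80 mV resting potential enters only as the
offset of the conduction term, so the rest state is exactly stationary, and
the pore equations below are driven by the deviation V_m. Since the resting
potential is 80 mV against a ~1 V poration scale, this convention is
inconsequential for results.

Because the model is a 2D plane, the passive steady-state TMV of the cell
cross-section follows the cylinder form V_m = 2 r_c E cosθ (not the
spherical 1.5 r_c E cosθ), and the membrane charging time constant is
τ = C_m (σ_i σ_e / (r_c(σ_i+σ_e)) + g_m)⁻¹ ≈ 656 ns — longer than the pulse,
so the membrane is still charging when poration fires. Both relations are
verified against the solver in the test suite (steady state to 2%, τ to 5%).

## Electroporation model

Pore density N (m⁻²) per interface node follows the asymptotic
(Smoluchowski-derived) creation law

    dN/dt = α e^(V/U_ep)² (1 − (N/N₀) e^(−q (V/U_ep)²)),

with α = 10⁹ m⁻²s⁻¹, U_ep = 170 mV, N₀ = 1.5×10⁹ m⁻², q = 2.46. At fixed V
this is linear in N with fixed point N_eq = N₀ e^(q(V/U_ep)²).

Pores carry a representative radius r per node (rather than K individual
pores), evolving down the gradient of the pore energy

    W(r) = −V² F_max (r − r_h ln(r + r_h + r_t)) + C (r*/r)⁴ + 2πγ r − π δ_eff r²,

i.e. dr/dt = −(D/kT) dW/dr. The published energy expression is typographically
garbled; the form above is the standard asymptotic-model energy whose negative
gradient reproduces the published, self-consistent radius ODE exactly (checked
to ~10⁻¹⁰ by central differences). Constants: F_max = 0.7×10⁻⁹ N/V²,
r_h = 0.97 nm, γ = 1.8×10⁻¹¹ J/m, D = 5×10⁻¹⁴ m²/s. Two constants the
parameter table omits are taken from the asymptotic-model literature and
recorded in the corrections ledger: r_t = 0.31 nm and the steric coefficient
C = 1.4×10⁻¹⁹ J (the printed steric term "4λr⁴(1/r)" is dimensionless-
inconsistent unless λ = C r*⁴; the steric term is configurable off).

The effective tension relaxes with the fractional pore area A = π r² N:

    δ_eff = 2σ′ − (2σ′ − σ₀)/(1 − A)²,   σ′ = 2×10⁻² J/m², σ₀ = 10⁻⁶ J/m².

**Resting radius.** With the steric term on, the radius ODE is *not*
stationary at the minimum hydrophilic radius r* = 0.8 nm: the steric force
4C/r* ≈ 7×10⁻¹⁰ N dominates the line tension 2πγ ≈ 1.1×10⁻¹⁰ N, and the
resting stationary radius (the energy-minimum radius) is 1.152 nm. Pores are
therefore initialized at that stationary radius — solved by root finding at
V = 0 with the self-consistent δ_eff — so the rest state is an exact fixed
point; r* remains the radius at which newly created pores enter (they are
merged into the representative radius area-weighted). With the steric term
off the rate is negative for all small r and the configured floor
(0.65 r* = 0.52 nm) acts as the rest radius.

**Pore current.** J_EP = N·i_pore with the per-pore current
i_pore = V_m / (R_interior + R_access), R_interior = d/(σ_p π r²),
R_access = 1/(2 σ̄ r) (σ̄ = mean of the adjacent bulk conductivities,
σ_p = 0.22 S/m); an ohmic-only variant (`pore_current_model: ohmic`) drops
the access term. Because i_pore is linear in V_m, J_EP enters the implicit
field solve as an areal conductance g_ep = N/(R_int + R_acc) — this is what
clamps the TMV near ~1 V once poration fires, and it is unconditionally
stable. The nuclear envelope uses the same pore model with its own σ, ε and
thickness; no envelope-specific electroporation constants are published, so
the outer-membrane constants are reused.

## Discretization

**Mesh.** Boundary-conforming Delaunay triangulation (scipy) with a
Lipschitz size field: `h_membrane` (default 0.4 µm) on both membrane
circles, `h_tip_frac`·(D/2) (default 0.35) at capsule caps, `h_far`
(default 8 µm) in the bulk, grading rate 0.5. Interior nodes come from a
graded quadtree with deterministic jitter; nodes that would invade the
diametral circle of any boundary segment are removed, which guarantees the
triangulation recovers every interface edge (verified explicitly, and the
build fails loudly if not). Triangles are tagged by centroid point-location;
membrane circles are then slit into coincident inner/outer node traces.
Meshes are pure functions of their inputs (the jitter stream is fixed), so
reruns are bit-identical.

**Time stepping.** Backward Euler (first order — verified by Richardson
self-convergence) on the bulk displacement and membrane charging terms, with
operator splitting per step: (a) implicit field + membrane-charging solve at
frozen pore state; (b) pore update at frozen V_m. The creation ODE uses its
exact exponential update, evaluated in the cancellation-safe form
N e⁻ᶻ + a·dt·φ(z), φ(z) = (1−e⁻ᶻ)/z — the naive fixed-point form loses the
entire density increment to floating-point rounding at high V, where the
relaxation rate underflows. The radius ODE is sub-stepped explicitly with a
5% relative-change bound. The global step tracks the pulse (0.1 ns in the
ramps, 1 ns elsewhere) and a step is rejected and halved when any node's
|ΔV_m| exceeds 0.1 V or |ΔA| exceeds 0.01 — the creation law is stiff in V_m
near threshold, and without rejection a single 0.1 ns step can overshoot N
by orders of magnitude while V_m crosses 1 V.

**Guards.** |V_m| is capped at 2 V inside the e^(V/U)² exponentials with a
logged warning (the clamp physically keeps |V_m| near 1 V; the guard exists
for robustness, and the standard run never exceeds ~1.05 V). N ≥ 0,
r ≥ 0.65 r*, A < 1 are enforced as floors/caps.

## Synthetic scenes

The CNT capsules (2D stadium cross-sections) are placed by rejection
sampling: centers area-uniform in an annulus 1–15 µm outside the cell
(the study discusses CNTs "near the cells"; configurable), orientation
uniform, tip-to-tip length uniform in [0.5, 2] µm and diameter uniform in
[20, 100] nm (the study gives no ranges; these bracket its 10 nm × 1 µm
worked example's aspect ratio from below, aspect 5–100, and keep the 2D
mesh tractable), minimum clearance 100 nm to every other object, 10⁴
attempts per capsule before a packing error. n = 5 capsules by default (the
study's estimate for its CNT concentration). Identical seeds reproduce
identical scenes; capsule center angles are chi-square-uniform across seeds.

What the generator does not emulate: CNT agglomeration, membrane adhesion or
uptake, 3D orientation out of the plane, and any distribution of CNT sizes
beyond uniform ranges. Passing tests therefore certify the solver and the
pore model under the stated geometry, not the statistics of real CNT
suspensions.

## Dimensionality, and why the published maxima are not reproduced

The published simulation is described by a square domain drawn in a plane,
and this package commits to a 2D planar model throughout. Two consequences,
both quantified by this package's own diagnostics rather than hidden:

1. Around a porated cell the 2D bulk and pole fields exceed their 3D
   counterparts by the cylinder-vs-sphere factor
   (2σ_e/(σ_e+σ_i)) / (3σ_e/(2σ_e+σ_i)) ≈ 1.18–1.24. The solved exterior
   maximum sits on the outer membrane at 9.3 kV/cm ≈ 1.24 × the published
   7.5 kV/cm.
2. A 2D conducting stadium concentrates field like the thickened strip,
   E_tip/E₀ ~ O(√(L/D)) — solved 12.6× at L/D = 100 — whereas 3D needle-like
   conductors reach 10²–10³. The published worked example (10 kV/m →
   10⁴ kV/m) implies an effective β ≈ 10 in the field-emission relation
   E_tip/E₀ = β L/D; β defaults to 1 here and the relation is exposed as an
   analytic diagnostic, with the monotone-in-aspect-ratio trend verified
   against the solver.

Additionally, a mesh-converged per-element maximum resolves a genuine
feature of the model that a coarse mesh cannot: once the nuclear envelope
porates, the conductive nucleoplasm (σ = 1.35 S/m vs 0.3 S/m cytoplasm)
concentrates the cytoplasm-side field at the envelope poles by
2σ_np/(σ_np+σ_c) ≈ 1.64× the bulk, giving an intracellular maximum of
~15 kV/cm at the plateau. The published intracellular values (~7 kV/cm) are
readings from area-ratio distributions and field maps of a model meshed with
~1.4×10³ elements in total, which averages this sub-µm² hotspot away. The
acceptance checks report the converged per-element maxima and are therefore
expected to sit above the printed values; the comparison script reports both
honestly.

Within-model comparisons — with vs without CNTs on matched meshes — are
unaffected by these offsets and reproduce the study's qualitative findings:
CNTs raise the local field maximum severalfold, and increase pore density,
electroporated area, and permeabilized flux on both membranes.

## Problem sizes and run times

Default analyses use: CNT-free reference at h_membrane = 0.2 µm
(~2×10⁴ triangles; plateau maxima change <2% under h → h/2, checked at
0.4 → 0.2 µm), CNT ensembles at h_membrane = 1 µm with per-capsule tip
refinement (~10⁴ triangles per seed, 20 seeds), and full-pulse runs of
~450–500 accepted implicit steps. Oracle tests use coarser meshes (quoted in
the test fixtures). A full CNT-free pulse takes seconds to tens of seconds
on one CPU at these resolutions; the 20-seed ensemble a few minutes.

## Known limitations

- 2D planar geometry only (see above); no axisymmetric or 3D solve.
- One representative pore radius per membrane node; no per-pore population,
  coalescence, or stochastic (Brownian) pore dynamics.
- Fixed temperature; no Joule heating, electrode electrochemistry, or ion
  transport beyond the flux proxy (time-integrated electroporated area).
- The electroporated-area contour integral in 2D has units of area per unit
  out-of-plane depth; it is reported as such (µm²/µm) and compared only
  within-model.
- Plate electrodes are ideal Dirichlet surfaces spanning the domain sides.
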