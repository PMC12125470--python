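# Methods

`nosegc` is a reduced-order model of odorant and aerosol transport in rodent
noses. Instead of an image-based 3D airway, it works on a *synthetic
channel-network nose*: a directed acyclic graph of straight circular and
slot (parallel-plate) channels whose topology mimics the two inspiratory
flow regimes of macrosmatic mammals — a ventral respiratory route past the
maxilloturbinates, and a dorsal-medial (DM) stream feeding a bank of
parallel coiled olfactory channels in the ethmoid recess. Every analysis in
the package (flow screening, odorant uptake, gas-chromatograph efficiency,
particle deposition) runs on this network.

## The synthetic nose

Topology (fixed): naris → vestibule → {ventral slot, DM feed};
DM feed → Np parallel olfactory columns → collector; {ventral slot,
collector} → nasopharynx.

Species presets (frozen once chosen; all network-level numerics are
stand-ins, not measured anatomy):

| parameter | mouse | rat | note |
|---|---|---|---|
| parallel olfactory columns Np | 6 | 30 | rat ethmoid recess is the more convoluted |
| column radius r | 200 µm | 300 µm | mouse pathways narrower |
| column path length Lc | 7 mm | 12 mm | |
| DM flow fraction | 0.1 | 0.1 | the controlling unknown; exposed in config |
| surface-area / volume targets | 2.90 cm² / 0.0291 mL | 14 cm² / 0.26 mL | mouse: micro-CT morphometry; rat: literature-order stand-in |
| restful flow rate Q | 25 mL/min | 200 mL/min | medians of the physiological ranges 10–35 and 100–450 mL/min |
| breathing frequency | 4 Hz | 2 Hz | |

The ventral slot's half-gap and width are solved in closed form so the
whole network hits the surface-area and volume targets exactly;
`calibrate_to_morphometry` then applies the two-parameter similarity family
(transverse scale t, axial scale a; wall area ∝ t·a, volume ∝ t²·a), which
solves any positive (area, volume) pair exactly. Column radii carry a ±1%
seeded jitter so that "identical spec + seed ⇒ identical network" is a
meaningful contract.

With these presets the solved olfactory-column velocities are ≈0.054–0.056
m/s (mouse) and ≈0.038–0.040 m/s (rat), inside the physiological bands
0.03–0.14 and 0.02–0.12 m/s. The preset values were fixed from the
closed-form Golay algebra below *before* the acceptance suite was run, and
are not revisited.

What the generator deliberately does **not** emulate: scrolled 3D
turbinate geometry, secondary recirculation inside the ethmoid recess
(replaced by a statistic on synthetic swirl fields), septal asymmetry,
expiration, and compliant walls. Tests passing on this network therefore
validate the transport formulations and their couplings, not anatomical
fidelity.

## Network flow

Steady, incompressible, laminar, quasi-steady flow: each segment is a
Hagen–Poiseuille resistor (circular: 8µL/πr⁴; slot: 12µL/wh³), solved as a
nodal-pressure Kirchhoff problem. The DM/ventral split is *imposed* at the
configured fraction — the real split is set by geometry we do not model —
by removing the DM-feed edge from the conductance Laplacian and injecting
±f·Q at its endpoints; inside the olfactory bank flow splits by resistance.
Air: ρ = 1.2 kg/m³, ν = 1.5×10⁻⁵ m²/s.

Screening numbers per segment: Re = U·d_h/ν (laminar if < 2300, strict),
Womersley W0 = (d_h/2)·√(2πf/ν) (< 4) and Strouhal S = f·L/U (< 1) for
quasi-steadiness, with the segment length as the default stroke length.

Secondary-flow strength SS = √(v²+w²)/√(u²+v²+w²) is computed pointwise on
gridded velocity fields; because the package has no 3D solver, it is
exercised on synthetic planes (uniform axial flow + solid-body in-plane
rotation) whose swirl ratio sets SS analytically.

## Odorant uptake

Transport in a channel is the Graetz problem with a Robin wall condition:
fully developed laminar profile, axial advection, transverse diffusion, and
finite mucosal uptake

    D_a ∂C/∂n = −k_w C,   k_w = D_m / (β·d),

where β is the air–mucus partition coefficient (air ÷ mucus; small β =
highly soluble) and d the mucus thickness (default 10 µm, an
order-of-magnitude rodent value). The equivalent dimensionless wall
parameter K = d_in·D_m/(D_a·β·d) is reported for comparability, but the
solver uses the dimensional k_w to avoid any ambiguity about the reference
length. Mucus-phase diffusivities default to the Wilke–Chang correlation
(water solvent, φ = 2.6, 310 K); air-phase diffusivities come from the
odorant table or a Fuller-type gas estimate — Wilke–Chang is a liquid-phase
correlation and is not applied to air.

Numerics: conservative finite-volume discretization across the half-gap /
radius (default 64 cells), backward-Euler marching along the axis (default
200 steps), wall flux through a half-cell-diffusion + film series
conductance. The scheme closes the flux budget (inlet = outlet + absorbed)
to machine precision by construction and is grid-converged to <1% against
doubled resolution; an independent explicit finite-difference solve agrees
on absorbed fractions to <1%. Axial diffusion is neglected (axial Péclet ≫ 1
for every preset).

Across the network, segments are processed in topological order; junctions
mix mixed-mean concentrations perfectly and split flux in proportion to
flow; each segment restarts with a flat inlet profile (the network has no
transverse structure across junctions). Consequence: serial segments
compose as 1−(1−a₁)(1−a₂).

The solubility sweep varies β from 10⁻¹⁰ to 1. Very soluble odorants are
scrubbed in the anterior respiratory path before reaching the DM feed;
insoluble ones traverse unabsorbed — so the olfactory deposition fraction
is unimodal in log β with an interior maximum, and the rat curve lies at or
above the mouse curve across β = 10⁻⁸…10⁻² (the rat's higher flow scrubs
relatively less anteriorly and its olfactory bank carries more area).

## Gas-chromatograph efficiency

Each olfactory flow path is treated as an open-tubular GC column with the
mucus as stationary phase. Plate height follows the two-term Golay form

    H(u) = B/u + C_tot·u,  B = 2D_g,
    C_tot = f_g(k)·r²/D_g [+ f_s(k)·d_f²/D_s],
    f_g(k) = (1+6k+11k²)/(24(1+k)²),  f_s(k) = 2k/(3(1+k)²),

with retention factor k = 2d_f/(β·r) from thin-film geometry, and
N = Lc/H. Optima are closed-form: u_opt = √(B/C_tot), H_min = 2√(B·C_tot).

Two deliberate choices:

- **Stationary-film term off by default.** With a full-thickness 10 µm
  film and liquid diffusivity ~10⁻⁹ m²/s the f_s term dominates C_tot and
  pushes u_opt below every physiological operating velocity, which
  contradicts the operating regime this analysis is meant to probe; the
  effective film participating in rapid exchange is poorly constrained. The
  term is implemented and one flag away (`film_term=True`).
- **Comparison odorant β = 0.01** (low-intermediate solubility, k ≈ 5–10
  in the columns), a regime where retention is substantial but the mobile
  term still controls the optimum.

The null architecture is the amphibian-like *elongated tube*: the parallel
olfactory bank replaced by one circular duct of equal airspace volume fed by
the same DM flow. Default packing keeps the column path length (so
r_tube = √Np·r); by continuity the tube then runs at the same velocity as a
single column but its optimum velocity is √Np-fold lower, so the tube
operates *above* its optimum while the parallel columns operate *below*
theirs, and N_peak(parallel)/N_peak(tube) = √Np for identical columns. An
alternative `dm_feed` packing (tube continues the DM duct cross-section,
becoming long and narrow) is available.

Velocity robustness is the band [u₁,u₂] with N(u) ≥ fraction·N_peak;
u₁·u₂ = u_opt² exactly. A known degeneracy: for *any* two-term H the
log-width log(u₂/u₁) at a fixed fraction is architecture-independent, so
under this model the mouse's robustness equals the rat's rather than
exceeding it; the comparison is asserted as ≥.

## Particle deposition

The particle force balance is du_p/dt = 18µ/(ρ_p d_p²)·(C_D Re_p/24)(u_f−u_p)
+ g(ρ_p−ρ_f)/ρ_p + F_s with Schiller–Naumann drag (1 + 0.15·Re_p^0.687,
clamped above Re_p = 1000 with a warning) and optional generalized Saffman
lift (constant 2.594, from the local velocity-gradient tensor; off by
default in network tracking, available in single-channel validation). The
reference integrator is semi-implicit — exact exponential update of the
linear drag — hence unconditionally stable; an explicit mode exists and
refuses dt > 0.1τ.

Network tracking exploits that inside a straight segment the
small-relaxation dynamics (terminal settling v_t across, local fluid speed
along) integrates in closed form: y(t) = y₀ − v_t·t and z(t) is a cubic,
so deposit-vs-escape is decided exactly (monotone cubic root by bisection)
and no particle can be "lost" to step caps. Gravity is transverse to every
axis (horizontal-channel assumption; slot plates horizontal, which
maximizes sedimentation capture). Inertial impaction enters through
idealized circular-arc bends at segment entries (vestibule 60°, DM feed and
collector 90°, columns 45°): the outward drift over a bend is the exact
linear-drag solution of the centrifugal balance,
δ = (U²/R_b)·τ·(t_b − τ(1−e^(−t_b/τ))). Junctions choose a downstream
branch with flow-proportional probability and re-sample the transverse
position uniformly (the perfect-mixing analogue of the odorant model); a
fixed seed reproduces every record bit-for-bit.

Deposition efficiency is reported against the impaction factor
IF = ρ·d_p²·Q in g/cm³·µm²·(cm³/s) units. On the mouse preset at 25 mL/min
with 2000 unit-density particles per size across 1.5–43 µm, the curve is a
monotone sigmoid in IF reaching 100% around IF ≈ 60–90 (15 µm sits at
IF ≈ 94). Known regime limit: at fixed d_p ≲ 15 µm, efficiency can
*decrease* with flow rate because sedimentation (∝ 1/Q) outweighs the
impaction gain; flow-rate monotonicity holds in the impaction-dominated
regime (≳ 20 µm here) and is tested there. Brownian diffusion, turbulent
dispersion, rebound and hygroscopic growth are out of scope.

## Problem sizes and defaults

Default study protocol: 21 β values (10⁻¹⁰…1), uptake grids 200×64 per
segment, 8 particle sizes × 2000 particles, 200-point plate curves. A full
two-species study completes in well under a minute on one core; the
protocol scales to 8000 particles per size via `--full-paper-protocol`.

## Degenerate inputs and tie-breaks

Zero-velocity points are excluded from SS means (an all-still region yields
an explicit null with a warning); S is undefined (flagged, not crashed)
when U = 0 with f > 0; dimensionless thresholds use strict inequalities;
β → ∞ gives k_w = 0 (impermeable wall) and k → 0 (no retention); odorant
table rows violating invariants are rejected row-wise with a report while
the rest load.
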