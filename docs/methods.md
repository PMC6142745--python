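# Methods

`cardiomp` is a desk-scale, reduced-order model of coupled cardiac
electromechanics and hemodynamics with a continuous-flow left-ventricular
assist device (LVAD). It keeps the causal chain of the full
fluid–electromechanics problem — Purkinje conduction → myocardial activation
→ active stress → chamber pressure → closed-loop circulation → pump — while
replacing the 3D finite-element wall and the resolved blood flow with
lumped, material-point and 1D/2D surrogates. This note records the model,
its assumptions, the calibrations that fix its unit-carrying constants, the
numerical choices, and what the reduction can and cannot show.

## 1. Membrane model and excitation–contraction coupling

Both myocardium and Purkinje fibers use a two-variable cubic
excitation/recovery model of the Aliev–Panfilov family, mapped to physical
units by a linear voltage map `V = B + A·u` and one global rate scale:

    Cm dV/dt = −i_ion + i_stim
    i_ion    = k1 k2 (V−B)(u−a)(u−1) + k2 R (V−B),   u = (V−B)/A
    dR/dt    = (ε0 + μ1 R/(u+μ2)) · (−R − k1 u (u−a−1))

- `A = 100 mV`, `B = −80 mV` (typical amplitude and resting potential; the
  model family is dimensionless, so these only set the voltage axis).
- The cubic's last factor is `(u−1)`, not `(V−1)`: a membrane potential in
  mV cannot be compared with a pure number, and only the dimensionless
  reading recovers the standard cubic. The recovery-rate bracket is the
  standard `ε0 + μ1 R/(u+μ2)` form; the flattened literal reading
  `ε0 + μ1·R·u + μ2` is selectable (`literal_recovery=True`) for
  sensitivity checks and changes no shipped result.
- Dimensionless seed constants: `k1 = 8, ε0 = 0.002, μ1 = 0.2, μ2 = 0.3`
  (the published constants of this model family). The calibration
  (`calibrate_cell`) fits the single global time scale `k2` (and scales
  `ε0, μ1` with it) by scalar root-finding so that the epicardial cell
  (`a = 0.12`) paced at 60 bpm with 2-ms pulses shows APD90 = 266 ms on the
  third beat. The anchor protocol (beat 3 of a 60-bpm train from rest)
  matches how APD90 is measured everywhere else in the package, so
  restitution effects are handled consistently. Shipped value:
  `k2 ≈ 0.090 /ms`.
- The excitation threshold varies transmurally and linearly:
  `a = 0.07` (endocardium) → `a = 0.12` (epicardium).

**Transmural APD gradient: a known structural limitation.** In this model
family the space-clamped APD90 scales almost exactly like `1/a` — the
plateau recovery source is `k1·u·(u−a−1) ≈ k1·a` near `u = 1` — and this
ratio (0.12/0.07 ≈ 1.71) is insensitive to `ε0, μ1, μ2, k1`, to the
literal-vs-standard recovery bracket, and to pacing. A clamped endocardial
cell calibrated on the 266-ms epicardial anchor therefore shows
APD90 ≈ 450 ms, while coupled 3D tissue — where electrotonic current flattens
repolarization gradients — shows a much shallower endo/epi gradient
(≈ 324/266 ms). The package reports the clamped value honestly; the
*ordering* (endocardium repolarizes last, opposite to activation) is a
robust prediction and is verified both space-clamped and in the coupled
transmural wedge.

Active stress follows the membrane potential through a first-order ODE with
a Gompertz delay switch:

    dTa/dt = ε(V) (k_Ta max(u,0) − Ta)
    ε(V)   = ε0act + (ε∞act − ε0act) exp(−exp(−ξ (V − Vthr)))

with `k_Ta = 60 kPa`, `ε0act = 0.01 /ms` (slow resting decay),
`ε∞act = 0.1 /ms` (fast excited attack), `ξ = 0.1 /mV`, `Vthr = 0 mV`.
The source is clamped at `max(u, 0)` so sub-resting voltage excursions
never drive tension negative. These choices give a tension transient that
peaks near end-plateau and decays below 1% of peak well before the next
beat at 60 bpm. Only the myocardial potential generates tension; the
Purkinje system is electrically coupled but mechanically silent.

## 2. Purkinje tree and fiber architecture

The conduction tree is generated, not meshed, on a truncated-ellipsoid
chamber surface built from the published chamber dimensions (apicobasal
extent 3.6 cm, equatorial radius 2.4 cm). Two bundle branches enter at the
septal base; the left splits into three minor bundles (150°/180°/210°), the
right into anterior and posterior minors (±45° from the septal entry).
Minors fan from the septal entry to their bundle angle over the first
centimetre of descent, then run apicobasally, emitting two circumferential
branches (arcs of 36° each) every 1 cm between base and apex whose
endpoints are the Purkinje–myocyte junctions (PMJs): 30 PMJs in the default
tree. Fiber radius tapers linearly in path length from 500 μm at the bundle
origin to exactly 50 μm at every PMJ; a trunk node shared by several leaves
takes the taper of its deepest descendant, which keeps the radius
non-increasing along every path. Bundle angles, spans, spacing and radii
are all generator parameters (the source figure gives the layout only
graphically).

Fiber architecture on tissue grids is rule-based: helix angle +60° at the
endocardium rotating linearly to −60° at the epicardium, sheets transmural,
normals completing the triad; an optional isotropic mask reproduces the
isotropic-apex assumption. The conductivity tensor is assembled as
`σ = σf F̂⊗F̂ + σs Ŝ⊗Ŝ + σn N̂⊗N̂` with the 4:2:1 anisotropy ratio
(`σs = σf/2`, `σn = σf/4`); isotropic cells get `σf·I`. 2D grids carry the
reduced in-plane triad.

## 3. Tissue solvers

**Purkinje cable.** The varying-radius cable equation
`r(Cm ∂V/∂t + i_ion) = ∂x(r²/(2ρi) ∂x V)` is discretized with
vertex-centered finite volumes on the tree graph: per-node mass =
trapezoidal integral of `r` over the half-edges, face conductance
`r_face²/(2ρi Δx)` with `r_face` the harmonic mean of the node radii.
Branch nodes satisfy discrete Kirchhoff balance by construction; sealed
ends are zero-flux (operator rows sum to zero, so diffusion conserves the
mass-weighted mean exactly). The root stimulus covers ~2 liminal lengths
(`ℓ = sqrt(D/(k1 k2))`, ≈ 0.5 cm at the 500-μm trunk) because a point
source cannot ignite a well-coupled cable. A run in which any node fails to
activate raises instead of reporting a bogus whole-tree time.

**Monodomain.** `βsv(Cm ∂V/∂t + i_ion + i_pr) = ∇X·(σ∇X V)` is solved
cell-centered on regular material-frame grids with face-averaged tensors.
Face fluxes carry the full tensor — normal gradient plus face-averaged
tangential gradients — so conservation holds exactly (each interior flux
enters two cells with opposite sign) and plane waves along rotated fiber
fields propagate at the axis-aligned speed (verified to a few percent).
Propagation in the material frame reflects the gap-junction argument that
the conduction substrate is unaffected by deformation; the grid is static
here, but the API takes material coordinates so a deforming-grid extension
cannot silently change the contract. `βsv = 1000 /cm`, `Cm = 1 μF/cm²`.

**PMJ coupling** is one-way: `i_pr = R_pmj (Vm − Vp)` is added only at
cells mapped from PMJ leaves (nearest cell, ties to the lowest index), with
`Vp` interpolated from a completed Purkinje solution and never written.
`R_pmj = 0.05 mS/cm²` is a tuned default: large enough that a Purkinje AP
reliably triggers the mapped cell, small enough that sub-threshold
differences do not.

Both solvers use explicit method-of-lines stepping with a
stability-bounded step (`dt ≲ 0.35 h²/(2·ndim·Dmax)` and a reaction-rate
cap) and track activation time as the time of maximum dV/dt at the solver
step, not the 2-ms resampled output. Divergence (|V| beyond physical
bounds) aborts with diagnostics.

**Conduction calibrations.**

- `σf` is set by scalar iteration (exact `CV ∝ √σ` scaling plus
  verification) so planar fiber-direction CV = 0.06 cm/ms, a typical human
  ventricular value; shipped `σf ≈ 17.5 mS/cm` (the monodomain diffusivity
  `σf/(βsv Cm)` is what matters physically).
- The Purkinje cell variant keeps the endocardial threshold
  (`a = 0.07`), fits `k2` so the space-clamped upstroke is 2× the
  myocardial one, and fits the axial resistivity `ρi` so the cable CV at
  the tree's mean radius (275 μm) is 3× the myocardial CV, using the exact
  `CV ∝ 1/√ρi` scaling (shipped `ρi ≈ 0.21 kΩ·cm`, within the measured
  physiological range). The two upstroke readings — space-clamped and
  traveling-wave — agree within 5% because the wave profile of the cubic
  front is nearly threshold-independent; the stimulus window is excluded
  from upstroke measurements since the phenomenological intrinsic upstroke
  (~8.5 mV/ms) is comparable to the injection rate. Purkinje recovery
  rates are scaled by 0.75 so the Purkinje APD (≈ 580 ms) exceeds the
  myocardial APD, preventing retrograde re-excitation in principle (actual
  retrograde coupling is not modeled).
- Measured CVs use a cable whose length and grid step scale with the
  diffusion–reaction length `ℓ`, with the measurement window at 40–85% of
  the cable (clear of the ignition transient) and a linear fit of
  activation time against distance (Theil–Sen fallback when activation is
  non-monotone).

With these calibrations the whole default tree activates in ≈ 32 ms after
a 2-ms root stimulus — close to the ~34 ms of the full 3D network it
idealizes; the timing is an emergent property of path lengths, taper and
the √r CV law, not a fitted quantity.

## 4. Material-point mechanics

The myocardium is transverse-isotropic Holzapfel–Ogden with a volumetric
penalty:

    ψ = a_i/(2b_i) exp(b_i(Ī1−3))
      + a_f/(2b_f)[exp(b_f(I4f−1)²) − 1]   (only for I4f > 1)
      + κ(J−1)(ln J)²

- `Ī1` is computed from the isochoric `C` (`J^(−2/3)`-scaled) so the
  deviatoric term pairs correctly with the separate volumetric penalty.
- The fiber term switches off for `I4f < 1` (compressed fibers carry no
  passive load). `I4f` is nonnegative by construction, so a switch at zero
  would never act; the tension-only convention implements the stated
  physics. Energy and stress are continuous at the switch.
- The `−1` inside the fiber bracket is a constant offset chosen so the
  fiber energy vanishes at the reference state; it does not affect stress.
- Passive PK2 stress is the analytic `S = 2 ∂ψ/∂C` (verified against
  central finite differences of ψ to 1e-6 relative and against a symbolic
  evaluation for uniaxial fiber stretch). Active stress is added along the
  material triad with fractions (1, 0.4, 0.4); isotropic (apical) points
  get `Ta·I` and a fiber-free ψ.
- Default moduli (`a_i = 2.28 kPa, b_i = 9.726, a_f = 1.685 kPa,
  b_f = 15.779, κ = 350 kPa`) follow transverse-isotropic fits to
  myocardial biaxial data from the constitutive-modeling literature; all
  config-exposed.

Stress–strain loop analytics (shoelace signed area on (E, S) pairs, a
regional-work proxy) and the cannula contact penalty
(`P = k_contact(G − G_lim)` above the gap-reciprocal threshold
`G_lim = 150 m⁻¹`, `k_contact = 10³`) complete the module. The contact
operation consumes a supplied gap reciprocal — the wall-distance PDE of the
full model is out of scope — and its published unit pairing is dimensionally
irregular; the output is declared as a boundary load in model units.

## 5. Closed-loop circulation and the elastance surrogate

The circuit is a closed-loop Windkessel: per side an arterial and a venous
RC compartment with unstressed volumes, passive atrial compliances, and
diode-resistor valves (`Q = ΔP/R` when forward, else 0; optional softplus
smoothing). The finite-element ventricle is replaced by an elastance
surrogate per chamber:

    P(V) = c1(exp(c2(V−V0)) − 1) + k_act · ⟨Ta⟩ · (V−V0)

The passive exponential is the EDPVR; the active term is a time-varying
elastance proportional to the mean active stress, giving a linear ESPVR
through `V0` — which also produces the negative chamber pressures seen
during suction. `⟨Ta⟩` is the cell model's own tension in 0D mode or the
spatial-mean tension of a tissue run in staged mode.

Initialization follows the pre-inflation protocol: each chamber fills
toward its end-diastolic target under `dV/dt = −k_flow(V − V∞)` with the
Windkessel decoupled. `k_flow` is treated as a pure rate constant
(200 /ms, the published 200,000 s⁻¹), giving a sub-millisecond inflation time
constant; the integrator is verified against the closed-form exponential.
Initial Windkessel volumes are the stored ends of a 10-cycle warm-up run,
not hand-tuned numbers.

**Calibration.** The chamber gains and circuit constants are fitted once by
deterministic least squares so the healthy 3-cycle run lands on the published
healthy hemodynamics (LV 148.4/71.0 ml, RV 144.7/67.1 ml, aortic
126.7/75.2 mmHg, pulmonary 34.5/13.4 mmHg); the fitting script is shipped
(`scripts/calibrate_defaults.py`) and its products versioned
(`src/cardiomp/data/default_params.yaml`). Heart failure is a parameter
transform: LV `k_Ta` halved, heart rate 60 → 80 bpm, LV dilation (V0
shifted, passive slope relaxed) plus venous volume expansion fitted to the
published failing state (EDV 299 ml, EF 16.5%, peak pressure ≈ 89 mmHg); the
RV is untouched.

**Integration.** The coupled system (two cells + eight volumes + optionally
three pump states) is integrated monolithically with fixed-step RK4
(default dt = 0.05 ms — the fastest rates are ~1/ms membrane kinetics and
the ~1.2 krad/s pump electrical mode, both well resolved), output resampled
on a fixed 2-ms grid. Fixed-step RK4 makes runs byte-reproducible and
handles the diode kinks without event logic. Total blood volume is
conserved to ~1e-14 relative per run (the RHS moves volume only between
compartments).

## 6. Pump model and controller

The LVAD is the three-state rotary pump model described in the module
docstring: winding equation, torque transfer (`Te = 3ke·I` against
impeller inertia and a hydraulic load torque polynomial), and an inlet-flow
equation driven by pump head minus the LV–aorta pressure difference with
flow-proportional inlet/outlet losses. Conventions:

- The winding equation keeps the published sign of the back-EMF term (it
  enters on the drive side), because that is the convention under which
  the steady state at zero controller voltage is `I = 2ke·ω/R` — the
  algebraic identity the verification suite checks. The conventional
  opposing sign is a config flag. Stability is provided by the controller:
  `V = k_pump(ω − ω_set)` with `k_pump = −20 V·s/rad`, so a speed deficit
  raises drive and the closed electrical loop is a damped ~1.2 krad/s
  spiral. Speed regulation error stays well below 1%.
- The published loss `(Rin+Rout)Q = kr·Q²` is implemented as `kr·|Q|·Q` so
  the turbulent loss always opposes flow (identical for forward flow;
  backflow through the pump remains possible).
- The torque factor 3ke (torque) vs 2ke (back-EMF) is kept as published;
  both are config-exposed.
- Hydraulic and torque coefficients are derived from the published operating
  points (2.2 L/min baseline and 6.2 L/min peak at 2,100 RPM against the
  supported pressure envelope; 7 L/min baseline at 3,150 RPM) by
  steady-state algebra and a final least-squares pass through the coupled
  model; the cited source pump's own coefficient table was not available.
  Motor-side constants (`ke = 0.025 V·s/rad`, `R = 1 Ω`, `L = 10 mH`,
  `J = 1e-4 kg·m²`) are typical small-BLDC values; the resulting current
  waveform is physiologically shaped (systolic bump) but its absolute
  amplitude is indicative only.
- A unit conversion (L/min ↔ ml/s) happens exactly once, at the coupling
  boundary where the pump drains the LV chamber and feeds the systemic
  arterial compartment. The cannula-side pressure is the LV chamber
  pressure (single-pressure surrogate; the intraventricular gradient to
  the cannula tip is a 3D-flow quantity outside this model).

The speed set-point is piecewise linear in time; the published ramp protocol
(hold 2,100 RPM, half a cycle, 300-ms linear ramp to 150% = 3,150 RPM,
hold) is a one-line schedule. Suction analytics report per-cycle EDV,
minimum LV pressure, pump-flow pulsatility and the fraction of the cycle at
negative LV pressure, and flag suction when EDV declines ≥ 10% per cycle
for two consecutive cycles with negative minimum LV pressure (thresholds
config-exposed).

## 7. Protocols, staged mode, determinism

- `run_standard`: inflate to EDV, couple the loop, 3 cycles at 60 bpm,
  metrics (EF, SV, pressure envelopes, SV balance, volume drift).
- `run_lvad_suite`: the four-stage pump protocol at 80 bpm (failing heart
  alone; pump at 2,100 RPM; half-cycle + 300-ms ramp to 3,150 RPM, 3
  cycles; mitral stenosis ×25 at 3,150 RPM, 3 cycles), with per-stage
  cycle metrics, pump waveform statistics and suction reports, each stage
  continuing from the previous stage's final state.
- Staged mode replaces the 0D cell tension with the spatial-mean tension of
  a Purkinje-driven transmural wedge (2D monodomain sheet with the
  a-gradient and PMJ sources placed by apicobasal position); one paced
  period is computed and extended periodically. This is an explicit one-way
  reduction of the full-scale monolithic coupling: activation dispersion
  shapes ⟨Ta⟩(t), but mechanics does not feed back into electrophysiology.
- Determinism: fixed-step solvers, no randomness anywhere on the
  simulation path; re-running a configuration byte-reproduces the CSVs
  (checksums in the run manifest). Every numeric constant a run uses
  appears in the resolved config snapshot stored with the run record.

## 8. Problem sizes

Shipped problem sizes are chosen so the full verification suite runs on a
laptop-class single core: tree of ~1,200 cable nodes (ds = 0.05 cm),
wedge sheets of order 10³ cells (h = 0.025–0.05 cm, chosen so halving h
moves CV by < 5%), cable CV measurements on 2–6 cm cables, and 0D
protocols of 3–13 cycles at dt = 0.05 ms. The convergence metrics (Cq,
%RMS) used to verify the full-scale model are shipped as utilities and
exercised on these reduced problems.

## 9. What passing here does and does not show

The synthetic study conditions emulate: the published healthy and failing
hemodynamic operating points, the published conduction/upstroke ratios and
radii, the published pump protocol and operating points, and the qualitative
physiology (isovolumic phases and their loss, repolarization ordering,
suction under inflow starvation). They do not emulate: 3D wall mechanics
and torsion, intraventricular pressure gradients and vortices, atrial
contraction, valve structure, the Frank–Starling mechanism,
stretch-activated feedback, or retrograde myocardium→Purkinje conduction —
all are out of scope, and several are known limitations of the full-scale
model as well. Quantities that depend on resolved 3D fields (activation
maps of the biventricular geometry, kinetic energy, vorticity) are
represented only by direction-level behavior here, and numeric agreement on
the reduced quantities does not imply the reduction reproduces those
fields.
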