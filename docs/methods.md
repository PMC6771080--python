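# Methods

`mfhplan` simulates magnetic fluid hyperthermia (MFH) of a breast tumour at
desk scale: nanoparticle heat generation in the linear-response regime, the
non-specific eddy-current heating that accompanies any large alternating-field
applicator, and the resulting tissue temperatures and thermal dose on a voxel
phantom. This note records the models, the numerical choices, and what the
synthetic phantom does and does not capture.

## Nanoparticle heating (linear response theory)

Single-domain superparamagnetic particles in an alternating field
H(t) = Hmax·cos(ωt) dissipate

SLP = π·μ0·χ″·Hmax²·f / ρ_p    (W per kg of magnetic material),

with the out-of-phase susceptibility in Debye form
χ″ = χ0·ωτ/(1+(ωτ)²) and the equilibrium susceptibility per unit particle
volume χ0 = μ0·Ms²·V_M/(3·kB·T). The package averages the single-size
expression over a log-normal core-diameter distribution (median 15.2 nm,
shape 0.19 by default), volume-weighted; number weighting and a
Langevin-chord ("saturating") χ0 are available as conventions on `MNPSuite`
because the literature is not unanimous and the choice matters at
ξ = μ0·m·Hmax/(kB·T) ≈ 3 where these particles operate.

The relaxation time is the field-dependent parallel combination of the two
physical channels:

- Néel (internal moment reversal): the two-well escape rate
  1/τ_N = f0(1−h²)[(1+h)e^{−σ(1+h)²} + (1−h)e^{−σ(1−h)²}],
  σ = K·V_M/(kB·T), h = Hmax/Hk, Hk = 2K/(μ0·Ms). At h = 0 it reduces to the
  Néel–Arrhenius time e^σ/(2f0). The rate form is used because it is the only
  dimensionally consistent reading and has the correct Arrhenius limit.
- Brownian (body rotation in the carrier): τ_B = τ_B0/√(1+0.07ξ²),
  τ_B0 = 3ηV_H/(kB·T), hydrodynamic diameter = core + 2δ (δ = 2 nm default).

"Mobilised" particles (free in interstitial fluid) combine both channels,
1/τ = 1/τ_N + 1/τ_B; "immobilised" particles (bound to tissue) keep only the
Néel channel. The volumetric tumour heat source is P = SLP·c_ref·φ_r for a
ferrofluid of reference concentration c_ref (5 mg/mL default) diluted by the
relative concentration φ_r — exactly linear in φ_r by construction.

Default suite (the calorimetrically characterised magnetite ferrofluid):
K = 30 kJ/m³, Hk = 92 kA/m (hence Ms = 2K/(μ0·Hk) ≈ 519 kA/m — the table
quantity is read as the anisotropy field, the only reading consistent with a
10.3 kA/m applied amplitude), T = 298 K, η = 8.94×10⁻⁴ Pa·s (water),
f0 = 10⁹ s⁻¹, ρ_p = 5180 kg/m³ (magnetite; the material density is not part
of the characterisation and is configurable).

A caveat this package makes explicit: with the water-carrier viscosity the
Néel/Brownian crossover sits near 13.7 nm, well below the volume-weighted
bulk of the 15.2 nm distribution, so the model's immobilised/mobilised power
ratio is ≈0.07–0.16 depending on convention — far below the ≈0.70 of the
reference power table. Reproducing 0.70 (and, simultaneously, the ≈243 kW/m³
mobilised power at φ_r = 1) requires an effective carrier viscosity 10–50×
water, i.e. interstitial-fluid/cytoplasm-like. The viscosity is a first-class
parameter of `MNPSuite` for exactly this reason; the package defaults stay at
the characterised water value and the reference power table is used directly
(as data) wherever tumour heating at the published power levels is needed.

Numerics: the size average is a trapezoid sum over log-diameter on ±5 shape
parameters, 512 nodes by default, refined by doubling until two levels agree
to 10⁻⁴ relative; non-convergence raises with diagnostics.

## Synthetic breast phantom

A parametric stand-in for an MRI-derived "heterogeneously dense" breast:

- isotropic voxel grid, default 96³ at 1.5 mm (14.4 cm crop), axis order
  (x, y, z), chest wall at z = 0, voxel-centre coordinates;
- a 5 mm subcutaneous fat layer, then a hemispherical breast of radius 50 mm;
- a closed skin shell (2 mm nominal, at least one voxel) obtained from the
  Euclidean distance to the body surface; closure is verified by flood fill;
- a muscle disc (default radius 50 mm, 12 mm thick) behind the breast — the
  pectoral layer; the rest of the chest slab is fat;
- glandular tissue as a smooth retroareolar fibroglandular core: large,
  deeply overlapping ellipsoidal blobs (semi-axes 15–25 mm) centred near the
  breast axis, morphologically smoothed (binary closing then opening,
  4.5 mm radius) and kept behind an 8 mm subcutaneous fat margin below the
  skin — real fibroglandular tissue does not touch the dermis, and
  voxel-scale necks or spurs on the gland–fat boundary would act as
  artificial eddy-current crowding sites that a body-fitted mesh does not
  have.  Blobs are added until the glandular fraction of interior breast
  tissue enters the configured band, 51–75 % by default.  Generation is
  deterministic in the seed; an unreachable band raises.
- a spherical tumour of configurable volume (2 mL default, radius 7.82 mm)
  relabelled from breast tissue; the tumour carries the muscle properties
  with perfusion replaced by the nonlinear model below.

Tissue properties (density, conductivity at 171 kHz, specific heat, thermal
conductivity, metabolic rate, perfusion coefficient) are the IT'IS-derived
table for skin, muscle, breast gland, fat and breast fat; the tumour row
copies muscle.

What the phantom does not capture: ductal/lobular gland microstructure (blobs
are bulkier and better-connected azimuthally than real fibroglandular
strands), anatomical asymmetry, and any registration to a real patient.
Consequences for interpretation are noted under "Applicator" below.

## Applicator and eddy currents

The applied field is the exact single-loop solution (complete elliptic
integrals) superposed over the turns; per-turn radii support flat spiral
(pancake) windings as well as solenoids. The phantom is assumed not to
perturb the field (non-magnetic, weakly conducting tissue at 171 kHz), and
the current is calibrated linearly so that |H| at the applicator centre
equals the prescribed amplitude (10.3 kA/m default).

Default geometry: a 17-turn regional solenoid, radius 110 mm and length
120 mm, axis through the breast, i.e. the whole chest crop sits inside a
near-uniform field. The choice is deliberate: with any close-fitting breast
coil, azimuthal current rings in the glandular tissue (σ = 0.54 S/m, 3.2×
skin) at a large fraction of the skin radius dominate the dissipation map,
which contradicts the clinically expected pattern of surface-dominated
non-specific heating. In a near-uniform regional field the lateral chest
skin at ~100 mm from the axis is the largest conducting loop (σρ² argument)
and — together with the smooth, margin-respecting glandular core described
above — robustly hosts the maximum. Verified across ten generator seeds;
the known failure mode is convex-corner current crowding on a voxelised
glandular boundary, which the morphological smoothing is there to suppress.

The eddy problem is solved in the magneto-quasi-static scalar-potential
formulation: ∇·(σ(∇u + jωA)) = 0 with zero normal current on the conductor
surface. Writing u = jωv makes the system real, symmetric positive
semi-definite; it is discretised with a 7-point finite-volume stencil
(harmonic σ at faces, conductance σ_f·h) and solved by Jacobi-preconditioned
conjugate gradients to a 10⁻⁸ relative residual (configurable; failure raises
with the achieved residual). The right-hand side uses face-averaged normal
components of A, which makes the discrete compatibility condition exact; the
gauge is zero mean per connected conductive component. Currents are
J = −σ∇u − jσωA with central/one-sided differences for ∇u and the analytic
voxel-centre A; power is reported as the time average P = |J|²/(2σ) for
peak-amplitude phasors (a `peak` convention is provided). Hot spots are
ranked local maxima (3³ neighbourhood, plateau-deduplicated) outside excluded
labels — skin by default.

Validation: total dissipation in a homogeneous conducting sphere under a
uniform axial field matches πσω²B0²a⁵/15 within 5 % at 64³ (≈1 % measured),
with monotone grid-refinement convergence.

## Bioheat solver

Pennes' equation with metabolic, eddy and nanoparticle sources:

ρc ∂T/∂t = ∇·(κ∇T) + W(T)(Tb − T) + ρ·HGR + P_eddy + P_mnp.

Healthy tissues use the constant perfusion coefficient (HTR column, W/m³/°C).
The tumour uses the nonlinear mass flow rate
w(T) = 0.416 + 0.416·e^{−(T−37)⁴/220} kg/m³/s (exponent power and
denominator configurable), converted to a heat-transfer coefficient as
c_b·w(T) — the mass flow rate divided by blood density gives the volumetric
perfusion rate, which multiplies ρ_b·c_b. The perfusion halves as the tumour
vasculature shuts above ~42 °C, which is what makes tumour heating
self-reinforcing. Blood parameters ρ_b = 1050 kg/m³, c_b = 3617 J/kg/°C
(standard values; not part of the tissue table), arterial temperature
Tb = 37 °C.

Boundaries: Robin convection κ∂T/∂n = h(T_ext − T) on tissue–air faces
(h = 10 W/m²/°C, T_ext = 25 °C defaults — typical still-air values), the
bottom grid face held at Tb (chest wall in contact with the body core;
optionally insulated), and zero flux on lateral crop-truncation faces (the
torso continues there, so symmetry is the physical choice).

Time stepping is explicit (forward Euler) on the conservative finite-volume
fluxes, with the nonlinear perfusion coefficient evaluated at the current
state. The step is checked against the 3-D stability bound
ρc/(Σκ_f/h² + W + robin); at 1.5 mm spacing the bound is ≈2.8 s, so the 1 s
default (and the 2 s used for long runs) are comfortably stable, and one
1800 s run on 96³ takes well under a minute. An implicit scheme was
considered and rejected: at desk scale the explicit step is an order of
magnitude cheaper per simulated second than warm-started CG solves, and the
stability bound is checked, not assumed. The t = 0 state is the sourceless
steady state (metabolic heat only), computed by a sparse CG solve with a few
Picard iterations for the tumour nonlinearity.

Validation: uniform insulated tissue settles at Tb + ρ·HGR/HTR (+0.365 °C
for muscle); a uniform block with source follows the lumped exponential
approach to within 0.1 %; the global energy balance holds each step to
round-off; halving the step changes 96³ fields by < 10⁻² °C.

## Dosimetry and planning

- CEM43 uses the standard cumulative-equivalent-minutes form
  Σ R^(43−T)·dt/60 with R = 0.5 at or above 43 °C and 0.25 below (the
  conventional break), additive over intervals by construction.
- Isotherm volumes are voxel counts over tissue; tumour coverage is the
  fraction of tumour voxels at or above threshold.
- Concentration planning bisects φ_r against either the tumour-centre
  temperature (coverage goal 0) or the coverage fraction at the target
  temperature — both criteria are exposed because "temperature reached in
  the tumour" is ambiguous between them; the response is monotone in φ_r, so
  the bracket (auto-expanded up to 3 doublings) and a 0.02 tolerance
  determine the result independently of the initial bracket.
- The field–frequency safety index is the Atkinson–Brezovich product Hmax·f
  compared against the eddy-current pain threshold 4.85×10⁸ A/(m·s); the
  calorimetric settings (10.3 kA/m × 171 kHz = 1.76×10⁹) exceed it, which
  is precisely why the eddy map and skin temperatures belong in a plan
  review. Only strictly larger products are flagged.

## Degenerate inputs and failure modes

Nonpositive physical parameters raise `InvalidParameterError`; reduced field
h ≥ 1 (amplitude above the anisotropy field) is outside the linear-response
barrier picture and raises; a tumour sphere touching skin/muscle/air raises a
placement error; an unreachable glandular band raises a generation error; CG
non-convergence raises with the residual; an explicit step above the
stability bound raises before any work is done.

## Problem sizes

Defaults are desk-scale by design: 96³ phantom voxels, 64³ for the sphere
oracle, 1800 s heating at 1–2 s steps. The unit-test suite uses 32³–48³
grids and minutes-long heating for everything except the acceptance chain,
which exercises the full 96³ × 1800 s configuration.
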