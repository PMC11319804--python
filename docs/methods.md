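# Methods

## Scope and model structure

`aerodep` is a reduced-order Euler–Lagrange model of inhaled-aerosol
transport in the conducting airways. The full-scale methodology it
mirrors solves Reynolds-averaged Navier–Stokes with a two-equation
turbulence closure on CT-segmented patient geometry; here the Eulerian
side is replaced by a branch-network continuity model with analytic
velocity profiles and a turbulence surrogate, while the Lagrangian side —
the particle force balance, drag law, stochastic dispersion and boundary
events — is retained in full. The replacement is deliberate: it trades
geometric realism (secondary flows, carinal impaction hot spots) for a
model that runs in seconds on one CPU and whose statistical properties
can be tested exhaustively.

## Airway geometry

The airway tree is a rooted binary tree of straight cylinders:

| parameter | default | meaning |
|---|---|---|
| trachea radius / length | 9 mm / 10 cm | generation 0 |
| diameter ratio | 0.75 | child/parent diameter per generation |
| length ratio | 0.62 | child/parent length per generation |
| diameter cutoff | 1.5 mm | distal/peripheral boundary (CT resolution) |
| extrathoracic radius / length | 10 mm / 20 cm | single mouth–throat segment |
| branching angle | 35° | half-angle at bifurcations |

The five lobes attach below the main bronchi (right: RUL bronchus +
bronchus intermedius, which splits into RML and RLL; left: LUL + LLL);
children are ordered alphabetically for determinism. Defaults terminate
at generation 9 with 512 outlets and ≈145 mL of airway dead space.

The classical volume-preserving ratio 2^(−1/3) ≈ 0.794 is often quoted
for regular lungs, but applied uniformly down to a 1.5 mm cutoff it
produces an 11-generation tree whose dead space (~370 mL including the
mouth–throat) approaches a resting tidal volume. In that regime most
particles cannot reach the outlets within one inspiration, pure-advection
transport exhales ~75 % of the dose, and the per-lobe dose no longer
tracks the lobar ventilation split — contrary to both observation and the
behaviour the model exists to demonstrate. Real conducting airways taper
faster than 2^(−1/3) in length, so the defaults use diameter ratio 0.75
and length ratio 0.62, which put the dead space in the anatomical range.
Both ratios are configurable; the 2^(−1/3) tree remains available.

Every branch carries a deterministic 3D frame (origin, axis, transverse
basis) computed from topology alone, used only to map deposition sites to
spatial coordinates for projection images; serialization stores the
topological record and recomputes frames on load.

## Ventilation boundary conditions

Per-lobe ventilation fractions come from paired FRC/TLC lobe volumes:
f_l = ΔV_l / Σ ΔV. The synthetic volume generator realises any prescribed
split exactly (the split → volumes → split round trip is the identity on
the unit simplex to 1e-12; percentage tables that sum to ≈100 after
rounding are renormalised on input). The tidal waveform is a sinusoid
with V_T = 0.5 L and T = 4 s by default (one cycle); its inspiratory
integral equals V_T exactly. Within a lobe, flow divides by outlet area
(uniform face velocity), the most direct reading of area-based outlet
conditions; the *area-uniform* mode divides the whole flow by area,
ignoring f_l — the network analog of giving every outlet the same
pressure. Expiration reverses all profiles with the same fractions (no
phase-dependent split is modelled).

## Flow state and turbulence surrogate

Because every outlet profile is proportional to the mouth waveform, each
branch carries a static continuity weight w_b with Q_b(t) = w_b·Q(t);
mass is conserved at every junction to round-off. Branches below the pipe
transition (Re < 2300; ties turbulent) use the Poiseuille profile
u(η) = 2U(1−η²), above it plug flow. The turbulence kinetic energy is
k = 3/2·(I·|U|)² with the fully-developed-pipe intensity correlation
I = 0.16·Re^(−1/8); laminar branches keep a small residual intensity
I = 0.02 so that stochastic dispersion — the only wall-deposition
mechanism for micron particles in a straight tube — does not vanish
identically. Air is ambient (ρ = 1.204 kg/m³, μ = 1.81×10⁻⁵ Pa·s);
body-temperature values can be passed explicitly.

## Particle transport

Drag is the only force (gravity, buoyancy and Brownian motion are
negligible for ~1 µm pharmaceutical aerosol at these time scales). The
drag coefficient uses the Morsi–Alexander piecewise bands; construction
verifies C_D continuity at band edges within 5 % and the tests cross-check
against the independent Schiller–Naumann correlation (within 10 % on
Re_p ∈ [1, 800]). The velocity update is the exact relaxation solution
u_p ← u_f + (u_p − u_f)·exp(−βΔt), unconditionally stable for any Δt —
essential because β ≈ 2×10⁵ s⁻¹ for the default 1.32 µm, 1015 kg/m³
droplets while Δt = 5×10⁻³ s. Positions advance with the trapezoid of old
and new velocity in branch-local coordinates (axial s, radial fraction η,
azimuth φ); the azimuth is advanced passively by the tangential
fluctuation and the radial axis reflects at the centerline.

Dispersion follows the eddy-interaction discrete random walk: per
component u′ ~ N(0, 2k/3), eddy length L_e = 0.07·D, lifetime
L_e/max(σ, ε) with a small floor ε = 10⁻⁶ m/s so quiescent branches keep
a frozen zero fluctuation.

Boundary events: wall contact (η ≥ 1) traps; crossing a terminal outlet
during inflow escapes (peripheral dose of that lobe — escape is terminal
even though flow later reverses, matching the dosimetric convention that
dose leaving the resolved domain is peripheral); crossing an internal
junction transfers to a daughter with probability proportional to the
instantaneous daughter flow magnitude, entering at the daughter inlet;
moving backwards out of a branch during expiration transfers to the
parent's distal end, and leaving the mouth inlet during expiration counts
as exhaled. Particles are injected at the mouth over the inspiratory
phase with flow-weighted timing (continuous nebulised delivery), over the
inlet disc by default (a centerline option exists for verification runs);
delivered dose is the full injected count. Particles still airborne at
the end of the simulated time (default: the full breathing pattern) are
reported as their own *suspended* class.

The engine advances all particles on a shared time grid with vectorised
numpy kernels; the per-particle operations exposed in the API use the
same formulas and serve as the reference implementation in the tests.
One-way coupling is asserted by comparing the total particle volume to
the airway volume against the 10⁻⁶ dilute-flow limit (a warning, not an
error, since the check is conservative).

## Dosimetry and comparison conventions

Regional results are percentages of delivered dose. *Intrathoracic* is
defined as distal + peripheral — the convention used by the reference
tables this package mirrors — with central deposition reported separately.
(The alternative prose convention that includes the central zone in the
intrathoracic region is not used; the table arithmetic fixes the choice.)
Lobar totals combine distal wall deposition and peripheral escape per
lobe; airways serving more than one lobe (trachea, main bronchi, bronchus
intermedius) carry no lobe label and contribute only to zone totals.

For comparison against SPECT-style references, RUL and RML are merged and
the four-zone vector is rescaled to sum to 100 (reference rows sum to
≈100, which fixes the normalisation). The per-patient statistic is the
mean of the four absolute differences in percentage points. The cohort
mean rounds each per-patient value to reporting precision (two decimals)
before averaging, in exact decimal arithmetic — this reproduces published
table arithmetic and avoids binary round-off flipping the last printed
digit. Projection images accumulate deposition counts on a 128×128 grid
by default, with no point-spread blurring.

## Synthetic data: what it does and does not emulate

The generators replace three acquisitions: CT airway segmentation (regular
symmetric tree), FRC/TLC lobe volumetry (volumes realising a prescribed
split, with seed-controlled jitter on the FRC partition that does not
affect the fractions), and SPECT reference tables (the model's four-zone
vector plus zero-mean Gaussian noise in percentage points, clipped at
zero and renormalised to the original total). Passing tests therefore
demonstrate the *mechanics* — conservation, ventilation-driven dose
partitioning, statistical convergence, metric arithmetic — on idealised
geometry. They do not demonstrate geometric deposition effects absent
from a straight-tube network: laryngeal jet impaction, carinal hot spots,
asymmetric branch morphometry, or inter-patient anatomical variability.
Absolute zone percentages from this model should not be read as
predictions for real airways; the lobar partitioning behaviour should.

## Default study conditions and problem sizes

Monodisperse 1.32 µm, 1015 kg/m³ droplets; Δt = 5×10⁻³ s; 5×10⁴
particles for production runs (the convergence harness at
{10⁴, 2×10⁴, 4×10⁴} shows zone %DD spreads within three binomial standard
errors, the package's reduced-scale analog of full-scale
injection-independence studies at >10⁶ parcels); one breathing cycle.
A lognormal MMAD/GSD sampler (defaults 1.51 µm / 2.23) covers device-like
polydisperse aerosols; diameters are drawn from the mass-weighted
distribution directly since MMAD is what device data report, and the
fine-particle fraction is computed from the sample with a 5 µm cutoff
(the community default) as a report field only.

## Known limitations

Straight cylinders, fully-developed profiles and isotropic dispersion
underestimate inertial deposition at bifurcations and in the larynx; the
extrathoracic segment's deposition reflects the dispersion surrogate, not
mouth–throat impaction physics. The flow network carries no pressure or
compliance, so lobar filling is prescribed, not emergent. Escape is
irreversible, which slightly overstates peripheral dose for particles
that would re-enter on expiration. Mass-weighted dosimetry for
polydisperse runs is not implemented; reports are count-weighted.
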