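# Methods

## Constitutive model

The membrane (3M VHB 4910 acrylic elastomer) is treated as incompressible
and hyperelastic with the Yeoh strain-energy density
W = C10(I1−3) + C20(I1−3)² + C30(I1−3)³.  The shipped default profile
`VHB4910` stores the published constants bit-exactly: C10 = 0.0693 MPa,
C20 = −8.88·10⁻⁴ MPa, C30 = 16.7·10⁻⁶ MPa, ε0 = 8.85·10⁻¹² A s/(V m),
εr = 4.7.  Yeoh constants are kept in MPa as tabulated; electrical
quantities are SI, and unit conversion happens at the module boundaries so
the defaults never round-trip through a conversion.

With negative C20 the cubic fit eventually loses convexity, so a validity
window λ ∈ [1, 4] is documented and evaluation outside it warns rather than
errors (the device never operates beyond λ ≈ 3.2).  For the default
constants W1 = dW/dI1 stays positive everywhere in the window (its minimum,
C10 − C20²/(3 C30), is positive), which guarantees a monotone equibiaxial
stress and a unique equilibrium root.  The relative dielectric constant is
taken stretch-independent, as tabulated.

The Maxwell stress σ_M = ε0 εr (V/t)² enters as an equibiaxial reduction of
the in-plane true stresses — equivalent, via incompressibility and pressure
elimination, to the through-thickness squeeze it physically is.

## Homogeneous equilibrium (`actuation`)

"Prestretched radially by 200%" is read as stretch ratio λp = 3
(engineering strain 2), consistent with the 1 mm film thinning to
1/9 mm ≈ 0.1 mm and with the convention of obtaining actuating strain by
subtracting the prestretch engineering strain of 2 from total strain.

The homogeneous model closes the boundary-value problem with a dead
prestress: the passive annulus is idealized as holding the equibiaxial true
stress at its prestretch value, giving the one-equation voltage–strain law
σ_el(λ) = σ_el(λp) + σ_M.  This scalar closure is deliberately simple — it
exists to support calibration-style sweeps — and is cross-checked against
the axisymmetric field solver's center value (they agree to ~3% at 5 kV and
~1% at 1 kV with the default geometry).

Two thickness conventions are offered for σ_M.  The default, `"initial"`,
freezes t at the post-prestretch thickness t_init/λp²; σ_M is then
independent of λ, the equation always has a unique root in the validity
window, and no electromechanical pull-in exists.  `"true"` lets
t = t_init/λ² follow the deformation, so σ_M grows as λ⁴; this convention
exists for sensitivity analysis, and `snap_through_voltage` reports its
pull-in voltage (≈ 9.4 kV for the default device) by bisection on
solvability.  Roots are bracketed on [λp, 4] and found by Brent's method to
1e-10 in stretch.

## Viscoelastic drift

The device's warm-up and cyclic drift are modeled phenomenologically, not
constitutively.  The observable strain is

ε(t) = ε_el(V(t)) + c(t) · Σ_k a_k s_k(t),

where ε_el is the elastic equilibrium strain, each internal state s_k
tracks ε_el(V(t)) with time constant τ_k (exact piecewise-exponential
integration on constant-voltage segments), and the creep amplitudes
a_k = g_k/(1 − Σ g) derive from Prony relaxation amplitudes g_k ∈ (0, 1),
Σ g < 1.  Under sustained load the strain creeps from ε_el toward
ε_el/(1 − Σ g).

A bare Prony kernel is linear, and a linear kernel driven at a fixed duty
cycle converges at a frequency-independent rate — it cannot reproduce the
observed behavior that higher-frequency cycling reaches its steady state
earlier in wall-clock time.  The drift model therefore carries an optional
cyclic-conditioning state c (Mullins-type softening): c starts at cond0,
jumps by κ(1−c) at every loading onset, grows toward 1 with time constant
τ_c while loaded, and does not recover.  Conditioning is off (cond0 = 1) in
a bare `DriftModel`, so the linear-kernel limits hold exactly: with no
Prony terms the response is purely elastic, and with full recovery between
tests all tests coincide.

The shipped `default_drift()` profile — g = (0.25, 0.25, 0.20),
τ = (1, 8, 25) s, cond0 = 0.35, κ = 0.12, τ_c = 150 s — was calibrated once
against the device's documented behaviors and then frozen: (a) under the
static protocol (60 s holds, 600 s relaxations) the per-test strain rises
with strictly decreasing increments and is within 5% of its asymptote by
test 6, matching the six-test warm-up; (b) the 0→5 kV cyclic steady band
spans roughly 4–12% strain across 0.15–1 Hz, against the reported 5–13%;
(c) the 1 Hz run settles (per-cycle mean within 5% of final) in ≈ 40 s of
wall-clock time versus ≈ 105 s at 0.15 Hz.  Tests assert the behaviors, not
the parameter values.

All simulators are deterministic — no RNG, uniform sample grids, exact
exponential updates per constant-voltage segment.

## Axisymmetric membrane field (`membrane_axisym`)

The electroded membrane is modeled as a thickness-integrated (plane-stress)
axisymmetric membrane — justified because thickness ≪ radius
(0.1 mm vs 30 mm) — replacing any 3D continuum treatment; the electrode
lead strip is dropped, so the model is exactly axisymmetric.  Equilibrium
in the reference configuration is d(R P_r)/dR = P_t with
P_r = 2W1(λ_r − λ_r⁻³λ_t⁻²), P_t by symmetry, and σ_M reducing both
in-plane true stresses inside the electrode.  Boundary conditions:
regularity at the center, clamp at the prestretch position
r(frame_radius) = λp·frame_radius.  The electrode boundary is specified in
the prestretched configuration (the electrode is deposited after
prestretching) and mapped to reference coordinates R_e = electrode_radius/λp.
The default electrode radius, 5.85 mm, is inferred from the device's
strain↔displacement pairing (49.73 μm at 0.850% strain) and is configurable;
path and radius arguments of `path_profile`/`equiaxiality_index` are in
reference coordinates.

Within a region of constant load the unique regular solution is the uniform
equibiaxial field r = λc R, so the electrode interior is exactly uniform
and equiaxial in this model; structure appears at the electrode edge —
where total radial traction is continuous but λ_r jumps down — and across
the passive annulus.  The solver shoots on the center stretch λc (bracket
scan + Brent to 1e-10) and integrates the annulus with classic fixed-grid
RK4 on states (r, m = R·P_r), inverting the radial tension for λ_r at every
stage by Newton's method with an analytic Jacobian (bracketed fallback).
The (r, m) formulation was chosen over (r, λ_r) because λ_r is
discontinuous at the electrode edge and because it makes the per-node
closure residual |P_r(λ_r, λ_t) − m/R|/C10 directly checkable (< 1e-12 in
practice, asserted < 1e-8).  A fixed graded grid (a third of the nodes
inside the electrode, the rest uniform across the annulus, interval counts
scaling with n_nodes) was preferred over adaptive integration so that mesh
self-convergence is meaningful; the observed convergence order is ≈ 4, and
nodal strains at shared radii differ by ~1e-10 between 200 and 400 nodes.

Uniformity and equiaxiality are reported as a coefficient of variation
along in-electrode paths and as |ε_r − ε_t|/max(|ε_r|, |ε_t|, floor); the
0.05 acceptance thresholds on both are package choices (the underlying
property is only known qualitatively), and the floor (1e-6) guards the
0/0 of an unactuated field.

## Measurement and calibration (`measurement`)

Radial strain is (r − r0)/r0 with the radius taken as half the distance
between diametrically opposite electrode-edge points; percent linear strain
is ε×100.  Cycle summaries detect cycles by rising mid-level threshold
crossings with a hysteresis band of 5% of the trace range (robust on
drifting square waves) and report per-cycle maxima and minima averaged over
the analysis window; avg_diff = avg_max − avg_min holds exactly by
linearity of the mean.

The calibration line is stored in plot units (% strain vs kV) so the
default slope 1.7 and intercept −0.85 stay bit-exact; it is valid on
0.5–5 kV, and evaluation below its zero crossing clamps the strain at 0
with a warning.  Fitting is unweighted OLS (no error model is assumed);
diagnostics include R², residual SE, and parameter standard errors, and the
95% CI for the slope achieves nominal coverage on synthetic data (checked
over 2000 seeded replicates).

## Transduction (`transduction`)

The amplifier chain is modeled as linear amplitude modulation about the
offset: V(t) = V0(1 + m·s(t)).  The default m = 0.01 is chosen because the
device's published NUMS strain envelope (0.833–0.867%) is exactly the
calibration line evaluated at 0.99–1.01 kV; both V0 and m are configurable.
Audio is peak-normalized to full scale before modulation, so any nonzero
input exercises the full modulation depth; silence maps to the constant
offset (the US condition).  Whether the music modulated amplitude,
frequency, or both is not documented for the original device; amplitude
modulation is the implemented reading.  The strain trace is sampled at the
audio rate; no actuator-bandwidth low-pass is applied by default (none is
documented), and the gauge length converting strain to displacement
(5.85 mm by default, giving 49.7 μm at 0.850%) is an inferred, configurable
constant.  Spectra use Welch's averaged periodogram (Hann window, 0.5 s
segments, 50% overlap, density scaling), which is Parseval-consistent to
within 1% on the fixtures used.

## Expression (`expression`)

Fold change is the pure 2^−ΔΔCt form with no amplification-efficiency
correction.  Replicates are folded against the control-group mean ΔCt and
summarized by the geometric mean with a log2-space SD, matching the
additive-in-cycles error model of Ct measurements.

## Synthetic data (`synthetic_data`)

Generators are pure functions of (parameters, seed); substreams are derived
by SHA-256 hashing of the generator name combined with the seed, so adding
a generator never perturbs existing fixtures.  The music-like generator
sums harmonic note events (log-uniform fundamentals 110–880 Hz, 8 partials
with 1/k^1.5 amplitudes, exponential note durations, raised-cosine
envelopes); every seed yields >50% of power below 1 kHz, matching the
documented spectral balance of the stimulus, but it does not emulate real
music's rhythm, dynamics, or production.  The Ct generator encodes effect
*directions* (stemness down in both stretched groups, osteogenic marker up
under NUMS only, chondro-/adipogenic markers up under US) with magnitudes
as free parameters — no numeric fold changes are published.  Passing tests
therefore demonstrate that the computational chain is correct and
invertible on data with the documented structure; they do not reproduce any
biological conclusion, and the original stimulus recording and sequencing
data are not used.

## Problem sizes and numerical choices

Default test and acceptance runs use: 200–960 node membrane solves (a
solve costs ~0.5 s), 400 s cyclic simulations at 30–50 Hz sampling, 2000
calibration replicates, and 2–4 s audio fixtures at 16 kHz — sizes chosen
so the whole suite runs in well under a minute on one core while leaving
every estimator comfortably inside its asymptotic regime.  Tie-breaks and
degenerate inputs: zero voltage returns the prestretch state exactly;
coincident measurement points, empty traces, constant traces (no cycles),
sub-physical invariants (I1 < 3), and non-finite Ct values raise
`ValueError`; loss of the equilibrium root raises `InstabilityError`
carrying the bracket and voltage.

## Known limitations

- The dead-prestress closure of the homogeneous model is approximate; use
  the field solver when the annulus matters.
- The drift model is phenomenological; its parameters are device-level
  calibration constants, not material properties, and the conditioning
  state never recovers (no overnight rest).
- The membrane model cannot represent the electrode-lead asymmetry,
  wrinkling, or 3D edge effects at the clamp.
- The calibration line is empirical and device-specific; extrapolation
  below 0.5 kV is clamped, not modeled.
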