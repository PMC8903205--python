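# Methods

`larynxsim` simulates voice production under explicit intrinsic laryngeal
muscle control.  The pipeline has four stages — posturing, tissue
mechanics, flow-induced vibration, and airway acoustics — followed by
feature extraction and a two-parameter activation sweep.  All internal
quantities are CGS (cm, g, s, dyn/cm²); pressures cross the user boundary
in kPa (1 kPa = 10⁴ dyn/cm²).

## Posturing

The control vector is the activation of five intrinsic muscle pairs (CT,
TA, LCA, IA, PCA; fractions of maximal activation) plus lung pressure.
Posture is quasi-static: activations set a prephonatory geometry on which
vibration is superimposed.

**Strain.**  The anterior–posterior strain ε solves a one-degree-of-freedom
force balance: active cricothyroid force elongates the fold against the
summed passive stresses of the three fold layers, while active
thyroarytenoid force pulls toward shortening,

    F(ε) = (a_CT·G_CT − a_TA·G_TA)·FL(ε) − Σ_l A_l [σ_l(ε) − σ_l(0)] = 0 .

FL is a Gaussian force–length factor (peak at ε = 0.4, width 0.6).  The
layer cross-sections A_l (SLLP 0.03, ligament 0.05, muscle 0.40 cm²) are
config constants on the order of the layers' anatomical shares of the fold
cross-section.  The two gains are fixed in closed form by two anchors —
full CT alone gives ε = +0.1875 (L = 1.9 cm), full TA alone gives
ε = −0.375 (L = 1.0 cm) — reproducing the physiological male length range
from a 1.6 cm rest length.  The root is found with Brent's method on
ε ∈ [−0.45, 0.45]; the residual is verified below 10⁻⁶ of the force scale.
This balance is a deliberately simple stand-in for full cartilage
mechanics (a 3-D torque/translation model of the cricothyroid and
cricoarytenoid joints); it preserves the nonlinear saturation of length
with CT activation that the layers' exponential stress laws impose, but
not arytenoid kinematics.

**Posture rules.**  From ε: L = L₀(1+ε), T = T₀/(1+ε) (isovolume,
L·T = L₀·T₀ exactly), ξ₀₁ = ξ₀₂ + max(0, 0.1 T (1 − 1.5 a_TA)),
ξ_b = 0.05 T (1 − a_TA).  The medial surface half-width is

    ξ₀(y,z) = (1 − y/L)[ξ₀₂ + (ξ₀₁ − ξ₀₂ − 4 ξ_b z/T)(1 − z/T)] ,

affine in y, quadratic in z, vanishing at y = L.

**Adduction.**  The vocal-process half-width follows a linear rule
ξ₀₂ = ξ₀₂ʳᵉˢᵗ (1 − k_LC (a_LC + a_IA)/2 − k_TA a_TA), clipped below at a
small negative overlap bound (−0.02 cm).  Defaults ξ₀₂ʳᵉˢᵗ = 0.06 cm,
k_LC = 1.0, k_TA = 0.2 were chosen once so that over the sweep's entire
LCA/IA constraint range (20–60 %) the gap stays in (0, 0.05] cm — adducted
enough that the phonation threshold is reachable, never fully pressed.
(A 0.15 cm rest gap cannot satisfy both ends of that range under a linear
rule; the smaller rest gap was preferred over a steeper slope.)

## Tissue mechanics

Passive fiber stress per layer follows a combined linear + exponential law
with the packaged per-layer constants (σ₀, σ₂, B, ε₁, ε₂),

    σ_y(ε) = −(σ₀/ε₁)(ε − ε₁) + σ₂[e^{B(ε−ε₂)} − 1 − B(ε−ε₂)] ,

where the exponential bracket is zeroed for ε ≤ ε₂ (keeping the law C¹
there).  The linear term uses the positive-slope normalization −σ₀/ε₁
(equal to σ₀ at zero strain); the literal negative-slope rendering found
in some sources is available via the `as_printed` switch but makes stress
decrease with strain.  Active muscle stress is quasi-static,
σ_act = a·σ_m·FL(ε); activation kinetics are out of scope.  A taut
fiber's transverse restoring force per unit length per unit displacement
equals its tension, so the fiber-equivalent shear modulus is
μ′ = max(0, σ_y); slack fibers carry none.  The gel ground substance has
shear modulus μ = 0.5 kPa and viscosity η = 0.1 Pa·s in all layers.  The
exact μ′ conversion of the original fiber-gel formulation is not public;
μ′ = σ_y is the simplest mechanically motivated choice and is flagged as a
stand-in (see Limitations).

## Vibration

Each fold is 15 coronal slices of a 2-D plane-strain finite-element mesh:
10 × 6 cells, two linear triangles per cell, 77 nodes per slice.  Columns
split 1/2/7 into SLLP cover, ligament and muscle body.  The medial node
column lies on ξ₀(y,z); the lateral boundary is curved (depth
0.8·(0.5 + 0.5 sin πz/T) cm).  Anterior, posterior and lateral surfaces
are fixed; inferior, medial and superior surfaces are pressure-loaded.
Incompressibility is enforced by a penalty bulk term (50 μ); tissue
density is 1.04 g/cm³.  Anterior–posterior fibers couple matching nodes of
adjacent slices as tensioned strings (tension = layer fiber stress × nodal
coronal area share, spacing L/14), which is where μ′ acts.  Damping is
stiffness-proportional with time constant η/μ, assembled from the
deviatoric (shear-only) operator so the numerical penalty term is not
damped.

Time integration is symplectic (semi-implicit) Euler at 44.1 kHz, the
acoustic rate, keeping tissue and waveguide synchronous.  The damping term
is handled implicitly through one prefactorized constant sparse solve per
step, so the scheme is unconditionally stable in the damping and reduces
to energy-conserving leapfrog when η = 0.  Midline collision uses a
one-sided penalty spring (3× the local medial stiffness) plus a critical
local damping while in contact, applied as a split-step velocity
relaxation.  A run aborts (status `failed`) if displacements exceed 1 cm
or go non-finite.  A seeded 10⁻⁴ cm/s initial nodal velocity breaks the
symmetric equilibrium; left–right symmetry is assumed, the right fold is
simulated and mirrored (glottal width = 2 × half-width).

## Aerodynamics and airway acoustics

The airways are wave-reflection tubes with section length
c/(2·44100) = 0.3968 cm (c = 350 m/s): 36 subglottal sections (uniform
2.5 cm² trachea, anechoic lung end carrying the constant lung-pressure
source) and 44 supraglottal sections holding a packaged representative
male /ɑ/ area function.  Waves cross one section per half sample; two
scattering passes per audio sample.  Viscous and wall losses are
represented by a per-section amplitude factor 0.996 — a stand-in with the
right sign and order, not a fitted loss model.  The mouth terminates in
the low-frequency parallel inertance/resistance radiation load,
discretized with the bilinear transform (reflection → −1 at DC); the
radiated signal is the mouth-end pressure.

The glottal flow solves the junction quadratic
(ρ/2)(u_g/A_g)² + (Z_s+Z_e) u_g = 2(F_sub − B_supra) (positive root,
rectified at zero), where A_g is the minimum of the glottal area function
a(z) = 2∫ξ dy.  Surface pressures follow energy-conserving Bernoulli from
the subglottal stagnation pressure up to the minimum-diameter row and a
non-recovering jet (supraglottal pressure) at and above it; with a closed
row, rows below see the upstream stagnation pressure.  This
convergent/divergent pressure asymmetry is the energy-transfer mechanism
for self-sustained oscillation; collision limits the amplitude, producing
the saturation of radiated level with lung pressure.

## Features

* **fo** — autocorrelation over the final 0.2 s with parabolic peak
  interpolation, search range 50–600 Hz, periodicity-confidence gate 0.3
  (returns none for aperiodic signals).  This replaces the SWIPE′ tracker;
  on clean periodic signals the two agree to ~1 Hz, and the gate makes
  irregular phonation explicit rather than guessed.
* **SPL** — 10 log₁₀(p̄ₒ²/(4πR²·R_m·I₀)) at R = 30 cm with
  I₀ = 10⁻¹² W/m².  R_m defaults to 1 in normalized units; the absolute
  calibration lives in `spl_offset_db`, whose default −12.0 dB equals
  −10 log₁₀ of the physical radiation resistance 128ρc/(9π²A) ≈ 16 cgs at
  the packaged 3.6 cm² mouth section.  Doubling the waveform amplitude
  adds exactly 6.02 dB.
* **NSC** — Hann-windowed magnitude-spectrum centroid over the final
  0.2 s, divided by fo.
* **ApEn** — ApEn(m = 2, τ = 1), radius r = 0.2·SD(x) (the standard
  scale-invariant convention; `apen_r_mode = "variance"` reproduces the
  r = 0.2·var(x) reading), self-matches included; a constant signal
  returns 0.  Signals are decimated to 4410 Hz first: the estimator is
  O(N²) and the decision-relevant structure sits far below 2 kHz.
* **Postural means** — arithmetic means over the final 100 ms.

The synthetic-signal generator (pure tones, harmonic complexes,
period-jittered tones, white noise) exercises these extractors against
closed-form expectations and a brute-force ApEn oracle.  These fixtures
probe the extractors, not the voice model: they contain no formant
structure, no amplitude modulation and no additive turbulence noise, so
extractor tests passing says nothing about simulation realism — that is
what the sweep-level property tests are for.

## The activation sweep

CT and TA activations run over 0–100 % (default step 5 %, 441 cells; the
packaged verification uses 25 % steps, 25 cells).  Each cell applies the
closed-form constraints P_L = 0.8 + 0.025 a_CT + 0.01 a_TA kPa and
a_LC = a_IA = 30 + 0.3 a_CT − 0.1 a_TA % (PCA fixed at 0 %), simulates
0.4 s, and extracts features.  A cell is *oscillating* when the
glottal-area peak-to-peak amplitude over the final 100 ms is at least 95 %
of the preceding 100 ms and above a 10⁻³ cm² floor.  Cells are cached by
(a_CT, a_TA, config hash), so sweeps are resumable; failures are recorded,
never raised.  Maps export as tidy CSV plus contour plots (TA on x, CT on
y, in percent); non-oscillating cells are blanks, not zeros.

Problem sizes in the packaged checks — 25-cell sweeps, 0.4 s signals,
0.12–0.2 s signals for stepping/threshold unit checks — were chosen as
the smallest sizes at which the qualitative map properties are stable.

## Numerical choices

* Brent root-finding for strain (deterministic, bracket [−0.45, 0.45]).
* Explicit symplectic stepping at the acoustic rate; stability is
  monitored by the 1 cm displacement abort rather than adaptive stepping.
* Collision penalty 3× the local stiffness; penetration tolerance is the
  resulting static compliance.
* Glottal areas are clamped at zero before integration; flow is rectified
  at zero; closed glottis (A_g ≤ 10⁻⁶ cm²) carries no flow.
* Lung pressure ramps over 10 ms to avoid an onset shock.
* All randomness (the onset perturbation, test fixtures) is seeded.

## Limitations

* The posturing balance and the adduction rule are stand-ins for
  unpublished cartilage mechanics; they are calibrated only through the
  two length anchors and the adduction postcondition.
* μ′ = σ_y over-tensions the folds at high CT activation: phonation
  reaches ~430–660 Hz there (above the ~400 Hz ceiling expected for a male
  configuration), and consequently the fo estimator's 600 Hz search bound
  folds the highest cell down an octave.  High-pitch cells also radiate a
  few dB above the expected 90 dB ceiling.
* A handful of grid cells do not self-sustain: the rest cell (0,0) sits
  marginally below this model's phonation threshold at 0.8 kPa, and a few
  high-activation cells are chaotic or decaying rather than periodic.
* The muscle-layer net fiber stress is not monotone in TA activation at
  low CT: far below the optimal fiber length the Gaussian force–length
  factor outweighs the activation increase.
* No turbulence/aspiration noise, fixed /ɑ/ tract, no nasal tract,
  symmetric folds only, no contact friction, plane-strain slices with
  string coupling rather than full 3-D elasticity.
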