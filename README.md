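# larynxsim

A muscle-activation-controlled simulator of human voice production.  It
maps the activation of the intrinsic laryngeal muscles — cricothyroid
(CT), thyroarytenoid (TA), with the lateral cricoarytenoid/interarytenoid
(LCA/IA) adductors and lung pressure constrained to keep phonation above
threshold — to:

* prephonatory vocal fold **posture** (strain, length, thickness,
  adduction, the medial-surface half-width field);
* per-layer **fiber stresses** from a combined linear + exponential
  constitutive law with active muscle stress;
* flow-induced **self-sustained oscillation** of a layered fiber-gel
  finite-element fold model (15 coronal slices of 10×6-cell plane-strain
  meshes coupled by tensioned fibers, with midline collision);
* a radiated pressure signal through a **wave-reflection vocal tract**
  (36 subglottal + 44 supraglottal sections of 0.3968 cm at 44.1 kHz,
  /ɑ/ area function, low-frequency radiation load);
* four **acoustic features** per phonation — fundamental frequency fo
  (pitch), sound pressure level SPL at 30 cm (loudness), normalized
  spectral centroid NSC (brightness), approximate entropy ApEn
  (roughness) — and steady-state postural means;
* **muscle-activation maps**: every feature contoured over the TA–CT
  activation plane (0–100 % in 5 % steps, 441 cells by default).

It is aimed at voice scientists and speech-physiology modelers who want a
transparent, fully scripted path from muscle activation to acoustics.

The core control laws are

    P_L  = 0.8 + 0.025 a_CT + 0.01 a_TA   [kPa]
    a_LC = a_IA = 30 + 0.3 a_CT − 0.1 a_TA  [%]

    L = L0 (1 + ε),  T = T0 / (1 + ε)
    ξ01 = ξ02 + max(0, 0.1 T (1 − 1.5 a_TA)),  ξb = 0.05 T (1 − a_TA)
    ξ0(y,z) = (1 − y/L) [ξ02 + (ξ01 − ξ02 − 4 ξb z/T)(1 − z/T)]

    σ_y(ε) = −(σ0/ε1)(ε − ε1) + σ2 [e^{B(ε−ε2)} − 1 − B(ε−ε2)]

with the strain ε from a calibrated quasi-static CT–TA force balance
(L spans 1.0–1.9 cm from a 1.6 cm rest length).  See `docs/methods.md`
for the full model description, parameter defaults and limitations.

## Worked example

Simulate one phonation at 20 % CT and 20 % TA activation (lung pressure
and adduction follow the constraint rules automatically):

```sh
$ larynxsim simulate --act 20,20 --out run/
status: oscillating  PL = 1.500 kPa  aLC/aIA = 34.0%
fo = 129.9 Hz  SPL = 80.8 dB  NSC = 19.71  ApEn = 0.609  L = 1.600 cm
```

The fold self-oscillates at 129.9 Hz — a typical male speaking pitch —
radiating 81 dB at 30 cm; the high spectral centroid reflects the sharp
collision-driven flow pulses, and the small ApEn indicates nearly
periodic vibration.  `run/` receives the radiated waveform (`po.wav`),
the time series (oral pressure, glottal flow, glottal area, length,
layer stresses) and a one-row feature CSV.

The same thing from Python:

```python
from larynxsim import run_point
res = run_point(20, 20, keep_record=True)
print(res.status, res.features.fo, res.features.SPL)
```

A full activation map (this is minutes per grid with 25 % steps, hours
with the default 5 % steps):

```sh
larynxsim sweep --step 25 --out maps/
```

writes `feature_map.csv` plus one contour plot and tidy CSV per feature
(lung pressure, adduction, fo, SPL, NSC, ApEn, length, three layer
stresses) over the TA–CT plane.

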