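# Methods

## Scope and model structure

The package computes post-implantation bone-mechanics metrics (stress
shielding increase, equilibrium bone resorption, implant factors of
safety, experiment/model agreement) over *paired element fields*: two
tables, intact and implanted, aligned element-by-element, each row
carrying a Gruen-zone label, centroid, volume, density, von Mises stress
and signed principal compressive strain. The metrics themselves are
exact, closed-form aggregations; the only modeling lives in the
synthetic femur generator that produces desk-scale input fields.

## Synthetic femur (composite-beam generator)

The femur construct is idealized as a stack of axial stations over a
328 mm working length (z = 0 at the lesser trochanter, increasing
distally). Each station carries a cortical annulus (outer radius
13.5 mm, inner 8 mm) and, proximal to the stem tip at z = 150 mm, either
a cancellous core (intact) or a press-fit stem cylinder plus a resin
annulus filling the reamed canal (implanted). The stem radius tapers
linearly from 7.5 mm proximally to 5.0 mm at the tip, so the proximal
canal is nearly filled — the press-fit situation — while distal bands
retain more resin. The stem-tip coordinate is always inserted as a
station edge so intact and implanted stacks share one element layout;
for the intact femur the would-be stem/resin split is two cancellous
sub-regions, which changes nothing mechanically but makes the pair
element-aligned by construction.

Loading follows the single-leg-stance/ISO 7206-4 arrangement: a joint
force of magnitude P applied at the head centre (default offset
(42, 0, −54) mm from the shaft axis at the lesser trochanter), tilted
10° in adduction (coronal plane, applied first) and 9° in flexion
(sagittal plane). Axes: z distal, x lateral→medial, y posterior→anterior.
At each band the internal axial force and bending moments give the
composite-section strain field

    ε(z, x, y) = N/ΣEA + M_x·y/ΣEI_x + M_y·x/ΣEI_y,

one strain shared by all materials at a point (plane sections), with
modulus-weighted section rigidities. Per-material stress is σ = E·ε and
the uniaxial magnitude |σ| stands in for the von Mises stress: shaft
surface stress is bending-dominated and every downstream metric is a
ratio, so the deviatoric correction cancels. The signed axial strain is
reported as the principal compressive strain.

Because the implanted section is stiffer than the intact one wherever
the stem is present, cortical strain — and hence stress — drops
proximally in proportion to the rigidity ratio, which is the physical
mechanism of stress shielding; distal to the stem tip the sections are
identical and the fields agree up to noise. This reproduces, by
construction rather than calibration, the qualitative structure of a
volumetric FE comparison: proximally concentrated shielding for a stiff
stem, near-zero shielding in Gruen zone 4, a medial/lateral asymmetry
from the oblique load, and monotonicity of total SSI in stem modulus.

**Noise model.** Each element draws one multiplicative factor
(1 + σ·N(0,1)), σ = 2% by default (strain-gauge repeatability scale),
applied to both stress and strain so the row stays self-consistent.
Intact and implanted tables use independent streams spawned from one
seed, as two separate measurement campaigns would. Because the factor is
independent of load, fields scale exactly linearly with load magnitude
at fixed seed, and SSI is exactly load-invariant.

**Discretization.** Default 20 stations (+ the stem-tip edge) and
mesh_density 8: per band, 8 medial + 8 lateral cortical elements spread
over ±60° arcs around the bending plane, and 8 elements per interior
region — 552 elements per configuration, 320 of them cortical. This is
deliberately small: every metric is a ratio of volume-weighted sums that
converges at coarse resolution, and the full test suite plus pipeline
runs in seconds.

### Default parameters

| Parameter | Default | Why |
|---|---|---|
| E cortical / cancellous / resin | 16.7 / 0.155 / 2.5 GPa | composite-femur manufacturer values |
| E Ti6Al4V / PEEK | 110 / 1.69 GPa | stem materials under comparison |
| ν (PEEK 0.35, others 0.30) | — | standard values |
| ρ cortical / cancellous / resin | 1.64 / 0.27 / 1.69 g/mL | composite-femur values |
| Analysis load | 2300 N | ISO 7206-4 level used for SSI/resorption/safety |
| Validation loads | 500–1200 N, 100 N steps | single-leg-stance protocol, linear-elastic range |
| Load angles | 10° adduction, 9° flexion | test-standard orientation |
| Head offset | (42, 0, −54) mm | anatomic femoral-head offset scale; configurable since no standard value exists |
| Dead zone s | 0.6 | typical clinical densitometry value; threshold 1−s = 0.4 |
| Fatigue | R = 0.1, σ_y = 85.5 MPa, σ_N = 70 MPa | PEEK stem cycle/strength data |
| Jogging loads | 4839 N and 4883 N | both literature values accepted via config; neither is a default |
| noise_sd | 0.02 | gauge-repeatability scale |
| Gruen band edges | thirds of the stem length | zones are defined pictorially in clinical use; equal axial thirds is the neutral choice |

## Metric definitions and numerical choices

- **Volume averages** use element-centroid values × element volume — the
  same first-order quadrature an FE post-processor applies; no
  higher-order correction.
- **Zones are cortical-only**: interior (stem/resin/cancellous) elements
  never enter SSI or resorption sums. Interior elements still carry a
  zone label (their band's lateral number) purely to keep the label
  total; it is inert.
- **SSI** is a signed fraction internally; percent only at presentation.
  Total SSI normalizes volume fractions over the included zones
  (default: all seven).
- **Resorption** squares the ratio of signed compressive strains, so a
  sign flip between configurations is treated as the energy change it
  is. Elements with |ε_intact| ≤ 1e-9 (effectively unloaded, e.g. on the
  neutral axis) are excluded from both sums and counted in the report.
  Only the resorption branch is implemented — no densification, no
  dρ/dt time integration: the output is the remodeling-equilibrium
  resorbed fraction. The dead-zone indicator uses x = ratio/(1−s) < 1,
  the algebraic form consistent with the resorption inequality
  S < (1−s)·S_intact.
- **Safety**: σ_min is obtained by scaling σ_max by R rather than
  re-solving at the trough load — exact under linear elasticity.
  Unstressed elements report infinite FoS and are excluded from minima;
  ties in the minimum break toward the lowest element id.
  ``unsafe_fraction`` defaults to element counting; volume weighting is
  available. FoS presentation uses explicit half-up rounding
  (engineering-table convention; banker's rounding would print the exact
  tie 85.5/76 = 1.125 as 1.12 instead of 1.13).
- **Rosette reduction**: gauge A defines 0° (parallel to the shaft
  axis), B +45°, C +90°, counterclockwise positive. The generator
  renders surface states as uniaxial stress along the axis (free
  surface), so channels are (ε, (1−ν)ε/2, −νε). Repeat averaging is the
  plain mean, matching averaged peak counts; no outlier rejection.
- **Stiffness fit**: OLS slope of load on displacement; without an
  explicit window, the contiguous window of ≥50% of samples maximizing
  R² is chosen (ties: longer, then earlier). Construct stiffness for
  synthesized records comes from unit-load virtual work over the
  section stack (axial + bending compliance at the offset load point).
- **Bland–Altman**: sample (n−1) SD; limits bias ± 1.96·SD; agreement
  declared when no point falls outside the limits.

## What the generator does and does not emulate

It emulates: paired element tables with realistic magnitudes (tens of
MPa cortical stress at 2300 N, ~10⁻³ strains), proximally concentrated
shielding that grows with stem stiffness, zone-4 neutrality,
medial/lateral asymmetry, measurement-like multiplicative noise, and
exact seed-reproducibility.

It does not emulate: 3-D geometry of a real femur (neck and calcar
stress concentrations, curved shaft), implant–bone contact mechanics,
inhomogeneous bone properties, or absolute magnitudes of any published
volumetric-FE result. Consequently, passing tests demonstrate the
correctness and internal consistency of the *metrics pipeline* — not
agreement with any particular femur's absolute SSI or resorption
numbers, which depend on subject-specific geometry. Field-scale
headline numbers from volumetric studies are therefore checked as
*properties* (orderings, invariances, exact parameter recovery), while
desk-scale quantities (worked FoS values, porosity, rosette identities,
Bland–Altman examples) are checked at printed precision. In particular,
the stem elements of the beam field carry low stress (the stem's
critical neck region is outside a straight-beam model), so the safety
map's minima are large; the critical worked values enter through the
measured peak stresses instead.

## Known limitations

- Straight prismatic shaft: no anteversion, bow, or neck; zones 1 and 7
  differ only through the oblique-load asymmetry, not anatomy.
- Linear elasticity throughout; no interface micromotion or debonding.
- The dead-zone rule is an equilibrium predictor; it says nothing about
  the resorption time course, and with a band-uniform rigidity ratio the
  per-zone resorbed fraction can saturate at 0 or 1 — the taper spreads
  it, but less smoothly than subject-specific geometry would.
- The nominal porosity of the lattice coating is a design quantity
  (pore/(pore+strut)); manufactured porosity is not modeled.
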