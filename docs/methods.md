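# Methods

## Model overview

`tkrwear` predicts volumetric wear of the ultra-high molecular weight
polyethylene (UHMWPE) insert of a total knee replacement over millions of
gait cycles.  The chain is: activity kinematics → per-step contact pressure
→ per-step relative sliding → per-cycle frictional-work tensors and
cross-shear → wear coefficient → nodal linear wear → periodic worn-surface
update.  The same wear law, driven by a multidirectional pin-on-plate
simulation, predicts screening-test wear rates.

### Wear law

Per cycle, `W = A · S · C` and nodally `δ = S · C`, with

    C(CS, P/E) = a (1 − e^{−b·CS}) (c + d (P/E)^e),

defaults a = 1.47e-9, b = 116.21, c = 0.84, d = 450.23, e = 1.49 — the
fitted surface for moderately cross-linked (5 Mrad) GUR 1020 UHMWPE.  C is
dimensionless; with A in mm², S in mm, W is mm³.  C vanishes at CS = 0:
unidirectional sliding is treated as (nearly) non-wearing, consistent with
the order-of-magnitude gap measured between unidirectional and
multidirectional pin tests.

### Cross-shear ratio

Each node accumulates a symmetric 2×2 tensor in its tangent plane,
`M = Σ μ p a |ds| û ûᵀ` over the sliding increments of one cycle.  The
principal molecular orientation (PMO) is defined as the eigenvector of the
larger eigenvalue — the direction accruing the most frictional work — and
CS = λ_min/(λ_min + λ_max) ∈ [0, 0.5].  This eigen-definition is basis
invariant and is cross-checked in the tests against a brute-force
orientation scan.  Nodes with zero accumulated work have undefined CS and
accrue zero wear.  The CS aggregation window is one full cycle (two-pass
scheme: tensors first, wear second); the published description computes
wear per cycle from nodal histories without defining the window, so the
cycle window is this package's explicit choice.

For the in-phase pin-on-plate rig (plate x(t) = (L/2)cos 2πft, pin
θ(t) = Θ cos 2πft), the centre-point cross-shear has the closed form
CS = 1/2 − sin(2Θ)/(4Θ), which reproduces the published per-condition
values (±30° → 0.087, ±15° → 0.022 (we obtain 0.0226), ±45° → 0.18,
±10° → 0.010).  Face-averaged CS (area-weighted over a 16×32 polar grid)
differs from the centre value by well under 1% of CS for these conditions;
both are reported.

### Contact

The commercial FE stage of the original workflow is replaced by an elastic
foundation: pressure p = K · pen / h with K = (1−ν)E/((1+ν)(1−2ν)) and
layer depth h (default the 10 mm insert thickness).  Penetration is
measured along the superior axis by vertical projection of the rigid
counterface onto the insert vertices (robust, aligned with the load axis).
Equilibrium in vertical translation and adduction–abduction rotation about
the (7%-of-width medially offset) load axis is a damped two-variable Newton
iteration with analytic Jacobian and a bisection fallback; AA enters the
gap in small-angle linearisation.  Tolerances: |ΣpA − F| ≤ 0.1% F and
|moment| ≤ 0.1% F × 1 mm.

For a rigid ball on a flat specimen the layer depth can be calibrated so
the foundation contact radius equals the Hertz radius
(h = πK a_H⁴ / (4FR)); the mesh solution then reproduces the Hertz contact
area to ~1% at grid 96.  For the knee the default h = 10 mm is used — the
conforming curved-on-curved contact has no Hertz reference, and foundation
models with h = insert thickness are the standard desk-scale substitute.

### Geometry

No proprietary implant CAD is used.  The synthetic insert has two
symmetric dishes (sagittal arc radius 45 mm + frontal arc radius 25 mm,
crossed-arc height field); the femoral component is a torus segment per
condyle about the flexion axis (distal radius 32 mm, frontal radius 20 mm,
condyle spacing 46 mm, insert width 70 mm, thickness 10 mm).  The torus
construction makes the femoral articulating surface exactly invariant
under flexion rotation, so contact geometry depends only on AP/IE/load
while femoral material points still sweep the arc (the sliding the wear
law needs).  All radii except the 10 mm thickness are synthetic-geometry
knobs, not published implant dimensions; generated grids pass exactly
through the condyle centres and the midline so the rest poses touch at the
two theoretical lowest points.  Frame: x anterior, y superior, z medial
(left knee); mm / N / MPa / N·mm throughout; vertex areas use the
barycentric one-third split.

### Activity profiles

Only the published extrema are contractual: maximum axial loads
2600 / 2879 / 3008 N, maximum AP translations 14 / 17 / 12 mm (anterior
tibial shift negative, femoral-rollback polarity), flexion ranges 0–58° /
0–104° / 0–60°, IE ranges −5–5° / 0–5° / −5–5° for walking, deep squat and
stairs ascent.  Waveform shapes between the extrema are sinusoid
composites (double-hump stance load for walking/stairs, single hump for
squat) affinely rescaled so the extrema are bit-exact on a 128-step grid;
the published plots are not tabulated, so the shapes are documented
stand-ins, and ISO-style profiles can be supplied as CSV
(`time_s, load_N, fe_deg, ap_mm, ie_deg[, ml_mm]`).  The swing-phase
minimum load (150 N) is a synthetic choice keeping the joint lightly
loaded between peaks.  A medial-lateral translation channel (`ml_mm`,
default zero) exists so degenerate flat-on-flat verification motions can
impose orthogonal shear; knee activities do not use it.

### Knee wear loop

The 1 s cycle is divided into 128 steps (configurable).  One
representative cycle is solved per update block; nodal depths scale
linearly by the block length (default 500,000 cycles) and vertices recede
along the inward normal before the next block.  No re-meshing is done —
desk-scale depths are far below element size.  Blocks assume frozen
contact within the block; the update interval is exposed so the
sensitivity can be checked (halving the interval changes total wear by
< 5% on the test fixture).  Geometry update uses each block's current
vertex areas for the volumetric bookkeeping, so Σ δ·area = W holds to
1e-9 relative per block.

### Pin-on-plate

Nominal (uniform) pressure load/(π(d/2)²) on the pin face, matching the
published "nominal contact stress" convention; per-cycle sliding distance
is the centre-point path length (2 × stroke; pin rotation adds nothing at
the centre).  Face-averaged CS is area-weighted over a polar sample grid
(default 16 radii × 32 angles; stable to < 2% against 32×64).  Predicted
wear rate is A·S·C per cycle × 10⁶ (mm³/Mc).  Gravimetric reduction:
C = (Δm/ρ)/(A·S_total) with ρ = 0.93 mg/mm³ and two weeks ≡ 660,000
cycles; group statistics use t-based 95% confidence intervals (one-way
ANOVA provided as a convenience).

The bundled 12-condition test matrix was reconstructed from the published
table by requiring stress = load/(π(d/2)²) and P/E = stress/553 at printed
precision (pins 5/5/4/3/3/2 mm with 80/216/252/212/283/252 N at CS 0.087;
the 11 MPa series at CS 0, 0.01, 0.022, 0.18; 4 and 80 MPa at CS 0.01).

### Coefficient-surface fitting

`C = a(1−e^{−bCS})(c + d x^e)` has an exact scale degeneracy
a ↔ (c, d), so the scale a is held fixed (default 1.47e-9) and b, c, d, e
are fit by nonlinear least squares on C/a (residuals O(1); raw C ~1e-9
starves gradient-based stopping rules).  Initialisation b = 100, c = 1,
d = 400, e = 1.5 with five seeded random restarts on failure.  At least
five observations spanning both axes are required; all-constant CS or P/E
raises an identifiability error.

### Coefficient of determination

`r_squared` is the squared Pearson correlation between predicted and
observed.  This convention is deliberate and documented prominently: for
the published activity wear rates (4.5, 3.7, 5.6 predicted vs 5.8, 3.5,
7.1 measured mm³/mc) it gives 0.94, whereas 1 − SS_res/SS_tot gives ≈ 0.40;
only the correlation convention reproduces the published statistic.  It is
symmetric and offset-insensitive — it measures trend agreement, not
absolute agreement.

### Inverse material procedures

*Poisson's ratio.*  A 12 mm × 10.2 mm cylinder under 1 mm compressive
displacement: displacement control makes the contact area independent of
E.  The full boundary-value problem is replaced by an axisymmetric
bonded-end barreling approximation — a parabolic lateral bulge pinned at
the ends whose magnitude conserves the elastic volume change
ΔV = −V₀ ε (1−2ν), with a fixed fraction (0.5) of the near-end bulge
folding onto the platen as extra footprint.  ν = 0 gives exactly the
nominal face area.  Only the strict monotonicity of area in ν (hence the
invertibility) is contractual; absolute agreement with any particular
measured area is not claimed.  End friction in the physical test is
unknown; bonded ends are assumed.

*Equivalent modulus.*  A rigid 63.5 mm ball on a 10 mm flat specimen at
the 500 N peak of the 0–500 N sinusoidal load (peak, not mean, because the
contact area is measured under dynamic loading; creep is absorbed into the
"equivalent" modulus).  Area from the Hertz-calibrated foundation backend,
measured as the spherical-cap area 2πR·d of the solved peak penetration
(smooth in E where the vertex-area sum is mesh-quantised); strictly
decreasing in E.  Inversion uses monotone PCHIP interpolation and refuses
extrapolation.

## Problem sizes and determinism

Tests and examples run desk-scale configurations: implant grids 32–48,
8–64 steps per cycle, 0.1–1 Mc totals; the full published protocol
(3 Mc walking + 1 Mc squat + 1 Mc stairs at grid 64+, 128 steps) is a
documented long-running mode of the same code path.  Everything is
deterministic given a configuration; the only stochastic component is the
fit multi-start, controlled by a single seed (CLI `--seed`, default 0).

## What the synthetic data does and does not show

The synthetic geometry reproduces moderately conforming curved-insert
contact and the qualitative structure of the published results (wear
concentrated in stance, cross-shear generated by IE rotation + AP
translation, medial bias under the offset load), but not the absolute
published knee wear rates or per-activity contact areas — those require
the proprietary implant shape.  Accordingly the knee-loop acceptance
checks are property-based (Archard-limit closed form under constant CS,
volumetric conservation, force balance, CS bounds, symmetry and frame
independence) rather than value-based.  Waveform shapes, the swing load,
and the barreling fold-over fraction are likewise synthetic stand-ins;
conclusions that depend on them are flagged above.

## Known limitations

* Linear-elastic insert; no creep or plastic deformation (these are known
  to matter in high-demand activities and are absorbed only crudely into
  the equivalent modulus).
* Elastic foundation has no shear coupling between springs; accuracy is
  anchored to Hertz for ball-on-flat, not verified against FE for the
  conforming knee contact.
* Counterface roughness effects and lubricant chemistry are out of scope.
* AA equilibrium is linearised in the rotation angle (valid for the <~2°
  rotations encountered).
* Frame independence holds for rotations about the load (vertical) axis;
  penetration is always measured along the load axis by construction.
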