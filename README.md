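# tkrwear

Pre-clinical wear simulation for total knee replacements (TKR) with a
cross-shear- and contact-stress-dependent polyethylene wear law.

Polyethylene wear is the dominant long-term failure mode of knee
replacements, and classic Archard-style models with a single literature
wear factor transfer poorly between activities.  `tkrwear` implements a
combined framework in which the wear law's inputs are measured quantities:

* **Wear law.** Wear volume per cycle follows the contact-area form of
  Archard's law, `W = A · S · C`, with linear depth `δ = S · C`.  The
  non-dimensional wear coefficient depends on the cross-shear ratio CS and
  the non-dimensional contact stress P/E:

  `C(CS, P/E) = a · (1 − exp(−b·CS)) · (c + d·(P/E)^e)`

  with the fitted surface for moderately cross-linked UHMWPE
  (a = 1.47·10⁻⁹, b = 116.21, c = 0.84, d = 450.23, e = 1.49) as default.
* **Cross-shear.** Per node, a 2×2 frictional-work tensor
  `M = Σ μ·p·a·|ds|·û ûᵀ` accumulates over a motion cycle;
  CS = λ_min/(λ_min+λ_max) is the fraction of frictional work perpendicular
  to the principal molecular orientation (the major eigenvector), bounded in
  [0, 0.5].
* **Contact.** An elastic-foundation (Winkler) layer with confined modulus
  `K = (1−ν)E/((1+ν)(1−2ν))` replaces a full FE contact stage; a Hertzian
  closed form anchors its accuracy.  Load and varus–valgus moment
  equilibrium are solved per step of a 128-step, 1 s gait cycle, with the
  load axis offset medially by 7% of the insert width.
* **Inputs.** Compressive material constants E = 553 MPa, ν = 0.32
  (plus ρ = 0.93 mg/mm³, μ = 0.04); activity profiles for walking, deep
  squat and stairs ascent generated from published extrema or read from
  CSV; a bundled multidirectional pin-on-plate test matrix (nominal
  stresses 4–80 MPa, CS 0–0.18).
* **Inverse procedures.** Calibration curves recover ν from the end-face
  contact area of a compressed cylinder (E-independent by displacement
  control) and the equivalent elastic modulus from a ball-on-flat contact
  area at the 500 N peak of a dynamic load.

The proprietary implant geometry used in the original experiments is
replaced by a parametric synthetic insert/femoral pair (curved conforming
condyles), so absolute knee wear rates are illustrative; the pin-on-plate
worked values, the wear-law algebra, the validation statistic and the
inverse procedures are quantitative.

## Worked example

Simulate the bundled pin-on-plate matrix:

```sh
$ tkrwear pop --out pop.csv
12 conditions -> pop.csv
```

First rows of `pop.csv` (columns abridged):

```
pin_diameter_mm load_N stroke_mm rotation_deg stress_mpa p_over_e    cs   wear_rate_mm3_per_mc
5               80     28        30           4.07437    0.007368 0.086591 1.84105
5               216    28        30           11.0008    0.019893 0.086591 3.48098
5               216    28        0            11.0008    0.019893 0.000000 0.00000
5               216    10        10           11.0008    0.019893 0.010107 0.859125
```

The 28 mm / ±30° in-phase condition gives a face-averaged cross-shear
ratio of 0.087; pure reciprocation gives CS = 0 and therefore zero
predicted wear; the 10 mm / ±10° condition gives CS = 0.010.  `stress_mpa`
is the nominal load over the pin face (80 N on a 5 mm pin ≈ 4 MPa, i.e.
P/E = 0.007 with E = 553 MPa).

Compare predicted and experimental activity wear rates:

```sh
$ tkrwear validate pred.csv exp.csv --out report.csv
r^2 = 0.94 (units mm^3/mc) -> report.csv
```

where `pred.csv` holds 4.5 / 3.7 / 5.6 mm³/mc (walking / deep squat /
stairs ascent) and `exp.csv` 5.8 / 3.5 / 7.1 mm³/mc: the squared Pearson
correlation between them is 0.94.

Run the knee wear loop on the synthetic implant (two 0.5 Mc blocks of
walking, 64 steps per cycle, grid 48):

```sh
$ tkrwear knee --config knee.yaml --out-dir knee_out
mean wear rate 12.58 mm^3/Mc -> knee_out
```

`knee_out/` contains per-block wear rates (12.84 and 12.32 mm³/Mc here —
the surface update slightly relieves contact), a per-step cycle summary
(contact area, average stress, percent wear contribution), the per-vertex
wear depths and the worn insert as STL.  Absolute values depend on the
synthetic geometry.

The same functionality is available as a library
(`tkrwear.run_pop`, `tkrwear.run_simulation`, `tkrwear.fit_coefficient_model`,
`tkrwear.build_poisson_curve`, ...).

## Layout

```
src/tkrwear/
  geometry.py      meshes, STL I/O, synthetic implant + rig primitives
  contact.py       elastic-foundation contact, Hertz oracle, equilibrium
  kinematics.py    activity profiles, pin-on-plate trajectories, sliding
  tribology.py     cross-shear tensor, wear law, coefficient-surface fit
  pin_on_plate.py  pin-on-plate simulation + gravimetric data reduction
  knee_sim.py      iterative TKR wear loop with worn-surface update
  materials_id.py  inverse recovery of nu and E from contact areas
  cli.py           pop / fit / knee / material / validate commands
docs/methods.md    model assumptions, numerical choices, limitations
```
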