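# Methods

## The problem

Biometers, topographers and anterior-segment tomographers report the
Chang-Waring (CW) chord: the 2-D offset between the centre of the
entrance pupil and the first Purkinje reflex (PI), as seen coaxially
under far fixation. Angle alpha — the angle between the eye's optical
axis and its visual axis — is not directly measurable, but it is the
quantity clinicians actually reason about when centring refractive
procedures. `cwchord` computes the CW chord from anterior-segment
biometry and an incident beam angle by exact raytracing, and distils the
relation into a bidirectional linear translation so that a measured CW
chord can be converted to an estimate of angle alpha with a single
matrix operation.

## Optical model

Each eye is reduced to the anterior segment of a schematic eye:

* two rotationally symmetric conic surfaces, coaxial with the Z axis —
  corneal front (radius `Ra`, asphericity `Qa`, apex at the origin) and
  back (`Rp`, `Qp`, apex at `z = CCT`);
* refractive indices 1.0 / 1.376 / 1.336 (air / stroma / aqueous), the
  Liou-Brennan values;
* a circular aperture stop of diameter `Pup`, decentred by
  `(Pup_X, Pup_Y)`, in the plane `z = CCT + ACD`.

Coordinates: origin at the corneal front apex, X right, Y superior, Z
towards the retina; mm and degrees throughout. Right eyes are mirrored
in X (`Pup_X → -Pup_X`) so every analysis runs on left-normalised eyes
with +X temporal. The fixation beam arrives from the nasal side: its
direction is `Ω(I_X, I_Y)·(0,0,1)` with `Ω = R_y(-I_X)·R_x(I_Y)`, so
`I_X < 0` gives a temporal (+X) direction component. The sign convention
is pinned by an observable: for a spherical cornea of radius 7.76 mm and
`I_X = -5°` the Purkinje landmark must sit at `x = -0.679` mm, which the
analytic oracle in the test suite checks in closed form.

**Stop-plane placement.** The tabulated anterior chamber depth is read
as the aqueous depth, placing the stop at `z = CCT + ACD` rather than
`z = ACD`. This calibration is empirical: with the cohort-mean biometry
(`Ra 7.76, Qa -0.22, Rp 6.56, Qp -0.11, CCT 0.55, ACD 3.36, Pup 3.24,
Pup_X -0.30, Pup_Y -0.10` and beam `(-5.03°, 0.01°)`) it reproduces the
reference cohort's landmark means (`PupC ≈ (-0.35, -0.10)`, Purkinje
`≈ -0.68`, `CW ≈ (0.33, -0.10)` mm), the fitted pupil-term coefficient
(≈1.02) and the entrance-pupil magnification (~14%) simultaneously; the
front-apex placement reproduces the landmarks but yields a magnification
of only ~11.5%.

## Landmarks and the chord

* **Pupil-centre ray** — the incident-direction ray whose refracted
  continuation passes exactly through the stop centre, found by a 2-D
  root solve on the lateral offset (Powell hybrid, apex start, residual
  tolerance 1e-9 mm at the stop plane). The landmark coordinate is the
  refracted (aqueous) chief ray's lateral position at the entrance-pupil
  depth `z_E = B/A` (from the apex-to-stop ABCD matrix) — the depth at
  which an instrument focused on the pupil localises its centre. This
  readout, not the incident ray's apex-plane crossing, matches both the
  reported pupil-landmark means and the ≈1.02 pupil-term regression
  coefficient of the reference cohort (the apex-plane crossing readout
  would imply ≈1.12, the raw entrance-pupil magnification).
* **Purkinje ray** — the incident-direction ray meeting the corneal
  front surface perpendicularly (refracted direction equals incident
  direction; residual `1 - cosθ ≤ 1e-12`), read at its apex-plane
  crossing. For `Q > -1` and beams within ±9° the perpendicular point is
  unique in the central zone and the solver's basin from the apex start
  selects it.
* Both landmarks are rotated about the apex by `Ω⁻¹` (unit-quaternion
  composition of the two axis rotations) onto the plane perpendicular to
  the beam — the frame a coaxially aligned instrument reports — and the
  chord is their difference, `CW = PupR - PurkinjeR`, exactly by
  construction.

Both solvers are deterministic (fixed start, no randomness) and their
solutions are verified in the test suite against an independent
refine-on-argmin dense-grid search to 1e-6 mm on random eyes.

## Entrance-pupil footprint

A collimated bundle (hexagonally packed, uniform areal density, default
10 000 rays over a 7 mm disc perpendicular to the beam; tests and batch
runs use 2 000–4 000 for speed) is traced to the stop plane; rays inside
the aperture are marked and their incident-segment crossings of the apex
plane form the entrance-pupil footprint. The "constraining ellipse" is
the second-moment ellipse of those points: centre = centroid, axes =
eigenvectors of the 2x2 central moment matrix, diameters `4·√λ` — the
uniform-filled-disc convention, so a uniformly sampled disc of diameter
`d` returns `D = d` (exact up to grid resolution; the ellipse scaling is
a convention of this package, chosen for that calibration property).
Reported diameters/orientations come from the fit on the derotated
(instrument-view) points, so `|A_long - A_short| = 90°` exactly;
magnification is `D_long/Pup - 1` per eye.

Note one deliberate asymmetry: the footprint lives at the apex plane
while the pupil-centre landmark is read at the entrance-pupil depth, so
the ellipse centre and the pupil landmark differ by ≈`tan(I)·z_E`
(≈0.24 mm at 5°). The footprint centroid is instead consistent with the
chief ray's apex-plane crossing, which is what the test suite checks.

## Synthetic population

No clinical dataset ships with the package (a `status`-column filter
hook in the CSV reader stands in for the usual pseudophakic / mydriasis
/ ectasia / incomplete exclusions). The canonical simulation input is a
synthetic population emulating a large tomographer cohort:

| parameter | mean | SD | truncation |
|---|---|---|---|
| Ra (mm) | 7.76 | 0.28 | [6.77, 8.83] |
| Qa | -0.22 | 0.13 | [-0.70, 0.25] |
| Rp (mm) | 6.56 | 0.25 | [5.67, 7.49] |
| Qp | -0.11 | 0.11 | [-0.55, 0.28] |
| CCT (mm) | 0.55 | 0.04 | [0.41, 0.68] |
| ACD (mm) | 3.36 | 0.40 | [1.87, 4.79] |
| Pup (mm) | 3.24 | 0.81 | [0.83, 6.28] |
| Pup_X (mm) | -0.30 | 0.21 | [-1.12, 0.42] |
| Pup_Y (mm) | -0.10 | 0.19 | [-0.78, 0.58] |

Truncation bounds are the cohort's empirical 5%/95% quantiles widened by
two SDs. `Ra` and `Rp` are drawn jointly with correlation 0.85 (front
and back radii are strongly coupled in real corneas; the asphericities
are not, and are drawn independently). All sampling is exact rejection
sampling from a single seeded `numpy` Generator, so populations are
bit-reproducible.

Incident angles follow the Liou-Brennan fixation geometry:
`I_X ~ N(-5°, 2°)` rejected outside `[-9°, -1°]` and `I_Y ~ N(0°, 2°)`
rejected outside `[-4°, 4°]`. The symmetric ±2σ truncation gives a
closed-form SD of 1.759° for `I_X`. The stated `I_Y` bounds imply the
same ≈1.76° spread, noticeably wider than the ≈1.47° the reference
cohort reports (consistent with an effective ±3° truncation there); the
stated bounds are implemented, and the vertical-angle SD is therefore
not treated as a checked quantity. Consequently the simulated `CW_Y` SD
(~0.30 mm) slightly exceeds the reference ~0.26 mm; `CW_Y`'s *mean* is
insensitive to this.

What the generator does **not** emulate: any covariance beyond Ra-Rp
(real biometry correlates ACD with Pup and age, etc.), measurement
noise, per-eye pupil-size dependence of the pupil centre, or laterality/
age structure. Passing population checks therefore validate the optics
and the fitting machinery under the stated marginals, not the joint
distribution of any clinical population.

## Translation model

Candidate effects for each chord component are
`Ra, Qa, Rp, Qp, CCT, ACD, Pup_X, Pup_Y, Pup, I_X, I_Y`. Selection is
classical forward/backward stepwise regression on term p-values
(enter < 0.05, remove ≥ 0.05, max 100 iterations, stop when the RMS
error improves by < 1e-12 or the coefficient step is < 1e-9). P-values
are the standard OLS t-tests (statsmodels). The final model is OLS per
component with unselected coefficients fixed at zero, stored as 2x10
matrices over `(1, Ra, Qa, Rp, CCT, ACD, Pup_X, Pup_Y, I_X, I_Y)`; a
regressor selected outside that basis (`Qp`, `Pup` — in practice neither
enters) is reported in the diagnostics only. The exact membership of the
marginal biometry terms (p near 0.05) varies with the simulated
population; the load-bearing coefficients — `I_X` in the `CW_X` row
(≈ -0.128 mm/deg, equal to the raytracer's finite-difference chord
sensitivity on the mean eye) and `Pup_Y` in the `CW_Y` row (≈ 1.02) —
are stable and are what the acceptance checks pin down.

Because each chord component depends on exactly one angle component,
the model inverts algebraically:
`I_X = (CW_X - b₀ - Σ biometry terms)/coef(I_X)`, likewise `I_Y`. The
reversal is exact (forward∘reverse is the identity on angles) and
involutive. The bundled `published_2022` coefficient set is the
reference fit from a large clinical cohort; its transcription notes
(restored intercept signs, second forward row reconstructed from the
reverse matrix via the inversion algebra) are embedded in the JSON
provenance block.

## Numerical choices

* Ray-conic intersection in closed form (quadratic), apex branch chosen
  by smallest `|z - z_apex|`; surface residual ≤ 1e-10 mm. Misses yield
  NaN in vectorised bundles and an exception for single rays.
* Ray origins anchored at `z = -10` mm (any negative value is equivalent
  for collimated geometry).
* Degenerate inputs (non-positive radii/pupil, `ACD ≤ CCT`, unknown
  laterality) are rejected at construction, not clamped; batch runs flag
  per-row failures in an `error` column instead of aborting.
* Total internal reflection raises (cannot occur air → cornea).
* Problem sizes for the shipped acceptance computation: 2 000 eyes for
  chord statistics (Monte-Carlo SE ≈ 0.007 mm on mean CW_X), 300 eyes x
  4 000 rays for ellipse statistics, 100 000 draws for angle statistics.

## Known limitations

* Toric/free-form or tilted corneal surfaces, the crystalline lens,
  wavelength dependence, diffraction and Stiles-Crawford weighting are
  out of scope; consequently angle *kappa* (which needs the lens for the
  nodal points) cannot be derived.
* The linear translation is a local model for the simulated parameter
  ranges (beams within ~9°, physiological biometry); extrapolation
  degrades quietly.
* The entrance-pupil magnification reported here (~13.5-14%) reflects
  the exact two-surface trace with the uniform-disc ellipse scaling;
  reference cohort values quoted as "around 15%" depend on an
  unspecified ellipse-scaling convention and should be compared with
  ±2-3 percentage points in mind.
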