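# Methods

`doseaccqa` implements a phantom-based quality-assurance procedure for the
dose-accumulation step of online-adaptive radiotherapy platforms, together
with the synthetic phantoms, session doses and deformation fields needed to
exercise it end to end without any clinical data.

## The procedure under test

Adaptive platforms recompute ("reconstruct") the delivered dose on each day's
anatomy and then map it back to the planning CT through a rigid transformation
followed by a deformable vector field (DVF), summing the per-fraction
propagated doses into an accumulated dose. The QA question is whether that
chain is applied as intended. The check used here is the manual one a
physicist can perform with exported transforms:

1. per fraction, read the mean dose of every session structure from the
   session dose and sum over fractions (the *manual sum*);
2. independently, apply the rigid matrix, then the DVF, to each session dose,
   sum on the reference frame, and read the same structures there
   (the *accumulated* value);
3. compare per structure as `100 * (accumulated − manual) / manual`, and
   compare the full 3-D volumes with a gamma analysis at 2%/2 mm.

Action levels: ±2% for target structures, ±3% for organs at risk. Structures
whose contours deliberately traded places with the target are reported but
excluded from the verdict: with target-prioritised, structure-guided
deformation their dose history is scrambled by construction, and a large
discrepancy there is the expected signature, not a failure.

Inside this package the "platform" leg is the composed single-resampling
accumulation and the "manual" leg is the two-step rigid-then-DVF chain; the
two share transforms but not interpolation order, so their agreement is a
meaningful end-to-end consistency check rather than a tautology.

## Geometry and conventions

* World frame: LPS, millimetres; voxel values sit at voxel centers; arrays are
  indexed `(x, y, z)`.
* Grids are axis-aligned; rotations live only in 4×4 rigid matrices.
* All warps are pull-back: `out(x) = src(T(x + d(x)))`. The DVF convention is
  **pull** (displacement added to the output-frame point before sampling).
  Vendor exports with a push convention can be converted with the fixed-point
  inverter (`convert_convention`), since the push and pull dialects are exact
  inverses of each other.
* Interpolation: trilinear for dose/CT, nearest-neighbour for masks.
  Out-of-grid fill: 0 cGy for dose, −1000 HU for CT, `False` for masks.
* Dose is cGy everywhere; DICOM RT Dose (Gy) is converted at the boundary.
* Identity resampling (same lattice, identity transform, zero field) is
  short-circuited to a bitwise copy, so control pipelines conserve dose
  exactly rather than to interpolation error.

## Synthetic phantoms

### Insert-swap cylinder

A water-equivalent cylinder (radius 90 mm, length 100 mm, 2 mm grid) carries
eight 15 mm-radius inserts on a 60 mm ring at clock positions
{6, 7, 5, 9, 10, 11, 12, 1}; 12 o'clock is anterior and hours increase
clockwise viewed from the feet. The reference target (GTV) is the 6 o'clock
insert, with a concentric boost sub-cylinder and a 5 mm-expanded PTV; the
other seven inserts are OAR1–OAR7 (OAR1 at 7 o'clock, OAR2 at 5 o'clock).
The phantom is rigid: across fractions only the *contours* move. Fraction 1
re-draws the target at 7 o'clock (OAR1 takes the vacated 6 o'clock slot),
fraction 2 at 5 o'clock (OAR2 to 6 o'clock). Sessions carry random rigid
setup offsets (≤ 3 mm, ≤ 2°).

The platform's structure-guided DVF is emulated by a rotation about the
phantom axis through the target's clock-hour change, windowed radially to the
insert-ring annulus (flat over ±20 mm of the ring, cosine falloff over the
next 20 mm). Because the rotation angle depends on radius only, the map is
exactly volume-preserving and globally invertible; every ring structure is
dragged along with the target. An angularly localised field that matched the
target while leaving its neighbours in place was considered and rejected: at
these insert spacings it cannot keep a positive Jacobian (a 30° match would
have to decay within ~1 mm of arc), i.e. it would not be a usable
deformation model at all.

### Pelvis surrogate

An elliptical body (240 × 180 mm) with an ellipsoidal prostate, bladder
(anterior–superior), rectum tube (posterior), bowel volume (superior) and two
femur cylinders; organ masks are carved to be pairwise disjoint; the PTV is a
5 mm prostate expansion. The deformed planning CT is produced by pull-back
warping the phantom CT with a Gaussian displacement bump
`d(x) = peak · exp(−|x−c|² / 2σ²)` centred inside the bladder (or rectum),
pointing toward the prostate, with σ = 15 mm and |peak| = 8 mm. Sessions show
the original anatomy under small setup offsets, so the same Gaussian field is
the reference-to-session deformation of every fraction. A Gaussian bump folds
when `|peak|·e^{−1/2}/σ ≥ 1`; specs are rejected at `|peak|/σ ≥ 1.6`, and the
defaults (ratio 0.53) are comfortably diffeomorphic. The control scenario
uses identity rigids and a zero field.

The published per-fraction target means are ~218–221 cGy, so the default
prescription is 220 cGy per fraction.

### Session-dose synthesizer

Instead of a treatment planning system, each session dose is a conformal
surrogate: the prescription delivered through an aperture 10 mm outside the
PTV, blurred by a 4 mm Gaussian penumbra, on top of a 4 cGy in-body scatter
floor, normalised so PTV D98 equals the prescription, plus seeded Gaussian
noise (SD 2 cGy) clipped at zero. The aperture margin puts the 50% penumbra
line outside the PTV (as an optimised plan would), which makes the standard
coverage objectives (PTV D98% ≥ 100%, D_max < 110%) satisfiable; the scatter floor gives distal
organs-at-risk a small but stable nonzero dose so their percent differences
are well conditioned, mirroring the 20–35 cGy background a real delivery
produces. What this surrogate does **not** model: CT/CBCT texture and
artifacts, beam/MLC geometry, heterogeneity corrections, or optimizer
trade-offs — so passing tests certify the *accumulation machinery*, not
dosimetric realism.

## Numerical choices

* Trilinear sampling is one hand-written kernel shared by resampling and the
  gamma search; `scipy.ndimage.map_coordinates` serves as an independent
  oracle in the tests rather than as the implementation.
* DVF inversion: fixed-point iteration `d⁻¹(x) ← −d(x + d⁻¹(x))`, relaxation
  1.0, tolerance 0.1 mm, max 50 iterations, residual checked on an interior
  region eroded by the maximum displacement; non-convergence raises an error
  carrying the residual. Displacements are edge-clamped outside the grid to
  keep boundary iterations stable.
* Jacobian determinants use central differences (`numpy.gradient`), so
  "positive everywhere" is checked numerically, not symbolically.
* Gamma: global normalization to the reference maximum (switchable to local),
  10% low-dose threshold (0 disables), search radius 3 × DTA, candidate
  lattice step DTA/10 with trilinear evaluated-dose interpolation. The
  minimization is a numba-compiled per-voxel scan over distance-sorted
  candidates; a voxel stops once its running minimum is at or below the
  purely spatial term of every remaining candidate, a prune that cannot
  change the minimum, so the optimized search equals the exhaustive
  brute-force oracle bit for bit. Excluded voxels store NaN and are left out
  of the passing rate. Degenerate inputs (no dose above threshold, mismatched
  lattices) raise instead of returning vacuous rates.
* DVH: voxel-counting, no sub-voxel weighting; D_x% by linear interpolation
  between sorted-voxel ranks (numpy linear-percentile convention); objective
  comparison operators are taken literally from the objective strings at
  float64.
* The per-structure "fraction dose" is the mean voxel dose (the published
  tables do not state mean vs median; mean is used and labelled as such).

## Problem sizes and determinism

Default grids are 2 mm: ~0.5 M voxels for the cylinder, ~0.6 M for the
pelvis; a full scenario (two fractions) generates in ~1 s and a complete QA
report runs in seconds to a couple of minutes depending on how disjoint the
compared volumes are (gamma cost is dominated by failing voxels, which scan
the whole candidate sphere). Oracle-equivalence checks run on 12³ grids with
a 0.4 mm candidate lattice so the exhaustive reference stays cheap. All
generators are pure functions of `(spec, seed)`; the same seed reproduces
bit-identical bundles and reports.

## Known limitations

* No deformable *registration* is implemented or evaluated — the platform's
  DIR is a black box to this QA method; known synthetic fields stand in.
* Published gamma passing rates for a specific commercial system depend on
  its proprietary doses and vector fields and cannot be reproduced here; only
  the rigid-vs-deformable ordering and the target-vs-swapped-OAR contrast are
  asserted.
* Axis-aligned grids only (no direction cosines); no 4-D/time-resolved data;
  no biological accumulation (EQD2/BED); DICOM RT Structure Set polylines are
  out of scope — binary masks are the exchange currency.
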