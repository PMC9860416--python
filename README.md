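# doseaccqa

Phantom-based quality assurance of the **dose accumulation** step in
online-adaptive radiotherapy.

Adaptive platforms replan treatment on each day's anatomy, recompute the
delivered ("session") dose, and map it back to the planning CT through a
rigid transformation followed by a deformable vector field (DVF), summing
over fractions into an accumulated dose. Whether that chain was applied as
intended is a commissioning and periodic-QA question for the physicist.
`doseaccqa` provides:

* **synthetic QA phantoms** — a cylindrical electron-density phantom whose
  target contour hops between insert clock positions across adaptive
  fractions (with the displaced OAR contour taking the vacated slot), and an
  anthropomorphic pelvis surrogate whose planning CT is perturbed by a
  Gaussian displacement bump centred inside the bladder or rectum;
* **manual accumulation primitives** — pull-back rigid and DVF warping
  (`out(x) = dose(T(x + d(x)))`), field composition, fixed-point DVF
  inversion, Jacobian-determinant checks;
* **verification metrics** — per-structure mean-dose difference tables
  (`100·(accumulated − manual)/manual`) with ±2% target / ±3% OAR action
  levels, DVH metrics (D_x%, D_max, V_x%), and 3-D gamma analysis at 2%/2 mm
  with an exhaustive brute-force oracle;
* **standard-format I/O** — NRRD/MetaImage volumes and vector fields,
  DICOM RT Dose, JSON rigid matrices, and scenario-bundle directories;
* a CLI: `simulate`, `accumulate`, `gamma`, `report`.

## Worked example

```bash
doseaccqa simulate --scenario insert_swap --fractions 2 --seed 1 --out scratch/swap
doseaccqa report --bundle scratch/swap --out scratch/swap_qa
```

The report's mean-dose table for seed 1 (abridged; values in cGy):

```
Structure  Fraction 1  Fraction 2  Manual sum  Accumulated  Difference, %
GTV           223.0       223.0       445.9        445.8       -0.0
boost         223.1       223.1       446.2        446.2        0.0
OAR1           83.1         3.9        87.0        164.3       88.9
OAR2            4.0        77.8        81.8        165.4      102.2
OAR3            4.0         4.0         7.9          7.8       -1.2
OAR7            4.0         3.9         7.9          7.9       -0.5
```

Reading it: the target (GTV) and boost accumulate correctly — the manual sum
of per-fraction means matches the accumulated dose within 2% — because the
deformation maps the re-contoured target back onto its reference insert.
OAR1 and OAR2, whose contours traded places with the target in fractions 1
and 2, are dragged through the dose history of the wrong insert and disagree
by ~90–100%; the report classifies them `swapped_oar_excluded` (an expected
signature of target-prioritised structure-guided deformation, not a QA
failure), while distal OARs stay within the ±3% action level. The exit code
is 0 because every non-excluded verdict passes.

The report also prints gamma passing rates (GPR, 2%/2 mm) between the
two-step (rigid then DVF) and composed single-resampling accumulations, and
between rigid-only and deformable accumulation. On the pelvis scenario the
former exceeds 99% while dropping the deformable leg costs ~14 GPR points —
deformation matters even for modest, clinically plausible organ shifts.

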