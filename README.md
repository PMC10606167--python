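# tavimetrics

Automated morphometry of the aortic valvular complex for transcatheter
aortic valve implantation (TAVI) planning.

Sizing a prosthetic aortic valve from a pre-procedural CT requires a set
of geometric measurements that are tedious to derive by hand: the area,
perimeter and diameters of the **aortic annulus** (the virtual ring through
the three leaflet nadirs), the same metrics for the **LVOT** (left
ventricular outflow tract, taken 4 mm below the annulus along the lumen
centerline), the **sinus of Valsalva** diameters, the **sinotubular
junction** (SNTJ) dimensions, and the perpendicular **heights of the
coronary ostia** above the annulus plane (low ostia raise the risk of
coronary obstruction).  `tavimetrics` computes all 22 of these scalars
from two inputs a segmentation pipeline produces upstream:

* a closed triangular surface mesh of the aortic root + left ventricle
  (STL/PLY/OBJ/VTP, coordinates in mm, LPS frame), and
* five anatomical landmarks (left/right coronary ostium; left/right/
  non-coronary leaflet nadir) as JSON.

The geometric chain is: Laplacian-based contraction of the surface onto
its lumen **centerline**; the **annulus plane** fitted through the three
nadirs; plane–mesh **cross-sections** reduced to area *A*, perimeter *P*,
centroid-chord minimum/maximum diameters, and the derived diameters
d_area = 2√(A/π) and d_perim = P/π; an **area profile** of 1 mm-spaced
transverse planes above the annulus, whose maximum locates the sinus of
Valsalva and whose stabilization point locates the SNTJ; per-sinus
diameters measured along the lines from the section centroid through the
projected nadirs; and signed point–plane distances for the coronary
heights.

The package also ships:

* `tavimetrics.phantom` — a parametric synthetic aortic-root generator
  (LVOT tube, annulus, three sinus lobes, STJ taper, ascending aorta,
  straight or curved axis) with **analytic ground truth** for all 22
  measurements, so the whole pipeline is testable without patient data;
* `tavimetrics.landmarks_post` — deterministic post-processing of
  5-channel landmark mask volumes (binarize at 0.5 → largest connected
  component → voxel centroid → LPS world coordinates);
* `tavimetrics.agreement` — method-comparison statistics for paired
  measurement tables: mean absolute relative error with the
  CI = x̃ ± Z·s/√(n−1) convention, Pearson r with Fisher-z intervals, and
  Bland–Altman limits of agreement.

## Worked example

```python
from tavimetrics import generate_phantom, run_pipeline

mesh, landmarks, truth = generate_phantom()   # default TAVI-like root
report = run_pipeline(mesh, landmarks)

print(f"annulus area      {report.annulus.area:8.2f} mm²  "
      f"(truth {truth.report.annulus.area:.2f})")
print(f"annulus perimeter {report.annulus.perimeter:8.2f} mm")
print(f"LVOT area         {report.lvot.area:8.2f} mm²")
print(f"LCH / RCH         {report.coronary.height_left:5.2f} / "
      f"{report.coronary.height_right:5.2f} mm")
print(f"sinus (LCC)       {report.sov.diameter_lcc:8.2f} mm")
print("QC flags:", report.metadata["qc_flags"])
```

prints

```
annulus area        490.52 mm²  (truth 490.87)
annulus perimeter     78.53 mm
LVOT area            407.20 mm²
LCH / RCH           14.00 / 12.00 mm
sinus (LCC)           31.00 mm
QC flags: []
```

The default phantom has a circular 12.5 mm-radius annulus (area
π·12.5² = 490.87 mm²), sinus lobes peaking at a 17 mm radius 10 mm above
the annulus (so the lobe-to-opposite-wall sinus diameter is
17 + 14 = 31 mm), and ostia placed 14 mm (left) and 12 mm (right) above
the annulus plane — the report recovers each within the mesh
discretization error.  The same pipeline runs from the shell:

```sh
tavimetrics phantom --out-dir case/           # mesh + landmarks + truth
tavimetrics measure case/phantom.stl case/landmarks.json --out report.json
tavimetrics agreement raterA.csv raterB.csv --out agreement.csv
```

## Layout

| module | contents |
| --- | --- |
| `tavimetrics.io` | mesh / landmark / report readers and writers, validation |
| `tavimetrics.centerline` | Laplacian-based contraction, plane-marching extractor, resampling |
| `tavimetrics.cross_section` | plane–mesh sections, diameters, area profiles |
| `tavimetrics.measure` | anatomical planes, the 22-measurement pipeline |
| `tavimetrics.landmarks_post` | mask-volume → landmark post-processing |
| `tavimetrics.phantom` | synthetic roots with analytic truth |
| `tavimetrics.agreement` | inter-rater agreement statistics |
| `tavimetrics.cli` | `tavimetrics` command-line entry point |

See `docs/methods.md` for the geometric definitions, parameter defaults
and numerical choices.
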