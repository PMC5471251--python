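# nussplan

Pre-operative planning of the Nuss procedure for pectus excavatum (PEX):
customized bar-shape design plus finite-element evaluation of where to
place the bar and how far to elevate the sternum.

The Nuss procedure corrects a depressed sternum by sliding a convex metal
bar under it through small bilateral incisions. Outcome depends on two
choices usually made from surgical experience alone: the bar's curve and
the intercostal space/elevation at which it acts. `nussplan` makes both
choices computable:

* **Morphometry.** Severity is the Haller index H = A/B at an axial cross
  section — maximum laterolateral diameter A over the minimum
  anteroposterior distance B from the anterior vertebral body to the
  posterior sternal surface. Plans are judged against the corrective
  criterion H ≤ 2.68 at all four measured sections (intercostal spaces
  2–5).
* **Elevation simulation.** The thorax is a 3-D Euler–Bernoulli frame
  (rigid fixed spine, cancellous-bone ribs/sternum, costal cartilage
  anteriorly); the bar is a prescribed purely anterior displacement at
  the sternal anchor node of one intercostal space. Every candidate plan
  (space × elevation grid) is solved, gated on the Haller criterion and
  on hypercorrection (B exceeding the healthy reference profile by more
  than 2 mm anywhere), and the surviving plan with the lowest maximum von
  Mises equivalent stress is selected.
* **Bar design.** A healthy reference chest is matched on gender, age and
  the expected post-operative transverse diameter A × 0.95 (transverse
  shrinkage rate A′/A ≈ 95% across a bundled 12-patient series). The bar
  curve is the reference boundary raised at the apex by the orthopedic
  distance Δ = B′ − B, constrained to be convex (signed curvature ≥ 0
  within tolerance — healthy chest walls are convex; depressed ones show
  curvature sign changes), and rounded up to a standard catalogue length.

Because CT segmentation is out of scope, all geometry comes from the
package's parametric generator: a bilaterally symmetric healthy rib cage
and a PEX variant with a controlled sternal depression (depth, width,
affected levels, asymmetry). See `docs/methods.md` for the models and
their assumptions.

## Worked example

Generate the packaged synthetic patient, measure it, and plan the
operation:

```sh
nussplan generate --kind pex --seed 1 --out pex.json --contours-out contours.csv
nussplan haller --contours contours.csv --report haller.csv
nussplan run --seed 1 --out report.json
```

which prints

```
a: A=249.94 mm B=72.14 mm H=3.465
b: A=249.30 mm B=72.01 mm H=3.462
c: A=247.81 mm B=71.03 mm H=3.489
d: A=245.36 mm B=69.70 mm H=3.520
selected: space 4, 25 mm elevation; bar 228.6 mm
```

Read: pre-operatively every section is far above the 2.68 criterion
(severe PEX, H ≈ 3.5). Of the 20 candidate plans, elevating 25 mm at the
4th intercostal space is the one that brings all four sections under the
criterion without over-elevating any of them past the healthy profile —
lower elevations fail the index, higher ones hypercorrect the
least-depressed sections — and among such plans it carries the lowest
peak stress. The designed bar, rounded up to the 9-inch (228.6 mm)
standard size, is the healthy boundary at that space raised 25 mm at the
apex; `report.json` records the full decision trace (per-plan indices,
gate outcomes, stresses) and the bar control points.

The same pipeline is available as a library:

```python
import nussplan as npl

pex, healthy = npl.synthetic_patient(seed=1)
report = npl.run_pipeline(npl.RunConfig(seed=1), pex, healthy)
print(report["selected"])          # {'space': 4, 'elevation_mm': 25.0}
print(report["bar"]["standard_length_mm"])   # 228.6
```

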