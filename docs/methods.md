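# Methods

`nussplan` plans a Nuss-procedure correction of pectus excavatum (PEX) in
four stages: morphometry, reference matching, elevation simulation, and
convex bar design. This note records the models behind each stage, the
parameters that matter, and what the synthetic study conditions do and do
not establish.

## Coordinates and morphometry

All geometry lives in a right-handed frame with x laterolateral, y
anteroposterior (anterior positive) and z craniocaudal (cranial positive);
lengths are mm. Severity is measured by the Haller index H = A/B at an
axial cross section: A is the maximum laterolateral inner chest-wall
extent and B the minimum anteroposterior distance from the anterior
vertebral body to the posterior sternal surface. B is measured along the y
axis only (the clinical measurement is axis-aligned on the CT slice), not
as a Euclidean point distance. Reported indices are rounded half-even at
the precision of the corresponding clinical table (2 decimals
pre-operative, 3 post-operative); raw values are kept at full precision.

Two derived quantities drive the design. The shrinkage rate A′/A is the
post-/pre-operative transverse-diameter ratio; across the bundled
12-patient series its mean is 95%, which is the default
`expected_shrinkage = 0.95` used when matching a healthy reference (a
patient's post-operative chest is expected to be ~5% narrower, so the
reference should match the *shrunk* diameter). The orthopedic distance
Δ = B′ − B is the sternal elevation needed to reach a target
anteroposterior distance; it sets the apex rise of the bar.

One bundled post-operative table row (5th space / 20 mm, section b) is
internally inconsistent — its printed index does not equal its own A/B
within rounding — and is excluded from arithmetic fixtures.

## Synthetic thorax model

CT segmentation is out of scope; the geometric substrate is a parametric
stand-in built to the same simplifications the structural analysis makes:
the spine is rigid (a fixed node column), ribs are planar elliptical arcs
per level closing into rings, the anterior 20% of each rib chain (by arc
length) is costal cartilage, and the sternum is a straight mid-sagittal
bar with one node per intercostal space 2–5 — the candidate bar anchors.
Sections a–d are identified with intercostal spaces 2–5. Defaults: 8 rib
levels (the number retained is a free parameter; clinical models keep
6–10), 25 mm level spacing, 24 nodes per ring, transverse diameter pinned
to `scale` at section a, and a healthy transverse/anteroposterior aspect
of 2.5 (a healthy Haller index of ~2.5). Per-level jitter (≤0.1% on the
transverse semi-axis, ≤2% on the anteroposterior one) makes each seed an
individual while preserving exact bilateral symmetry, which is built by
mirroring one half-ring in floating point.

The PEX variant displaces nodes purely posteriorly (x and z never change,
so A is exactly invariant under depression):

* axially, the full depth applies across the affected intercostal
  sections with a cos² taper one rib spacing beyond — a broad plateau
  rather than a single-peak bump, because the case-study patient's B
  deficit is nearly uniform across all four measured sections;
* laterally, a cos² bump of the given half-width (the `asymmetry`
  parameter skews the two sides);
* through the ring, the squared normalized anterior height, so the
  vertebra and posterior wall never move and the sternal node takes
  exactly the full depth.

Consequently B at every affected section is reduced by exactly
`depression_depth`. The packaged synthetic patient uses depth 28 mm,
half-width 60 mm, all four spaces affected, on a 250 mm chest — a
pre-operative Haller index of ~3.5, comparable to the bundled case study
(3.40–3.73). Cross sections are extracted by ruling the chest-wall
surface between adjacent rib rings (pointwise linear interpolation in z),
with the exact sternal anchor node substituted for the interpolated
anterior point so contour-level and model-level B agree identically.

What the generator does *not* emulate: rib obliquity (rings are planar),
asymmetric real-world torsion of the sternum, soft tissue, and
inter-individual topology variation. Tests passing on these models
validate the method's logic and numerics, not its anatomical fidelity.

## Frame finite-element model

The elevation simulation is a direct-stiffness solve over 3-D
Euler–Bernoulli frame elements (6 dof per node), one element per model
segment. Solid-element patient meshes are not reproducible without the CT
geometry; beams retain the relevant load path — the sternum is a beam
elastically restrained by rib/cartilage chains anchored on a rigid spine.
Materials are isotropic, homogeneous, linearly elastic: cancellous bone
(E = 4.55e8 Pa, ν = 0.3) for spine/ribs/sternum and costal cartilage
(E = 3.75e7 Pa, ν = 0.3). Densities (1.67e5 and 1.17e5 kg·m⁻³) are
stored verbatim from the tabulated source although their magnitudes are
physically implausible; a static solve never reads them.

Boundary conditions follow the clinical simulation: all spine nodes are
fully fixed, and the bar's action is a prescribed purely anterior
translation (the elevation, in mm) at the sternal anchor node of the
chosen intercostal space, imposed exactly by system partitioning;
rotations at the anchor stay free. The solver is a direct sparse LU; the
model is geometrically linear, so displacements and stresses scale
exactly with the prescribed elevation, and element strains above 20%
raise a validity warning. A singular constrained system is reported as a
rigid-body-mode error naming the dominant free degree of freedom.

Sections are circular: ribs and cartilage r = 5 mm; the sternum r = 9 mm,
a circle whose second moment is comparable to a 25 × 12 mm sternal plate.
The stiff sternum matters qualitatively: clinical simulations show an
elevation applied at one space carrying the *whole* sternum along
(post-operative B rises by nearly the full elevation at all four
sections), which requires the sternal bar to be rigid relative to the
rib-spring foundation; a 5 mm sternal rod would instead localize the
correction and oscillate along the beam-on-elastic-foundation decay.
All radii are configurable (`section_radii` in the run config).

Per-element equivalent stress is von Mises from the axial force plus the
extreme-fiber resultant bending moment (larger end), with torsional shear
and without transverse shear — the slender-member convention. The solver
is verified against closed forms (tip reaction 3EIδ/L³ and base stress
Mc/I of a prescribed-displacement cantilever, Hookean axial stress) at
1e-6 relative, and against equilibrium, stiffness symmetry and mirror
symmetry invariants.

## Plan evaluation and selection

Candidate plans are the Cartesian product of spaces {2,3,4,5} and
elevations {15,20,25,30,35} mm (the full grid is always evaluated). A
plan passes the corrective gate iff the post-operative Haller index at
*all four* sections is ≤ 2.68 — the mean post-operative index of a large
published series, and the interpretation consistent with every
accept/reject call in the bundled case study (one section at 2.809 is
enough to reject). Hypercorrection, judged visually in clinical practice,
is operationalized as the deformed B exceeding the healthy reference's B
by more than 2 mm at any section (configurable). Among surviving plans
the minimum maximum-equivalent-stress plan wins; ties (which cannot occur
in the continuous model but can in replayed tabular data) break toward
lower elevation, then lower space, making the selection independent of
evaluation order.

Replaying the bundled case study's printed tables through these gates
reproduces its decision: both reported candidate plans (3rd space/25 mm
and 4th space/30 mm) survive, the 2nd space/25 mm plan meets the index
but falls to hypercorrection, and with the reported stress ordering the
4th space at 30 mm is selected. Two printed 5th-space tables (25 and
30 mm) numerically pass the 2.68 gate even though the accompanying text
deems the 5th space unsuitable; the replay follows the printed numbers
(the 30 mm plan is eliminated as hypercorrected anyway, and the 25 mm
survivor never wins on stress).

## Bar design

The bar's working shape is designed in the axial plane of the selected
intercostal space. The matched reference boundary (gender match, age
within ±3 years, diameter closest to A_pre × 0.95; deterministic
tie-breaks by age gap then id) is clipped to the bar span, then raised by
a half-cosine bump peaking at Δ at the apex and vanishing at the ends —
chosen because its second derivative is nonpositive over the span, so it
cannot introduce concavity. Convexity (sampled signed curvature
≥ −1e-6 mm⁻¹ on a chord-length cubic spline, resampled uniformly in arc
length) is a hard post-condition: non-convex fits are projected onto the
nearest control polygon with nonpositive second differences (an SLSQP
least-squares projection), and a design needing Δ ≥ span/2 is rejected as
infeasible. Spline ends use the not-a-knot condition, since a bare point
list carries no end-slope data for clamping. Finally the span is rounded
*up* to the nearest standard catalogue length (default 7″–13″ in 1″
steps, in mm) by rescaling x about the apex, preserving apex height
exactly.

## Numerical choices and limitations

* Tolerances: convexity −1e-6 mm⁻¹; contour/landmark consistency 1e-9 mm;
  equilibrium residual 1e-6 relative; closed-form solver checks 1e-6
  relative; replay arithmetic ±0.002 against 3-decimal printed indices.
* Problem sizes: the packaged synthetic patient has 8 rib levels, 196
  nodes (~1.2k dof); a full 20-plan grid evaluates in about a second, so
  all tests run the complete study.
* Determinism: every random draw flows from a single `numpy` Generator
  seed; identical parameters and seed give bit-identical models and
  byte-identical pipeline reports.
* The model is linear and contact-free: the bar is a prescribed
  displacement, not a contacting implant; bar torsion, insertion
  kinematics, respiratory loading and fatigue are out of scope, as are
  DICOM ingestion and multi-bar plans.
* Stress magnitudes (a few MPa at 25 mm elevation on the defaults) are
  comparative quantities for ranking plans, not failure predictions — the
  section idealization and the rigid-spine assumption bias absolute
  values.
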