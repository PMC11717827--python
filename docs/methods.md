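# Methods

This note documents the models and procedures implemented in `dentofuse`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic validation does and does not
establish about real clinical data.

## Coordinate conventions

All coordinates are millimetres. The anatomical frame is right-handed
with X transversal (toward the patient's left), Y vertical (up) and Z
sagittal (anterior); the phantom head is centred at the origin. Rotations
are reported as pitch (about X), yaw (about Y) and roll (about Z), using
the intrinsic yaw(Y)–pitch(X)–roll(Z) Euler factorisation. The software
packages used clinically for such fusions do not publish their Euler
convention; at the few-degree deviations this pipeline produces, the
difference between reasonable conventions is second order in the angles,
so one convention is fixed, documented here, and round-trip tested to
1e-9. Decomposition refuses configurations within 0.01° of the
pitch = ±90° gimbal lock, far outside the working regime.

## Meshes and regions

Surfaces are triangle meshes with named vertex regions marking the
matching areas ("forehead", "zygoma", "anterior_teeth", "occlusal",
"tracer_body", "impression", …). Region delineation is an input: the
package requires explicit labels and makes no attempt at automatic
anatomical segmentation, mirroring the manual region selection a clinical
operator performs.

I/O supports binary/ASCII STL and PLY through trimesh. STL cannot carry
attributes, and one integer per vertex cannot encode overlapping regions
(the whole-dentition "maxilla" region contains the "occlusal" region), so
region membership always travels in a JSON sidecar
(`<mesh>.regions.json`) holding explicit vertex-index lists; PLY files
additionally get an integer `region_id` vertex property (first-listed
region wins per vertex) for viewers, which is honoured on read only when
no sidecar exists. STL stores facets independently in float32, so import
welds vertices at 1e-6 mm; the writer precomputes the welded indexing so
sidecar indices stay valid across a round trip.

The maxilla's measuring point is the **area-weighted surface centroid**
of the dentition mesh, not the vertex mean: it is invariant under
re-triangulation of the same surface, which a vertex mean is not.

## Registration engine

Every superimposition is trimmed iterative closest point between the
vertices of a source matching region and the vertices of a target
matching region, with correspondences from a k-d tree. Defaults: 100
iterations maximum; convergence when the trimmed RMS residual changes by
less than 1e-6 mm; the worst 10% of correspondences trimmed each
iteration plus anything beyond 10 mm; point-to-plane error metric
(linearised each iteration, with the exact rotation applied from the
small-angle solution) for large smooth areas, point-to-point (Kabsch/SVD)
for the sparse dental regions. Point-to-plane RMS can transiently
increase, so the engine tracks and returns the best-so-far transform.
There is no random subsampling by default; when enabled it is seeded, and
registration is deterministic for identical inputs and seed. A step with
no correspondence inside the rejection radius raises an error rather than
silently returning the identity.

Correspondence search is vertex-to-nearest-vertex rather than true
point-to-surface projection. At the phantom's mesh resolution (5 mm
target edge length on the head, ~2 mm feature size on teeth) the
difference is far below every tolerance used here; it is the main
numerical simplification in the engine.

Initialisation comes from `coarse_align`: match region centroids and
principal axes, resolving the four proper-rotation sign ambiguities by
the smallest median nearest-neighbour distance. Near-collinear regions
raise an error advising a manual initial transform. The basin of
attraction of the default ICP is roughly 10 mm / 10°; coarse alignment on
the phantom's acquisition-frame prior (±20 mm / ±15°) lands well inside
it. Note that for surfaces with repeating structure — the dental arch,
whose teeth sit ~7 mm apart — a 5 mm initial offset can already be
outside the basin (ICP snaps tooth-to-neighbouring-tooth); the workflows
avoid this because coarse alignment on the identical dental geometry is
nearly exact.

## Fusion workflows

Method A composes 2 registrations, method B 3, method C 2, exactly as
described in the README. Two asymmetries deserve note:

* **C2 (rest face → CBCT skin).** The CBCT field of view truncates the
  upper forehead, so part of the rest photo's forehead region has no
  counterpart. The ICP therefore runs from the (smaller) CBCT matching
  area onto the full rest face and the result is inverted — every source
  point then has a true match — and the coarse alignment uses the zygoma
  region only, which is fully visible on both surfaces. The step's
  contract is unchanged: its transform maps the rest photo into the CBCT
  frame.
* **Anterior-teeth matching (A2).** Only the canine-to-canine crown
  fronts are visible with retractors; registrations restricted to this
  short anterior strip constrain pitch weakly, which the test suite
  demonstrates against the full-arch registration method C performs.

**Per-step error model.** Each registration step may be followed by a
random rigid perturbation (translation N(0, σ_t²) per axis; rotation
about a uniformly random axis with angle |N(0, σ_r²)|), composed about
the **centroid of the step's matching region**. Rotating about the
matching surface rather than an arbitrary origin is what produces the
lever principle: a rotational residual on the tracer plate displaces the
dentition proportionally to the plate-to-teeth distance. Defaults when
simulating operator error are σ_t = 0.30 mm and σ_r = 0.2° per step —
the translational figure being the per-registration-step deviation
reported for chained surface superimpositions in this field. The
reference method C is perturbed with the same model by default
(`perturb_reference=False` restores an idealised gold standard): treating
C as error-free would be a modelling choice the comparison statistics
should not silently inherit.

**Pose deviation.** For experimental and reference poses `T_exp`, `T_ref`
(both IOS frame → rest-face frame), the relative transform is
`Δ = T_exp ∘ T_ref⁻¹`, evaluated at the reference-placed maxilla centre.
The displacement then equals `T_exp(c) − T_ref(c)` — a literal
subtraction of the two maxilla positions — and both the displacement and
the Euler angles are expressed in face-frame axes, where the anatomical
labels (transversal/vertical/sagittal) are meaningful. The conjugate
formulation `T_ref⁻¹ ∘ T_exp` has identical Euclidean and angular
magnitudes but expresses components in the arbitrary IOS acquisition
frame, which is why it was not used. In simulation, `run_cohort`
additionally conjugates poses by the rest photo's known acquisition frame
so cohort axes are exactly anatomical; with real scans the rest capture's
own axes serve, as they do clinically. Components are absolutized before
any cohort averaging; the Euclidean distance is computed from the signed
components and is unaffected.

## Synthetic phantoms

The phantom is parametric-analytic, keeping ground truth exact and
license-free rather than anatomically realistic:

* **Head**: a superellipsoid (power 2.4; semi-axes 70 × 90 × 75 mm) on a
  latitude–longitude grid at a 5 mm target edge length, with forehead,
  zygoma, cheek and lip regions labelled by geometric bands.
* **Dentition**: 14 box-like tooth crowns (7 × 9 × 7 mm, 2-fold
  subdivided faces) placed at equal arc length along a parabolic
  maxillary arch (width 60 mm, depth 45 mm), occlusal plane ~39 mm below
  the head centre. The bottom faces form the "occlusal" region, the outer
  faces of the middle six teeth the "anterior_teeth" region.
* **Tracer**: a bite fork under the occlusal plane, a stalk leaving the
  mouth, and a 40 mm matching plate with three knobs (the "transmission
  balls" of physical tracers, giving the plate full 6-DOF registration
  constraint) at a configurable lever arm, default 60 mm from the
  anterior dentition. The wax impression is modelled as an exact replica
  of the occlusal surface carried on the tracer.

Per-subject anatomy is jittered ±5% from a seeded generator, so a cohort
is a set of distinct subjects, bit-reproducible from its base seed.

The simulated acquisitions add per-modality Gaussian vertex noise
(default 0.05 mm, a typical optical-scanner figure), place each scan in a
random rigid acquisition frame (±20 mm / ±15°), and apply the
modality-specific effects: the retractor photo deforms the lower-face
band outward by a smooth radial bump (default amplitude 8 mm — strong
enough to corrupt a naive whole-face registration, making the
forehead-only matching choice testable) and exposes the anterior crowns;
the tracer photo shows the tracer body and loses the lip region; the
CBCT skin is cut 45 mm below the top of the skull, leaving only the lower
forehead; CBCT skin and teeth share one acquisition frame since they are
segmented from one volume. Retractor deformation amplitude and
tracer-related offsets are not quantified in the clinical literature;
the defaults are stated here and swept in experiments, not asserted as
measured values.

What the phantoms deliberately lack: photo-realistic anatomy, soft-tissue
biomechanics (the retractor deformation is a geometric bump), volumetric
CBCT synthesis with threshold-dependent surface extraction (the
tracer-conversion error is subsumed in vertex noise and the per-step
model), mandibular dentition, and texture. Consequently, passing tests
show the *pipeline* is correct and quantify how registration errors
propagate through it; they do not certify clinical accuracy on real
faces, where region delineation, occlusion, hair and skin specularity add
error sources the simulator does not model.

## Validation experiments

`dentofuse.validation` (driven by `scripts/acceptance.py` and the test
suite) runs, from scratch and seeded:

1. **Transform recovery** — 100 random rigid motions (≤30°/30 mm) of the
   forehead patch, initialised within 5 mm / 5°, noise-free: worst
   recovery error is at machine-precision level, asserted < 1e-3 mm/°.
2. **Euler round trip** — 200 random rotations ≤ 30° reconstruct to
   1e-9.
3. **Noise-free end-to-end** — with ideal acquisitions, all three
   workflows recover the ground-truth maxilla pose; all pairwise
   deviation components < 0.1 mm / 0.1° on 5 subjects (measured:
   ~1e-13).
4. **Error accumulation** — at 0.30 mm / 0.2° per step over a
   300-subject cohort, the 3-step tracer chain deviates more from the
   reference than the 2-step retractor chain (one-sided paired test,
   p < 0.01; the mean-squared deviation of a chain grows with its step
   count).
5. **Lever arm** — doubling the tracer lever arm (60 → 120 mm) under
   rotational-only step noise increases the tracer workflow's
   translational deviation (p < 0.01).
6. **Closed-form statistics** — paired t, mean/CI, Pearson r and DME
   reproduce hand-derived values on 3-point series to 1e-9.
7. **Bin semantics** — acceptability bins close at 2 and 3 (2 → first
   bin, 3 → second) and conserve counts.
8. **Replicate agreement** — re-fusing identical scans with a different
   operator realisation yields reliability ≤ 1 and DME > 0, and the DME
   vanishes when the per-step noise is zero.

Problem sizes (100 transforms, 5 noise-free subjects, 300-subject
cohorts, 60-subject lever sweeps, 12-subject replicates) were chosen so
the full battery completes in about a minute on one CPU while leaving
each statistical conclusion far from its threshold (observed p-values
are 1e-4 or smaller).

The headline accuracies published for the clinical versions of these
workflows stem from real patients whose scans are not public; those
numbers are therefore not reproduction targets here, and the simulated
cohort means (~1.0 mm for the 2-step and ~1.1 mm for the 3-step chain
under the default error model) should be read as the model's prediction
under the stated assumptions, not as a re-estimate of the clinical
values — though their ordering and magnitude agree with what is
reported clinically.

## Statistical conventions

Sample standard deviations use the n−1 denominator. Confidence intervals
are t-based with n−1 degrees of freedom, two-sided at 95%. No
multiple-testing correction is applied (the report mirrors studies that
publish unadjusted per-outcome comparisons). Zero-variance paired
differences are flagged degenerate (point CI, NaN p) rather than raising;
Pearson reliability on a constant series raises, and the report renders
it as NaN. The agreement table's `diff` column is the signed difference
of absolutized outcomes, so negative entries are possible and expected.
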