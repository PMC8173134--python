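# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ukacontact`. Units are millimetres and degrees throughout;
the coordinate convention is a right knee with x = anterior(+),
y = medial(+), z = proximal(+).

## Phantom

The phantom stands in for the patient data of a dual-fluoroscopy UKA study:
implant surfaces, activity motions, and the dual-view imaging geometry.

**Femoral condyle.** A toroidal section: a coronal circular arc (radius
`Rc`, default 11 mm) swept along a sagittal circular arc (radius `Rs`,
default 24 mm) over an arc span of 160° (coronal span 140°), closed into a
watertight convex solid by a convex hull with three interior closure
points. The frame origin is the sagittal arc centre, the sweep (tube) axis
is the ML axis, and the articular surface faces distally with its lowest
point at `(0, 0, -Rs)`. Vertices of the articular band satisfy the torus
implicit equation exactly, which the tests use as a closed-form oracle; the
limit `Rc = Rs` is a sphere. The radii are configurable because the
commercial component geometry is proprietary; what matters for the contact
algorithm is the low-congruence single-contact property (condyle radii well
below the insert dish radius), which the defaults preserve. Two mesh
resolutions are used deliberately: a coarse mesh (28 sagittal samples,
~1300 faces) for silhouette work, and a fine mesh (240 samples, ~100k
faces) for contact, whose facet size (~0.2 mm chord spacing near the apex)
sets the contact quantisation.

**Insert and baseplate.** The PE insert is a block with a superior surface
that is either flat (default, matching a low-congruence design) or a
spherical dish `z = t + R - sqrt(R² - x² - y²)`; its frame origin is the
footprint centre so the centroid projects to (0, 0). Default footprint
43 × 26.5 mm, thickness 8 mm. The 43-mm length is the representative-insert
length onto which contact patterns are mapped. The width is not printed in
the summary literature; 26.5 mm is reconstructed so that the millimetre and
percentage columns of the reference contact table agree (1.8 mm ≈ 6.8 % of
the width), and ML coordinates are normalised by the *width* — normalising
both axes by the length would make the printed ML percentages unreachable.
Both values are configurable. The baseplate is a 45 × 28 × 3.5 mm plate.

**Cameras.** Two point-source/flat-detector fluoroscopes with horizontal
view axes 90° apart (configurable 80–100°), source–isocentre distance
700 mm, source–detector distance 1000 mm — typical C-arm geometry. The
silhouette of a mesh is the set of edges shared by one source-facing and
one source-averted triangle, with facing judged along the per-edge ray to
the source (perspective-correct, not a single view direction); contour
points are sampled uniformly by projected arc length.

**Activity trajectories.** Each activity (gait stance keyed by percent
stance; lunge and sit-to-stand keyed by flexion angle) is defined by
keyframes of contact AP/ML, flexion and internal rotation. The stance and
sit-to-stand AP keyframes encode the published contact trajectories
(7.4 → 3.1 → 6.6 → 4.5 mm at 0/20/80/100 % stance; 7.3 → 0.9 → 0.7 → −0.6 mm
at 0/44/76/90° flexion); ML keyframes are chosen to give the published
average/range scale (~1–2 mm). Channels are interpolated with monotone
PCHIP cubics so the printed key values are never overshot. Poses are
constructed so the condyle's lowest point tracks the keyframed contact
exactly on a flat insert (by torus symmetry the lowest articular point lies
directly below the femoral origin whenever the needed patch angle is inside
the arc span; large flexion ranges are accommodated by a constant mounting
rotation recorded as `mount_offset`). Optional Gaussian pose jitter is
seeded; no function uses global RNG state.

## Registration

**ICP** is point-to-point with KD-tree correspondences against the target
vertices, optional rejection of the worst `trim_fraction` of matches (the
partial-overlap surrogate for excluding a resected compartment), and the
closed-form SVD update. The trimmed RMS is non-increasing by construction
and iteration stops when it changes by < `tol`. Point-to-plane is not
needed at the sub-millimetre accuracies involved. Note that the toroidal
condyle is nearly a surface of revolution, so ICP on the condyle alone can
slide along the sweep direction; exact-recovery tests therefore use
asymmetric geometry, which is also the realistic use (bone surfaces).

**Silhouette pose estimation** minimises the mean squared distance from
measured contour points to the projected model silhouette segments, summed
over both views. The distance is asymmetric (measured → model) because a
measured outline may be partial while the model silhouette is complete.
The optimiser is Nelder–Mead over (rx, ry, rz, tx, ty, tz) — intrinsic
Z–X–Y Euler angles plus translation — with an initial simplex step of
0.5°/mm, restarts at the incumbent best, and a deterministic multi-start
fallback (re-perturbing one parameter at a time by ±1 and ±2) that triggers
only while the residual RMS exceeds 10⁻³ mm; with noise-free contours the
cost at the true pose is exactly zero, so non-convergence is detectable and
is always flagged, never silent. A single view is refused outright because
out-of-plane depth is unconstrained. The published cost and optimiser of
clinical systems are not specified; these choices are this package's own
and are isolated behind `OptimizerConfig`.

## Kinematics

The 6-DOF decomposition is the knee joint coordinate system: e1 = femoral
ML axis (flexion), e3 = tibial long axis (internal–external rotation),
floating e2 = e3 × e1 (ab/adduction) — implemented as the intrinsic Y–X–Z
Euler decomposition of `R_femurᵀ R_tibia`, with signs flexion(+),
adduction(+), tibial internal rotation(+). Translations are the femoral
origin relative to the tibial origin *expressed along tibial axes*; the
axis basis for translations is ambiguous in the field's shorthand and the
tibial basis is chosen for consistency with the contact frame.
Decompose∘compose is the identity to 1e-9 away from gimbal lock
(|e1·e3| > 0.999 raises). Left knees are pooled by reflection across the
sagittal plane (meshes get a winding repair; poses are conjugated by the
reflection), which preserves medial(+) and is an exact involution.
Non-monotone flexion series are split at peak flexion and each limb
resampled separately. Resampling is linear, never extrapolates, and flags
out-of-range grid points as missing; grids are 1 % steps for stance and 2°
steps for flexion-keyed activities.

## Contact

The contact point lives on the insert superior surface (wear accrues on the
insert; the insert-side vs femoral-side choice is below reporting precision
for near-contact frames). The discrete stage evaluates the signed distance
from insert superior sample points to the femoral articular mesh — negative
inside the femoral solid, so "closest point" and "deepest penetration"
are the same argmin — using a KD-tree over triangle centroids with a
nearest-vertex upper bound and a mesh bounding-radius certificate, which
makes the accelerated search *identical* to exhaustive vertex–triangle
search (the acceptance suite verifies this against an independent kernel on
100 random poses). Ties within 1e-6 mm resolve to the most posterior sample
and are flagged. Gaps above 6 mm flag "no contact" (a distracted joint at
that scale indicates registration failure). An optional continuous
refinement polishes the discrete argmin by a 2-D simplex search over the
insert's closed-form height field, removing sample-grid quantisation; the
remaining error is the femoral facet size (~0.1–0.2 mm at the fine contact
resolution). Normalisation is `ap/length·100` and `ml/width·100`; mapping
onto the representative insert preserves percentages exactly. Excursion
summaries are per trial (frame mean; max−min range), averaged within
subject, then mean ± sample SD across subjects. Offsets against the in
vitro wear-region centre use the packaged aggregate centre (−0.5, 0.7) mm
≡ (−1.1 %, 2.6 %) on the representative insert, signed anterior(+) /
medial(+).

## Sensitivity

Pose noise is applied per axis to the six Euler/translation parameters of
each component — matching how tracking accuracy is quoted per DOF — with
defaults (0.27°, 0.10 mm) femoral and (0.39°, 0.18 mm) tibial. For each
frame × replicate the femur-in-tibia pose is rebuilt and the contact
re-solved with a warm start at the unperturbed contact; signed errors
(noisy − reference) are pooled over frames and replicates into one
mean ± SD per direction, and reports are bit-identical under the same seed.
Signed (not absolute) differences are reported, consistent with a
sub-SD mean. Two closed-form regimes anchor the tests: zero noise gives
exactly zero error, and single-axis tibial AP translation noise rigidly
co-translates the contact, so the propagated AP error SD equals the
injected SD. A caveat for interpreting rotational noise: on a faceted
articular mesh the contact responds to small rotations as a facet-quantised
staircase (jump size ≈ facet spacing), a discretisation artefact that
inflates rotational sensitivity relative to the smooth surface; the linear
regime property is therefore tested with translational noise.

## Statistics

All four tests are implemented from their definitions. KS normality uses
maximum-likelihood parameter estimates by default; the asymptotic
Kolmogorov p-value is anti-conservative under estimated parameters, which
is acceptable for a screening test (known parameters can be passed for the
fully specified case). ANOVA is textbook sums of squares. Duncan's multiple
range test sorts the means, uses critical ranges
`R_p = q(α_p, p, df_w)·sqrt(MS_w/n_h)` with protection level
`α_p = 1−(1−α)^{p−1}`, the studentized-range quantile computed by numerical
CDF inversion (scipy's `studentized_range`, cross-validated in the tests
against classical table values), harmonic-mean n for mild imbalance (a
warning beyond 2:1), and outside-in stepwise testing with the containment
constraint that no pair inside a homogeneous stretch is declared
significant; with two groups the decision coincides exactly with the pooled
t-test since `q(2, df) = √2·t(df)`. Duncan is implemented (rather than
Tukey) because it is the post hoc test of record for this analysis; its
familywise error under the null exceeds α by design, asserted
directionally in the tests. The rank-sum comparison is the two-sample
Wilcoxon–Mann–Whitney test: exact by full enumeration of rank assignments
(midranks under ties) when n ≤ 12, otherwise the normal approximation with
tie and continuity corrections. Rank-sum inputs are per-subject averages,
not per-frame positions (per-frame samples are serially dependent).

## Problem sizes and determinism

Default problem sizes were chosen so each analysis is comfortably resolved:
registration benchmarks use 50 trials × 2 components with 150 contour
points per view; sensitivity uses 1000 replicates for closed-form checks;
the end-to-end phantom runs 11 stance frames at contact resolution 240.
Every stochastic entry point takes an explicit seed, and the pipeline
derives per-stage seeds from the top-level seed via `SeedSequence`, so a
config + seed pair reproduces every artifact hash.

## Limitations

* The phantom emulates geometry and projection only: no radiographic
  physics (attenuation, scatter, spectral effects, detector distortion), no
  edge-detection errors, no soft tissue or bone — so passing tests validate
  the measurement chain, not robustness to real image quality.
* Implant geometry is a torus/block proxy for proprietary CAD models;
  absolute contact coordinates of a real implant system will differ,
  though the measurement chain is geometry-agnostic.
* Contact is a point estimate; contact area and stress are out of scope, as
  is the insert's inferior (backside) surface.
* The silhouette cost/optimiser are reconstructions of unpublished internal
  tooling choices and are isolated behind configuration.
* Normality p-values with estimated parameters are anti-conservative (no
  Lilliefors correction).
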