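# Methods

This note records the modelling assumptions, parameter choices, numerical
decisions and known limitations of the pipeline. Units throughout: mm, N,
MPa (= N/mm²), seconds, degrees. Frame: pelvis-fixed, right-handed,
+X anterior, +Y superior, +Z lateral; left hips are mirrored to the
right-hip convention before processing.

## Contact model

Discrete element analysis treats the subchondral bone as rigid and the
cartilage as a bed of independent linear compressive springs. Spring axes
are rays from the acetabular (cup) center through each acetabular contact
element centroid, fixed during a solve; this is the standard hip-DEA
convention and avoids normal-recomputation chatter inside the optimizer.
The per-area stiffness uses the confined-compression (aggregate) modulus
E(1−ν)/((1+ν)(1−2ν)) divided by the combined cartilage thickness along the
ray, the two layers acting in series (femoral thickness sampled on the same
ray at the neutral pose; it varies negligibly over the equilibrium
displacements of ~0.1 mm). With E = 12 MPa and ν = 0.43 the aggregate
modulus is 34.17 MPa. A configuration flag could substitute a plain E/h
law; the aggregate form is the default because ν = 0.43 makes the
correction a factor ~2.8, not a refinement.

Penetration is exact geometry: the overlap along each spring ray between
the femoral cartilage outer surface and the acetabular cartilage surface.
For the default spherical head this is a closed-form ray–sphere
intersection; an aspherical (noisy) head falls back to a star-shaped radius
function with nearest-direction lookup and a short fixed-point iteration.
The surface radius along a ray uses the mean vertex radius of the element
rather than the chord-centroid radius — the centroid of a flat triangle
sits below the curved surface by ~l²/R (≈ 2 µm at 0.7 mm elements), which
is 4% of the equilibrium displacement and would bias stresses if ignored.

Because penetration is exact, stress is *not* exactly linear in load on a
fixed contact set: the sphere–sphere overlap carries an O(u/R) geometric
term, amplified toward the rim where rays graze the head. Doubling the load
doubles core-element stresses to ~3×10⁻³ relative at physiological loads;
the tests assert that bound rather than machine precision.

## Equilibrium and divergence

Each load instance is solved for the three translational degrees of freedom
by a damped Gauss–Newton (Levenberg–Marquardt) iteration with a
forward-difference Jacobian (step 1e−5 mm). Convergence: force residual
below 1e−6 N. Divergence: more than 400 iterations, or a displacement step
below 1e−6 mm *while the residual has stopped contracting* (less than a
factor-2 reduction in the iteration). The contraction qualifier matters: a
quadratically converging Newton tail passes through the sub-1e−6-mm step
band exactly one iteration before crossing the force tolerance, and the
literal step criterion would misclassify those solves; a genuinely stuck
solve (subluxation) shows shrinking steps with a stagnant residual and is
still flagged. Cold starts are pre-equilibrated by marching the head along
the load direction to first contact and bisecting the 1-D axial force
balance; subsequent stance instances warm-start from the previous
equilibrium (path independence is regression-tested against cold starts).
Gait sequences are all-or-nothing: one diverging instance excludes the
hip's entire 7-instance sequence from that scenario.

## Cartilage constructions

*Uniform offset (healthy):* every subchondral vertex moves 1 mm along its
radial axis into the joint space — toward the center on the acetabulum,
away from it on the femur, so both layers carry 1 mm of cartilage between
bone and joint space. Five smoothing iterations follow: each vertex radius
moves toward the mean radius of its mesh neighbours, clamped to 0.05 mm per
vertex per iteration, applied Jacobi-style (all vertices from the previous
iterate) for order independence. The smoothing direction is toward the
neighbour average — the only contraction consistent with smoothing toward
sphericity. On a perfect sphere the construction is exactly a concentric
sphere.

*Mapped thickness (dysplastic):* acetabular vertices move toward the center
by a thickness map over (polar, azimuth) fitted with a thin-plate
(biharmonic) spline — an exact interpolant, C¹ between samples, clamped
below at 0.2 mm to preserve positive thickness. Topology is preserved
(element correspondence is kept for thickness bookkeeping rather than
re-meshing). The packaged 12-site map rises from 1.4 mm centrally to
2.6 mm at the superolateral rim, emulating the rim-thickened pattern
reported for dysplastic acetabula; it is a synthetic placeholder, and real
maps can be supplied as (polar_deg, azimuth_deg, thickness_mm) CSV rows.

## Synthetic cohort

The generator stands in for CT-derived anatomy and emits what the study
design needs: per-hip geometry, covariates, and the five radiographic
measures pre and post.

Geometry: near-spherical femoral heads (radius ~N(24.5, 1.5) mm, optional
seeded low-order harmonic asphericity, default 0); acetabular cups of
radius head + 4 mm clearance (with 1 mm cartilage on each side this leaves
a 2 mm radial gap, so contact localizes in a Hertz-like patch and peak
stresses reach the 5–12 MPa range reported for dysplastic hips — a fully
congruent joint would cap stresses near 1.5 MPa and leave the 6/9.5 MPa
threshold metrics degenerate). Cup orientation: opening axis tilted 40°
inferiorly (inclination) and 20° anteriorly (anteversion) from lateral,
per-subject jitter on both. Rim coverage is a polar-depth table at four
cardinal azimuths (superolateral, anterior, inferomedial, posterior),
interpolated by a periodic monotone cosine blend. The superolateral and
anterior knots are solved by 1-D root finding so the generated hip hits its
drawn LCEA and ACEA targets (pre-op LCEA ~N(17°, 6°), ACEA ~N(21.4°, 8°),
truncated); medial/posterior knots are drawn directly. Covariates follow
the published cohort statistics: age N(34.6, 6.4) yr, weight
N(72.5, 14.2) kg, height N(1.69, 0.08) m, 16/22 female, with physiologic
truncation. An optional bilateral flag duplicates one subject with
independent geometry (the 23rd-hip bookkeeping case).

PAO is a rigid rotation of the cup (axis and coverage table together) about
the head center: +X rotation targeted at a post-op LCEA of N(28.6°, 3°)
with 2° under/overcorrection noise, a −Y (version-reducing) rotation of
N(8°, 3°) that deepens anterior coverage, and a small axial component. No
translation and no rim reshaping — a first-order model of acetabular
reorientation; total cup area is exactly conserved, so post-op contact-area
gains are genuine containment gains.

Radiographic measures are computed from the 3-D rim by orthographic
projection at neutral pelvic alignment (no tilt, no magnification). The
landmarks are the rim points at the cup's cardinal azimuths: LCEA and ACEA
are the frontal/sagittal angles from vertical to the superolateral/anterior
rim edge; AAA is the axial angle of the anterior–posterior rim chord; FHEI
is the head width lateral to the superolateral rim edge as a percentage of
head width. AI is the frontal inclination of the roof chord from a medial
sourcil proxy — the point 60° of polar arc below the superolateral rim
along its meridian — to the rim edge. The 60° sourcil span was chosen so
that the AI↔LCEA covariation matches clinical reads (on a sphere
AI ≈ 30° − LCEA, reproducing dysplastic AI ≈ 14° at LCEA ≈ 17° and
post-op AI ≈ 1–3° at LCEA ≈ 28°); it is a stated geometric convention, not
a claim of radiographic equivalence. Mesh-derived rims reproduce the
parametric measures within 2°.

## Gait loading

Each profile is a double-bump |JRF| over stance (two Gaussian pulses over a
sine-enveloped mid-stance valley, zero load at the stance edges) with a
family-specific direction tilt from vertical. Family defaults encode the
literature contrasts: the implant-instrumented-like family peaks at
233/205 %BW with a 17° medial tilt; the dysplastic harris-like family at
285/255 %BW with the largest medial share (28°); the dysplastic
skalshoi-like family at 320/290 %BW with the most vertical force (12°) and
the least hip-extension excursion. Internal–external rotation defaults to
0°, as profiles lacking it are conventionally zero-filled. Discretization:
heel-strike and push-off peaks are detected as the first and last prominent
maxima of |JRF|; instance spacing is (t_po − t_hs)/4 with instances 2 and 6
exactly on the peaks, times clipped to [0, 1] with a warning. Forces scale
as %BW × weight × 9.81. The stance-phase duration converting instance
spacing into Δt (seconds) defaults to 0.6 s and is configurable; the dose
metrics (MPa·s) scale linearly with it.

## Stress metrics

All metrics are over acetabular contact elements. Thresholds are strict
(">"), including > 0 MPa for contact. Empty threshold sets contribute zero
(the Maxian per-instance term and the STE denominator). "Cumulative stress"
for the STE metric is Σ_j p_{i,j}Δt per element — the only reading with
MPa·s units. The peak stress–time dose is defined as the maximum over
elements of that same per-element dose, consistent with its name, units and
variables. The STE numerator is explicitly intersected with its denominator
(the ever-above-4-MPa area) so the metric is a true fraction; at the
default Δt the intersection is a no-op. Every metric is verified to 1e−12
against an independently coded brute-force double loop.

## Study statistics

Paired (dependent-samples) t-tests compare pre/post per metric and
scenario; zero-variance nonzero differences report p → 0 with an infinite
statistic rather than NaN. The correlation grid pools pre- and post-op
observations per scenario, each hip contributing its treatment-matched
measure, with pre and post groups each carrying half the total weight —
the guard against skew when divergences make group sizes uneven. Weighted
correlation significance uses the t transform with the Kish effective
sample size (Σw)²/Σw². Forward stepwise regression enters the candidate
with the largest partial F when F ≥ 3.84, removes entered variables whose
partial F drops below 2.71, bars perfectly collinear candidates, and stops
early when the residual R² deficit falls below 1e−9 (partial F is undefined
on a numerically exact fit — the analogue of SPSS's tolerance check). Sex
is coded F = 0, M = 1. Significance is α = 0.05 two-sided throughout, with
no multiplicity correction — a reporting convention, not a recommendation.
Omnibus repeated-measures MANOVA/ANOVA machinery is intentionally out of
scope; treatment, cartilage and loading effects are reported through the
paired tests and summary tables.

## Interface

The package is consumed as a library plus the numbered drivers under
`analysis/`; every pipeline stage (cohort generation, cartilage, gait
discretization, the solver, metrics, statistics) is an importable function,
and the drivers are thin narrative wrappers that write their tables under
`results/`. No shell CLI is provided: the audience for an analysis package
of this kind scripts against the API rather than a command line.

## Problem sizes and defaults

The analysis chain and the end-to-end checks run the 22-subject (23-hip)
cohort on 1.5 mm study meshes (~2–3 × 10³ acetabular elements per cup,
~1.8 × 10³ instance-solves in the full factorial, well under a minute on
one core); the solver-verification oracle refines to the 0.7 mm element
size used for the main results, where the closed-form hemisphere solution
is matched to 0.1%. The femoral side in the study uses the analytic sphere
model that the uniform-offset construction produces exactly for a noise-free
head; the mesh-backed femoral path is exercised separately with imposed
asphericity.

## What the synthetic cohort does and does not show

The generator reproduces the *structure* of a PAO cohort — coverage
distributions, covariates, double-peaked loading, rim-thickened dysplastic
cartilage, reorientation with correction noise — so passing tests
demonstrate that the pipeline recovers the expected mechanical directions
(contact area up, average/threshold stresses down post-PAO; AI positively
and LCEA negatively associated with stress) and that the statistical
machinery behaves. It does not reproduce patient-specific anatomy:
aspherical dysplastic heads, acetabular version deformities beyond the
coverage table, labrum and ligament load sharing, pelvic tilt at imaging,
or true cartilage maps. Absolute metric values and the published clinical
tables are therefore out of reach by construction; directional and
structural agreement is the claim. With the default truncation of pre-op
severity the synthetic cohort converges in all scenarios; divergence
behaviour is exercised by explicit undercovered-cup constructions rather
than by the cohort draw.

## Known limitations

- No friction or shear springs; no cartilage barrelling (lateral bulge
  under compression); depth-uniform material constants.
- Spring rays fixed at the cup center: accurate for near-concentric
  kinematics, increasingly approximate during large subluxating motions
  (which are classified as divergences anyway).
- The femoral thickness entering the series stiffness is sampled at the
  neutral pose, not re-sampled per iterate.
- Radiographic proxies are geometric conventions; absolute AAA values run
  ~15° above typical clinical reads because the chord-based axial angle
  responds to the full rim, not the sourcil alone.
- The stepwise perfect-fit guard means constructions with sub-1e−9 residual
  variance terminate at the true predictors; real (noisy) data never
  triggers it.
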