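# Methods

`coilwatch` measures whether a coil-embolized cerebral aneurysm recurs by
sac growth or by coil compaction, and whether the coil mass translates
measurably when it does. Each subject contributes up to four 3D rotational
angiography (3DRA) sessions — pre-first-coiling (1-), post-first-coiling
(1+), pre-second-coiling follow-up (2-) and post-second-coiling (2+) — and
each session contributes a *subtracted* volume (contrast-filled lumen) and a
*baseline* bone-scan volume (skull + metal coil). Control subjects, never
re-treated, lack the 2+ session.

## Measured quantities

Sac volumes V_S1-, V_S1+, V_S2-, V_S2+ and coil-mass volumes V_C1+, V_C2-
are integrated from watertight surface models (cc). Sac growth uses four
differences, prioritized by availability (retrospective series routinely
lack sessions):

    V_SG1 = V_S2+ − V_S1-     V_SG2 = V_S2+ − V_S1+
    V_SG3 = V_S2- − V_S1-     V_SG4 = V_S2- − V_S1+

V_SG > 0 is growth; the percent value divides by the definition's initial
volume. Coil growth V_CG = V_C2- − V_C1+ (< 0 is compaction),
%V_CG = V_CG / V_C1+. The coil-center translation δ is the Euclidean
distance between the volume-weighted mass centers of the coil models at 1+
and 2-, computed by signed-tetrahedron integration over the closed surface.
δ assumes both sessions share one coordinate frame; no inter-session
registration is implemented, so real data must be acquired or resampled
co-registered (phantoms are co-registered by construction).

## Segmentation

*Vascular chain* (subtracted volumes): grayscale morphological opening
(ball, radius 1 voxel) removes small-scale noise; Otsu's threshold —
exhaustive maximization of between-class variance, ties toward the lower
cut — separates contrast from background over a volume of interest (default:
the working region); the connected component under a user seed placed in the
sac is kept (26-connected foreground); a morphological geodesic active
contour refines the boundary against the inverse-Gaussian-gradient edge map
(defaults: 20 iterations, 1 smoothing pass, unit balloon, edge sigma 1
voxel). The seed only initializes: any seed in the same component yields the
identical mask. Post-treatment subtracted scans are handled two ways
differently: every foreground component is kept (residual blood often
detaches from the vessel lumen when the coil blocks contrast), and the
contour refinement is skipped — the residual is a thin shell around the coil
whose volume the curvature force would systematically erode; the union with
the coil mass is consolidated afterwards anyway.

*Coil chain* (baseline volumes): grayscale closing (radius 1 voxel) bridges
the coil-wire winding; Otsu over a VOI centered on the treated aneurysm
(default half-width 6.5 mm, excluding skull); largest connected component;
internal cavities bounded by coil wire are filled while through-going
tunnels — background reaching the image border — are retained, since no
bounding wire closes them; contour refinement runs *without* curvature
smoothing, because smoothing an inherently irregular coil boundary biases
the measured volume low (about −10% at study coil sizes, −4% without). The
result — wire plus interstitial thrombus — is the coil mass.

The morphological contour in scikit-image alternates its two curvature
operator compositions through a module-global cycle; `coilwatch` resets the
cycle on every call so that identical inputs give identical masks. The
evolution is windowed to the init bounding box padded by twice the iteration
count (the front moves at most a few voxels per iteration and is
edge-stopped in practice); this keeps the refinement local and fast.

## Surface models and sac isolation

Masks are meshed by marching cubes at the 0.5 level of the indicator after
one Gaussian pass (σ = 0.5 voxel) that reduces stair-step volume bias;
sub-resolution masks fall back to a 2× nearest-neighbour upsampled
indicator. Volumes and mass centers come from signed-tetrahedron
integration (divergence theorem) over the watertight mesh; non-watertight
meshes are rejected, never repaired.

The sac is isolated from the contiguous vasculature by reconstructing the
parent vessel and subtracting it, which leaves a sac bounded by a
*non-planar* neck surface (a single cutting plane discards sac surface near
the ostium). Concretely:

1. Euclidean distance transform and 3D skeletonization of the mask; each
   centerline voxel carries its maximal-inscribed-sphere radius.
2. The bulge center is the distance-map argmax of the seed's component; its
   radius bounds the sac, and centerline points beyond twice that radius
   anchor the parent-vessel caliber estimate (90th percentile of their
   radii — off-center skeleton voxels underestimate the lumen radius).
3. Centerline points of vessel caliber (< 1.5× the estimate) and clear of
   the bulge are ordered along their principal direction, robustly trimmed
   of off-axis spurs, smoothed, and extrapolated out of the grid along the
   end tangents; a tube of 1.1× the caliber is carved around this polyline.
   The smoothed chord bridges the junction where the centerline bows into
   the sac.
4. The connected remnant containing the seed is the sac; meshing the voxel
   remnant closes it across the removed tube, producing the neck cap, whose
   mesh vertices are reported as the neck boundary. If the seed voxel itself
   was carved, the largest remnant component within 2.5 mm is taken — the
   equivalent of an operator re-seeding.

Degenerate inputs are classified rather than mis-cut: a component with no
far centerline of at least tube caliber (3 voxels) is a lone bulge
(residual blood or coil detached from the vessel) and is returned whole,
unless it is elongated beyond 3.5× its inscribed radius, in which case it is
a vessel with no sac and an error is raised. The automatic cut assumes a
single, locally straight-ish parent vessel; branching complexes like true
bifurcation aneurysms need an explicit `vessel_info={"radius_mm": r}` hint
or manual editing, and very small sacs (caliber comparable to the parent
vessel, below roughly 2.5× its radius) cannot be separated automatically.

Post-treatment sacs are the Boolean union of the coil mask and the
angiographic mask ("the sac is the coil mass plus outlying residual
blood"), consolidated by a one-voxel binary closing and an internal-cavity
fill before isolation, because the two independently segmented solids meet
along thin seams.

## Statistics

Sac growth and coil compaction are tested per cohort with one-tailed paired
Wilcoxon signed-rank tests (growth: alternative *greater*; compaction:
alternative *less*); δ is compared between cohorts with a one-tailed
Mann-Whitney U test (recurrence greater). Zero differences are dropped
(Wilcoxon's original convention), tied magnitudes receive midranks, and
one-tailed p = P(statistic ≥ observed), observed included. Exact null
distributions are used at study sample sizes: the signed-rank distribution
by dynamic programming over doubled midranks (n ≤ 25), the rank-sum
distribution by the standard recurrence without ties or by full subset
enumeration with ties (up to 2·10⁵ subsets); beyond that, tie-corrected
normal approximations with continuity correction. ROC curves classify
positive at score ≥ threshold; AUC is the pairwise concordance (equal to
U/(n₁n₀) and to the trapezoidal area), and the operating point maximizes
Youden's J with ties toward the lower threshold. Investigator agreement is
the squared Pearson correlation of paired volume measurements. No
multiple-testing correction is applied, matching the study design.

The growth-outcome table reports, per cohort and per definition, the mean ±
SD of the paired differences (cc and %), the one-tailed p, and n — the
count of subjects for which that definition is computable. Missing volumes
are represented explicitly; absent is never zero.

## Synthetic phantoms

No clinical volumes accompany the study, so validation uses phantoms with
programmed truth. A subject is a scene of analytic solids on the scanner
grid (0.22 mm isotropic): an ellipsoidal sac over a capsule parent vessel
(overlapping it by ~40% of the vessel radius so the complex is contiguous);
a coil mass built as the union of capsule segments along a random walk
confined to the sac and grown to a target fill fraction; a residual-blood
envelope (the sac ellipsoid, minus the coil, on post-treatment subtracted
scans); optionally a skull-like shell (baseline scans only, and only when
the desk-scale grid leaves room for it to clear the coil VOI), Gaussian
intensity noise (default SD 5 on a background-10/blood-100/coil-180 scale)
and multiplicative radial streaks centered on the session's coil mass
emulating metal artifacts (default ±5%). Growth scales the sac semi-axes by
(1+g)^(1/3); translation rigidly shifts the coil path by a programmed
offset, oriented away from the neck. The translated coil may protrude
through the residual envelope; since the sac *is* coil ∪ residual, the
follow-up sac truth is the rasterized union volume, while 1-/1+ truths are
closed-form ellipsoid volumes. True coil volume and centers come from the
noiseless rasterized coil; the true δ equals the programmed offset norm.

Cohort draws (defaults, chosen to mirror the study conditions): recurrence
growth ~ N(20%, 10%), controls ~ N(0, 0.5%); recurrence translation ~
N(2.0, 0.5) mm, controls ~ N(0.5, 0.2) mm; sac radii uniform on 3.2–4.6 mm;
coil fill uniform on 0.25–0.40. What the phantoms do *not* emulate: x-ray
projection physics, beam hardening, patient motion, inter-scan registration
error, vessel branching, blind spots (clot invisible to both scans), and
partial-volume blur beyond rasterization. Passing tests therefore
demonstrate internal consistency of the measurement chain under the stated
image model, not clinical accuracy.

## Accuracy at the default scales

On 96³–128³ grids the chain recovers per-session sac volumes within about
−2% (1-) to −5% (union sessions) of truth — a consistent sub-voxel surface
peel from thresholding at the blurred edge — so percent growth is recovered
to within a few percentage points, and δ to well under half a voxel
(≲0.05 mm against programmed 0.5–2 mm offsets). Coil volumes are within a
few percent; the 1+/2- coil difference (a null in the phantoms) drifts
positive by ≈0.5%, which is conservative for the one-tailed compaction
test.

A known residual asymmetry: the 1+ union sac is measured about one
percentage point lower than the 2-/2+ union sacs, so on exactly-null
cohorts the secondary definition rows that pair 1+ against a follow-up
session (V_SG4 in particular) can drift slightly positive and, with enough
subjects, reach nominal significance. The prioritized definitions used for
the headline tests (1 for re-treated subjects, 3 for controls) drift
conservative (negative) instead. Interpret secondary definition rows on
near-null data accordingly.

## Problem sizes

The default phantom grid is 128³ at 0.22 mm; cohort-level runs (the
acceptance script's 15+12 study and the test suite's 8+7 study) use 96³
grids, which hold the full sac-vessel complex at scanner resolution while
keeping a full study run in minutes. The per-subject chain crops a 10 mm
working region around the seed; measurement results are unchanged by the
crop beyond the Otsu sample (which the VOI defines anyway).
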