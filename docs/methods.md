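# Methods

`dentalid` implements a three-stage pipeline for identifying a person from a
3D point cloud of their dentition (an intraoral scan, IOS): feature
extraction by curvature thresholding, local geometric description by FPFH,
and coarse-to-fine rigid registration whose residual error is the
identification score. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not establish.

## Stage 1 — crown-contour extraction

Most points of a dental scan (smooth crown faces, gingiva sheet) carry
little identity information; the discriminative geometry concentrates in
the crown contour, the rolled margin where each crown meets the gingiva.
The stage works on raw point clouds:

1. **Normals.** PCA normals: for each point, the eigenvector with smallest
   eigenvalue of the covariance of its `normal_k` (default 20) nearest
   neighbours, oriented toward a viewpoint 100 mm above the cloud centroid
   along +z (the occlusal direction in canonical pose). k-NN PCA normals
   at realistic sampling density are accurate to roughly 1–2.5°, which is
   ample for curvature signs and FPFH.
2. **Mean curvature.** For each point, its `curvature_k` (default 20, ≥ 6)
   neighbours are expressed in a local frame with the w-axis along the
   normal; the quadric `w = a·u² + b·uv + c·v² + d·u + e·v + f` is fitted
   by least squares via the Moore–Penrose pseudo-inverse and H is the mean
   curvature of that graph surface at the origin. Sign convention: a
   surface bending away from its normal is negative, so a sphere with
   outward normals has H = −1/r. Verified closed forms: plane 0 ± 1e−6,
   sphere and cylinder within 5% at ≥ 20 points per fitting neighbourhood.
   Rank-deficient neighbourhoods are flagged invalid, not raised.
3. **Thresholding.** Points with H < −0.6 mm⁻¹ are the contour. Under the
   convention above the threshold selects *convex* fine-scale structure:
   the gingival margin roll around each crown (tube radius well under
   1.6 mm ⇒ H below −0.6), while broad crown faces (|H| ≈ 1/r_tooth ≈ 0.3)
   and the gingiva sheet (H ≈ 0) survive. Concave valleys come out
   positive and are never selected.
4. **Denoising.** Connected-component filtering on the contour: points
   linked within `link_radius` (1.0 mm), components smaller than
   `min_component_size` (20) dropped. This is an automated, reproducible
   replacement for manual point-cloud cleanup.
5. **Subregions.** The gingival margin line is the height band within
   `gingival_band` (0.5) of the contour's z-range above its minimum; its
   three sectors partition it by angle about the arch centroid — anterior
   within 30° of the (±y) symmetry axis, remaining points left/right by
   sign of x. Canonical pose (occlusal +z, arch opening −y) is a
   precondition; the sector rule is sign-agnostic in y so a 180° pose flip
   about z swaps left and right but leaves the anterior sector fixed. The
   exact clinical boundary of the gingival line is inherently a judgement
   call; the height-band rule is a deterministic stand-in.

## Stage 2 — downsampling and FPFH description

**Voxel downsampling.** Axis-aligned cubes of edge `voxel_size` (default
1.0 mm) anchored at the cloud's minimum corner; each non-empty voxel emits
the centroid of its members. Boundary ties go to the lower-index voxel and
output order is the lexicographic voxel index, making the binning
bit-reproducible. Normals are averaged and renormalized (zero averages
fall back to the first member's normal).

**FPFH.** For a query point Ps with normal ns and neighbour Pt with normal
nt, the Darboux frame U = ns, V = U×(Pt−Ps)/‖·‖, W = U×V defines

    α = V·nt,   φ = U·(Pt−Ps)/‖Pt−Ps‖,   θ = atan2(W·nt, U·nt),

each binned into 11 equal sub-intervals of its range (α, φ ∈ [−1,1];
θ ∈ (−π,π]), giving a 33-bin SPFH per point over its exact in-radius
neighbourhood (`fpfh_radius`, default 5 × voxel_size = 5 mm; the
literature's standard rule of thumb, exposed as a config knob). Each
11-bin block is normalized to sum to 100, making descriptors independent
of sampling density. The fast variant re-weights neighbours' SPFHs by
inverse distance:

    FPFH(Ps) = SPFH(Ps) + (1/n) Σᵢ (1/ωᵢ)·SPFH(Pkᵢ).

Degenerate pairs (direction parallel to ns, cross-product < 1e−12) are
skipped, not binned; exactly coincident duplicates are excluded from the
neighbourhood. FPFH is rigid-invariant to float tolerance and is checked
bin-for-bin against an independent O(n²) brute-force implementation on
small clouds.

## Stage 3 — registration and identification

**SAC-IA (coarse).** Per iteration: draw t = 3 random source points with
pairwise spacing ≥ `min_sample_spacing` (5 mm), pair each with its
nearest target descriptor in 33-D (exact nearest neighbour, ties to the
lowest index), fit the rigid transform of the 3 pairs in closed form, and
score the candidate on the **full pre-downsampling clouds**: fitness =
fraction of transformed source points with a target neighbour within
`corr_dist` (2 mm), RMSE = root mean square of those inlier distances.
After `sacia_iterations` (1000) candidates, the lexicographically best
(fitness descending, then RMSE ascending) wins; first occurrence wins exact
ties. One seeded generator owned by the call makes the result bit-for-bit
reproducible. Scoring is exact but pruned: a point outside the target's
corr_dist-expanded bounding box cannot match, so candidates whose
inside-box fraction cannot strictly beat the current best fitness are
skipped without a nearest-neighbour query — the selected candidate is
provably identical to exhaustive scoring.

**ICP (fine).** Seeded with the SAC-IA transform; iterates exact
nearest-neighbour pairing within `corr_dist`, rejecting pairs whose
normals differ by more than `normal_angle_max` (45°, applied only when
both clouds carry normals; the rejection is disableable), then the
closed-form update (centroid subtraction + SVD of the cross-covariance
with a reflection guard) minimizing the mean squared pair residual
E(R,T) = (1/N)·Σ‖qₕ−(R·pₕ+T)‖². Terminates when the inlier RMS error
changes by less than `icp_tol` (1e−6 mm) or after `icp_max_iter` (50)
iterations. Zero correspondences at the first iteration return a
non-converged result with fitness 0 rather than raising.

**Identification.** A query is registered against every gallery entry; the
entry with the smallest RMSE is the identity. RMSE decides — genuine and
impostor fitness distributions overlap (most impostor alignments still
place >90% of points within 2 mm of *some* target point) while RMSE
separates — and fitness breaks ties, then label order. Infinite RMSE
(no overlap) ranks last. Grid evaluation derives a per-pair seed from the
global seed and the two labels (CRC32, 31-bit), so the score matrix is
independent of evaluation order and trivially parallelizable.

`corr_dist` = 2 × voxel_size: large enough that a coarsely aligned genuine
pair keeps all points matched, small enough that impostor residuals
(0.3–1.5 mm at realistic inter-subject variation) stay well inside it and
remain informative rather than saturating.

## Synthetic test bed

Clinical scans are private, so the package ships generators that emulate
the relevant geometry (all seeded, pure functions of their parameters):

* `generate_contour` — the idealized stage-1 output: one closed margin
  ring per tooth (default 14 teeth × 150 points ≈ 2,100 points) along a
  parabolic arch 50 × 40 mm, with per-subject jitter in tooth radius
  (σ = 0.25 mm), centre position, ellipse eccentricity, radial harmonics,
  and a scalloped vertical undulation (amplitude ~1.2 ± 0.3 mm). These
  scales were chosen so genuine and impostor registration residuals land
  in the 0–1.5 mm range typical of real dentitions: measured on the
  default benchmark, genuine RMSE ≈ 0.08 mm (at σ_noise = 0.05 mm) and
  impostor RMSE ≈ 0.67–1.32 mm.
* `generate_arch` — a full surface stand-in for testing stage 1: gingiva
  sheet (H ≈ 0), spherical crown caps (H ≈ −1/3 mm⁻¹), and a convex
  margin roll per crown (torus tube, radius 0.55 mm, fitted H ≈ −1 mm⁻¹),
  sampled at 0.25 mm arc-length spacing so a 20-neighbour quadric fit is
  well-conditioned. Curvature thresholding at −0.6 recovers exactly one
  ring per tooth.
* `perturb` — repeat-scan model applied in order: angular-sector regional
  deletion (simulated tooth loss), uniform dropout of ⌊n·fraction⌋ points
  without replacement (exact, testable counts), i.i.d. Gaussian coordinate
  noise, and a random rigid pose change (axis uniform on the sphere, angle
  uniform in [0, max_rotation], translation norm uniform in
  [0, max_translation]) returned as ground truth.
* `build_benchmark` — n subjects' contours as gallery, one perturbed query
  each, with truth map and ground-truth transforms; subject and scan seeds
  derive from the master seed via CRC32.

Default perturbation (rotation ≤ 30°, translation ≤ 10 mm,
σ = 0.05 mm, 20% dropout) reflects a plausible repeat-scan scenario:
arbitrary scanner pose, sub-0.1 mm sensor noise, moderate coverage loss.

**What the synthetic results do not show.** The generators vary tooth
size/position only, not arch topology, occlusion, wear, restorations, or
scanner-specific artefacts; inter-subject differences are statistically
homogeneous rather than anatomically structured. A 100% Rank-1 rate on 20
synthetic subjects therefore demonstrates that the pipeline's machinery
(feature extraction, descriptors, coarse-to-fine registration, score
separation) is sound at clinically plausible noise scales — it is not a
claim about recognition rates on real populations.

## Numerical and design notes

* Rigid fits guard against reflections (determinant sign flip on the
  smallest singular value) and raise on collinear point sets (second
  singular value ≤ 1e−9 × the first).
* SAC-IA sample spacing uses vectorized rejection; if the constraint is
  unreachable (tiny clouds) it is relaxed with a warning after 200 redraw
  rounds rather than looping forever.
* The θ bin for θ = π is clipped into the top bin; atan2 never returns −π
  for normalized inputs.
* Score-matrix pixmaps min–max scale to 0–255 after capping infinite RMSE
  entries to their row's finite maximum; a constant matrix maps to 0.
* Problem sizes in the shipped experiments (20 subjects, ~2,100-point
  contours, 1,000 SAC-IA candidates) keep a full 20×20 identification
  grid at roughly two to three minutes on one CPU while leaving the
  genuine/impostor margin wide; all sizes are parameters.

## Known limitations

* Stage 1 assumes canonical pose for subregion segmentation; no automatic
  pose normalization is provided.
* Mean curvature is point-cloud-based (quadric fitting); it will differ
  from mesh-based curvature near borders and at density discontinuities,
  where points are flagged invalid rather than estimated.
* Identification is closed-set: every query is assumed to have a gallery
  mate; there is no reject option.
* Registration is single-direction (query onto gallery) and strictly
  rigid; point-to-plane ICP and non-rigid variants are out of scope.
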