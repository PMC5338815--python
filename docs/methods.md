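# Methods

## Model and assumptions

The package treats inter-subject brain-shape difference as the size of the
diffeomorphic deformation connecting two images.  Deformations are
parameterised by stationary velocity fields (SVFs): the transform is
φ = exp(v), its inverse exp(−v), so a single field encodes both directions of
a registration and its ROI-restricted norm serves as a symmetric
dissimilarity.  This quantity is *not* guaranteed to satisfy the triangle
inequality — only symmetry, non-negativity and zero self-distance are
asserted or tested.  Downstream, classical metric MDS assumes the
dissimilarities are approximately Euclidean; negative eigenvalues of the
double-centered matrix are reported on the fitted model and never used for
coordinates.

Assumptions worth keeping in mind:

- **Shared contrast.** The demons data term and the internal affine
  registrar are driven by squared intensity differences, appropriate when
  all images share one contrast (the phantom case, or a single-protocol T1
  cohort after normalisation).  Multi-site or multi-contrast data would need
  a robust similarity metric, which is not implemented.
- **Pre-alignment.** Pairwise distances are meaningful only after global
  position/scale differences are removed; run the affine stage (or supply
  pre-aligned inputs with `skip_affine`).

## Registration parameters

The demons defaults (all exposed in `RegistrationParams`) follow common
log-domain practice:

| parameter | default | meaning |
|---|---|---|
| `pyramid_levels` / `iters_per_level` | 3 / (30, 30, 20) | Gaussian pyramid, coarse → fine iteration caps |
| `sigma_fluid` | 1.0 mm | Gaussian smoothing of the update field (fluid-like regularisation) |
| `sigma_diffusion` | 1.5 mm | Gaussian smoothing of the velocity field (diffusion-like regularisation) |
| `intensity_sigma_x` | 1.0 | demons force step bound; images are jointly rescaled to [0, 1] by the 1st–99th percentile so this is on intensity scale |
| `force_type` | symmetric | gradient term averages fixed and warped-moving gradients |
| `bch_order` | zeroth | update rule Z(v, u) = v + u; `first` adds ½[v, u] |
| `exp_steps` | auto | scaling-and-squaring depth: smallest N with max‖v‖/2ᴺ < 0.5 voxel |
| `stop_tol` | 1e-4 | relative MSE change for early stopping |

Zeroth-order BCH is the default because it is the standard demons update;
the first-order rule is provided and verified (on 8³ random smooth fields it
approximates the dense composition exp(v)∘exp(u) more closely in every
trial).  Boundary handling is edge-clamped sampling with one-sided gradient
stencils; velocity and displacement fields are stored in world millimetres
on the fixed grid.

The affine stage optimises 12 parameters (translation, rotation, log-scale,
shear, about the grid centre) by multi-resolution Powell descent on the mean
squared intensity error.  On a smooth, nearly ellipsoidal image the SSD
objective barely constrains shear, so sheared solutions can score as well as
the true transform; recovery to printed tolerances (translation < 0.5 voxel,
scale < 2%) holds on structured images, which is what anatomies are.

## Distance definition

Two norm modes are offered for ‖·‖ over an ROI mask:

- `l2` (default): √Σ‖v(x)‖² over masked voxels — the literal unnormalised
  field norm.  It scales with ROI size (units mm·voxel^½).
- `mean`: mean per-voxel magnitude (mm) — ROI-size invariant.

The second distance term masks the velocity in the moving subject's own
frame: −v is pulled back through the inverse deformation and masked with
that subject's labels (a `mask_in_fixed_frame` flag instead warps the moving
mask into the fixed frame; both readings agree for well-behaved pairs).
Pair orientation is deterministic (lower cohort index fixed); inverse
consistency of the registration makes the choice immaterial to tolerance.
Pairwise registrations are independent, can run in parallel (`jobs`), and
are cached on disk keyed by a content hash of the two images and the
parameter set, so reruns cost nothing and edited inputs invalidate stale
entries.

**Dose-response analyses use the `mean` norm.**  A volumetric atrophy dose
shrinks the ROI itself, so the size-dependent `l2` norm confounds growing
per-voxel displacement with a shrinking voxel count (and at coarse grids the
strongest dose can even lower the summed norm).  The per-voxel mean isolates
deformation magnitude and is monotone in the dose under the default
registration parameters.

## Embedding

Squared distances are double-centered (B = −½ J D⁽²⁾ J); subject coordinates
are e_im = √λ_m v_im from the top-M eigenpairs, M = 3 by default (the
smallest space in which the study contrasts separate, and cheap to
visualise).  The Nyström out-of-sample projection uses the matching
√λ scaling — the unique choice under which projecting a training row
reproduces that subject's training coordinates exactly; this identity is
enforced by test.  A compatibility flag centers *raw* distances instead;
that variant remains internally self-consistent but no longer reproduces
Euclidean geometry, which is why squared centering is the default.
Eigenvector signs are fixed (largest-magnitude entry positive) and ties
resolve by original index order, making embeddings deterministic and
permutation-equivariant.

## Classification protocol

Linear C-SVM with C = 1 (no hyperparameter search).  Folds are stratified by
default (the study groups are unbalanced); fold sizes differ by at most two.
Two CV protocols exist because embedding-then-cross-validating is ambiguous:

- `fold_honest` (default): each fold refits MDS on the training submatrix
  and projects held-out subjects via Nyström.  No information about held-out
  subjects reaches the training eigendecomposition (tested by perturbing a
  held-out subject's distances and asserting a bit-identical training
  embedding).
- `transductive`: embed the full cohort once, cross-validate the classifier
  only.  Kept for leakage audits and comparison; on separable synthetic
  cohorts the two agree closely.

Confusion counts are pooled over folds (micro-average), metrics reported as
percentages rounded to two decimals; ROC/AUC from pooled signed decision
values by threshold sweep with trapezoidal area (equal to the tie-corrected
concordance statistic, verified to 1e-12 against a brute-force pair count).
Metrics with zero denominators are reported as undefined, never as zero.

## Phantom generator

The phantom emulates the features of a clinical cohort that the chain
depends on: a shared template with labeled substructures (white-matter core,
gray-matter shell, two subcortical blobs), per-subject smooth random
diffeomorphic warps (inter-subject anatomical variability), group-specific
volumetric atrophy of selected ROIs, and additive Gaussian intensity noise.
Defaults define the study conditions used throughout the tests:

- grid 32³ at 1 mm isotropic spacing (geometry rescales to other grids while
  keeping a >2-voxel margin);
- random warp: white Gaussian vector noise smoothed at 4 mm, scaled to
  1.5 mm maximum displacement, exponentiated by scaling and squaring;
- intensity noise σ = 0.02 on unit-scale intensities (≈ SNR 30–50 for the
  structure contrasts used);
- atrophy: hippocampus-analog linear contraction 0.7 in the disease group
  (≈ 34% volume loss — the strong end of hippocampal atrophy in established
  disease), implemented as an exact radial scaling about the ROI centre
  inside the ROI, blended by a cosine ramp to identity at twice the elliptic
  radius.  The composite map's Jacobian determinant is checked positive
  everywhere; non-diffeomorphic settings raise instead of producing folded
  anatomy.
- two groups of 10 subjects, matching a small pilot-study arm.

Atrophy is applied first, then the random warp, composed into a single
displacement so image (trilinear) and labels (nearest-neighbour) stay
voxel-consistent.  Per-subject seeds spawn deterministically from the spec
seed.

What the phantom does **not** emulate: MRI physics (bias fields, partial
volume, skull), cortical folding, multi-modal contrast, or segmentation
error — passing tests demonstrate the correctness of the computational chain
under controlled deformations, not clinical performance.  Nearest-neighbour
label resampling biases warped ROI volumes at small structure sizes (the
f³ volume-ratio contract is tested at 64³ where the discretisation error is
a few percent).

## Problem sizes

The test suite and the acceptance script run the full study at reduced
scale: classification on two groups of 10 subjects at 32³ (190 pairwise
registrations), the dose-response sweep on 5 + 5 cross-pairs at 24³, and the
null-effect suite at 24³ — sizes chosen so the complete chain, not a
shortcut, executes on a single CPU in minutes while preserving the
behaviours under test.

## Known limitations

- The velocity-norm dissimilarity is a surrogate, not a geodesic metric on
  the diffeomorphism group; MDS embeddings of strongly non-Euclidean
  matrices lose information (negative eigenvalues are reported).
- SSD-driven registration restricts inputs to shared-contrast images.
- The n(n−1)/2 pairwise-registration cost grows quadratically with cohort
  size; the cache and `jobs` parallelism mitigate but do not remove this.
- Small ROIs (a few voxels across) sit below the demons regularisation
  scale; distances there under-report strong local deformation.
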