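# Methods

This note documents the models, parameters and numerical choices behind
`noseguard`, and what the synthetic phantom can and cannot show.

## Coordinate conventions

All coordinates are in mm, right-handed. Three frames are used:
`device` (digitizer), `mri_world` (NIfTI affine applied) and `head`,
the Neuromag-style frame built from the fiducials: x from LPA to RPA,
origin at the foot of the perpendicular from the nasion to the LPA–RPA
line, y toward the nasion, z = x × y. The nose-point exclusion rule —
drop points with y > 0 **and** z < 0, strict inequalities, fiducials
exempt — is defined in this frame only, and `exclude_nose_points`
refuses any other frame tag. Rigid transforms are 4×4 homogeneous
matrices with orthonormality and properness (det = +1) validated at
construction.

## The head phantom

Subjects are generated by deforming a shared template, so that
atlas-registration ground truth exists for every subject.

**Template geometry** (fixed physical size, default grid 52×56×48 at
3 mm): a superellipsoid head (semi-axes 60/70/65 mm, exponent 2.5) with
a protruding nose ellipsoid, two ear bumps, and concentric brain
(45/48/50 mm) and skull shells. The nasion sits at the nose root on the
midline; LPA/RPA at the lateral ear-bump tips — all on the head surface
by construction. Intensities are piecewise constant (air 0, soft tissue
0.7, skull 0.3, brain 1.0) with a smooth low-frequency modulation
inside brain (±0.15) and soft tissue (±0.08) standing in for grey/white
and tissue contrast; without it, intensity-driven registration would
have no signal inside flat compartments. A final 0.7-voxel Gaussian
smooth gives usable gradients.

**Face and de-face regions.** The face class is a thin outer shell of
the head superellipsoid (level set 0.80–1.0, ≈5 mm deep) restricted to
the anterior face below the brow line (y > 30, z < 5), excluding a
dilated nose, the ears, the skull and a 3-voxel brain guard. The guard
exists so that tissue-map smoothing plus a slightly imperfect warp can
never push face probability above the trimming threshold inside the
brain. The standard de-facing comparator is the classic face-covering
cuboid (y > 44, z < 25): it removes the nose and cuts deep to the
facial bones, reaching above the eyes, as common de-facers do. The
relative aggressiveness — trimming a shallow skin shell, de-facing a
deep cut including the nose — is what makes the two conditions behave
differently downstream; both regions avoid the brain by construction.

**Tissue probability map.** Hard labels (background, soft tissue,
skull, brain, face) smoothed with a 0.7-voxel Gaussian, renormalized to
sum to one, with the face class explicitly zeroed on the (dilated) nose
and near-brain regions before renormalization.

**Subject deformation.** A band-limited random field: six separable
sine modes per component with wavenumbers 1–2 across the field of view,
scaled to a peak magnitude of `deform_amplitude_mm` (default 4 mm).
Fields are rejected and redrawn (up to 5 attempts) unless the Jacobian
determinant of id + u stays above 0.05 on the grid; the numerical
inverse (fixed-point iteration, 40 steps) must round-trip within 0.1
voxel. Volumes and masks are pulled through the inverse map with
trilinear interpolation (masks thresholded at 0.5); fiducials and the
scalp/inner-skull meshes are pushed through the forward map, keeping
all ground truth mutually consistent.

**Digitized points.** Fiducials plus `n_scalp` points sampled
area-weighted on the upper scalp (z > 10 mm, outside the nose box) and
`n_nose` points on the nose surface, perturbed by isotropic Gaussian
noise and mapped into the device frame. The noiseless source locations
ride along for ground-truth evaluation.

## Registration

**Affine (12 dof).** Translation, Euler rotations, log-scales and
shears (the latter two in percent units so Powell sees comparable
scales), composed about the template's intensity centroid; sum of
squared intensity differences on a strided, Gaussian-smoothed pyramid
(strides 4/2/1, σ = 2/1/0.5 voxels); Powell search per level.

**Nonlinear.** Thirion-style demons on the same pyramid: update
u ← G_elastic ∗ (u + G_fluid ∗ step), step = diff·∇W/(‖∇W‖² + diff²)
clipped to 0.8 voxel, σ_fluid = σ_elastic = 1 voxel, 60/40/15
iterations. Each level tracks the best-energy state and reverts to it,
so the per-level energy never ends above its start (persistent increase
raises `RegistrationDivergence`); intensity mismatch from zeroed
regions otherwise makes late full-resolution iterations oscillate. The
returned field is the demons field composed with the initial affine,
smoothed further (up to 3×, σ = 1 voxel) if its Jacobian ever turns
non-positive. The inverse is cached per field. On the 4 mm phantom the
field is recovered to ≈0.8 mm mean error over the head.

**Tissue labeling.** Every TPM class is pulled through the inverse
deformation with trilinear interpolation — nearest-neighbour would
alias the 10% trimming boundary — and renormalized per voxel.

## Anonymization

`trim_face` zeroes voxels with face probability strictly greater than
the threshold (default 0.10; a voxel at exactly 0.10 is retained) and
leaves everything else bit-identical; removed voxels are set to 0
rather than noise-filled so the operation is deterministic and
idempotent. `deface_full` applies a boolean mask verbatim (face
including nose). Both return an audit report (voxels removed/changed,
fraction of head, brain/nose voxels altered when masks are supplied).

## Coregistration

Exact point-to-triangle distances (face/edge/vertex cases via the
barycentric region classification) with candidates from a cKDTree over
face centroids plus faces incident to the nearest vertices; exactness
is tested against brute force over all triangles. ICP alternates exact
closest points with the Kabsch fit; all starts iterate in lockstep so
closest-point queries batch into one lookup per iteration. Defaults:
10 starts (the initialization plus 9 perturbations of up to ±15° per
axis and ±10 mm about the point centroid — declared values, since no
published scheme exists), convergence when the RMS change drops below
1e-4 mm (cohort harness: 1e-3 mm, still three orders below digitization
noise), 200 iterations cap, no outlier trimming. The per-iteration RMS
is non-increasing by construction and asserted. The two-step procedure
fits the three fiducial pairs first and refines with ICP on the
non-fiducial points; with `use_nose=False` the head-frame nose rule is
applied first.

## Surfaces

Scalp extraction: threshold → largest connected component →
morphological closing (radius 2) → marching cubes on the padded mask →
Taubin smoothing (10 iterations; unlike plain Laplacian it does not
shrink) → world coordinates via the affine. The canonical inner skull
is the level-4 icosphere (2562 vertices) scaled into the template
brain; subject surfaces are obtained by displacing its vertices through
the template-to-subject field, preserving topology and index
correspondence. Surface comparison is therefore vertex-wise; optional
rigid alignment uses corresponded least squares (Procrustes without
scaling — the closed-form optimum, no iteration needed), with a guard
that falls back to the identity if the unsquared mean would increase,
so alignment never raises the reported error.

## Cohort simulation and statistics

Per subject: one phantom, one registration of the intact image (used
for trimming, the de-facing mask, and the intact inner skull), separate
registrations of the trimmed and de-faced images for their inner-skull
surfaces, one shared digitized point set under a random device
transform (paired design — only the MRI condition and the nose-point
exclusion differ), and six coregistrations (3 conditions × with/without
nose points). Recorded per row: the fiducial-error proxy, the
fiducial-only baseline, the error against the known device transform
(reported because the proxy is itself corrupted by marking noise), and
the inner-skull surface errors before/after alignment plus their
anterior/posterior means.

Study conditions (defaults, chosen once): 100 scalp + 10 nose points;
scalp noise 1.5 mm (electromagnetic-digitizer class); fiducial noise
2.9 mm per axis on each side, which puts the median fiducial-only
baseline error near 4.2 mm — the calibration anchor for the noise
level; device transform up to ±20°/±30 mm; deformation amplitude 4 mm;
n = 30 subjects at seed-controlled reproducibility (5 is the minimum
for the paired tests).

Statistics: Wilcoxon signed-rank with zero differences dropped and
mid-ranks for ties; the exact two-sided null is computed by the shift
algorithm over doubled ranks for n ≤ 25 and a continuity-corrected
normal approximation with tie-corrected variance above (the test suite
checks the exact branch against full 2ⁿ sign enumeration and scipy).
Welch's t with Satterthwaite df, or the one-sample t on differences
when paired. The JZS Bayes factor BF01 places a Cauchy prior (scale
√2/2, the conventional default, configurable) on the standardized
effect and integrates the noncentral-t marginal by adaptive quadrature;
tests verify it against the independent inverse-gamma g-mixture form to
1e-6 relative. No multiple-comparison correction is applied; raw
p-values are reported.

## What the phantom does and does not show

The generator reproduces the *mechanisms*: near-hemispherical scalp
symmetry (slippage), the nose as the symmetry-breaking anchor, thin-
shell versus deep-cut anonymization, and registration-mediated
distortion of the canonical inner skull concentrated frontally. It does
not model MRI physics (bias fields, sequences), realistic anatomical
variability (sinusoidal fields only), digitizer drift, or operator-
dependent fiducial placement biases. Passing tests therefore establish
correct algorithms and the direction and interaction of the published
effects, not clinical-scale error magnitudes; absolute errors here are
smaller than on real cohorts because the phantom's scalp is noiseless
and its deformations smooth. Problem sizes (52×56×48 at 3 mm, 30
subjects, 10 ICP starts) are the package defaults chosen to make the
full paired design comfortably reproducible on a laptop.

## Known limitations

- The demons registration is local; global low-dimensional warps (as
  in DCT-basis normalization) would transmit face removal to deeper
  structures somewhat differently. The frontal concentration of the
  de-facing effect is robust to this choice; exact ratios are not.
- The single-ellipsoid skull puts the "inner skull" closer to the lower
  face than in real anatomy, which is why the trimming region stops at
  the brow line and stays shallow.
- `compare_surfaces` relies on index correspondence and is meaningless
  for meshes of different topology (it refuses them).
- Exact Wilcoxon p-values require n ≤ 25 after zero-removal; beyond
  that the normal approximation is used.
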