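# Methods

## The problem and the pipeline

A single-voxel MRS prescription is a cuboid: dimensions (dx, dy, dz) in mm,
a center coordinate, and three console angulation angles — T>S (about x),
T>C (about y), Rotation (about z).  `avp` treats placement as a transport
problem between a template brain and each subject's anatomy:

1. **Authoring** (`prescribe.create_template_voxel`): the cuboid is defined
   once in template space, rendered for appraisal, and stored in a plain
   tab-separated library keyed by (study, description).
2. **Prescription** (`prescribe.prescribe_voxel`): a rigid 6-dof
   template→subject registration contributes the rotation; a 9-dof
   rotation+scale registration contributes the center mapping.  Dimensions
   are copied unchanged: head-size differences move the voxel's center but
   never resize the acquisition volume.  The result is reported at full
   precision and quantized to 0.1 mm / 0.1° (scanner entry precision).
3. **Quality control** (`overlap`): acquired voxels are reconstructed in
   template space by the mirrored procedure (subject→template) and compared
   as partial-volume masks.

## Conventions

* **Euler convention.** One convention everywhere, construction and
  decomposition: `R = Rz(Rot) · Ry(T>C) · Rx(T>S)` (intrinsic x→y→z),
  applied about the voxel center.  Decomposition refuses inputs within
  0.01° of T>C = ±90° (gimbal lock) rather than guessing.  Angles are
  canonicalized to (−180°, 180°], ties to +180°.  Whether a particular
  scanner host's sign convention matches is not decidable from geometry
  alone; the package guarantees internal self-consistency, which is all the
  overlap metrics depend on.
* **Frames and grids.** All coordinates are world millimetres under the
  image header affine (0-based indices; NIfTI pixel-center affines).  Masks
  live on regular grids with half-open extent `[origin, origin +
  shape·spacing)`; `Grid.for_spec` anchors the grid so the voxel center
  falls on the pixel-boundary lattice, which makes an unrotated voxel with
  spacing-multiple dimensions cover whole pixels exactly.
* **Angle composition in prescription.** The subject-frame voxel rotation
  is `R_registration · R_voxel` — voxel axes rotate with the anatomy.  The
  reconstruction step applies the same rule with the subject→template
  registration, so prescription and reconstruction are mutually inverse up
  to registration error; both directions are validated against phantom
  ground truth.
* **Scaling anchor.** 9-dof transforms are parameterized as rotation ·
  diagonal positive scale about the fixed image's world center (log-scale
  parameters keep scales positive).  The anchor choice is a free
  convention; anchoring at the fixed-image center decouples scale from
  translation.

## Partial-volume rasterization

A rotated cuboid's edge pixels are partially occupied, so binarizing at any
single cutoff misstates the volume ("partial volume problem").  Masks are
rendered at 0.5 mm isotropic with each pixel holding its occupied fraction:
pixels wholly inside/outside the cuboid (slab distance beyond the pixel
half-diagonal) are classified exactly; boundary pixels are supersampled on
a regular 5×5×5 lattice (deterministic, and checkable against exact
polygon clipping in 2D; tests raise the subdivision where tighter error is
needed).  The estimator conserves volume: summed fractions times pixel
volume match dx·dy·dz to well under 1% (typically ~1e-5 relative).

The **threshold table** reports, per candidate threshold t ∈ {0.05, …,
0.95}, the superlevel pixel count (strict `value > t`), its volume, and
"Percent Total Voxel" = 100 · volume / nominal volume.  Threshold
selection: the t whose Percent Total Voxel is closest to, without
exceeding, 100%; an unrotated voxel (all angles zero within 1e-6°) takes
0.95 outright.  Strict inequality makes t = 0.95 immune to edge values
sitting exactly at 0.95.  For the package's reference dlPFC voxel
(15×20×15 mm at 7/20/15°) the table gives 97.4% at t = 0.65.

## Registration

The pipeline consumes registration through a backend contract: callable
`(moving, fixed, dof, init) → RegistrationResult` returning the
moving-world→fixed-world transform.  The built-in backend:

* similarity: correlation ratio η²(moving | fixed bins), 32 equal-width
  bins of the fixed image; trilinear interpolation of the moving image;
* schedule: 4×/2×/1× pyramid (Gaussian smoothing σ = shrink/2 voxels at
  coarser levels), with a coarse per-axis rotation grid search (±30°, step
  10°) at the coarsest level when unitialized, then Powell refinement per
  level (xtol 3e-4·shrink, ftol 1e-8·shrink);
* sampling: fixed-image samples capped at 16 000 per level by a
  deterministic stride, **jittered** by a fixed pseudo-random subpixel
  offset.  Lattice-pinned samples let the cost reward subpixel
  misalignment — interpolation smooths the pulled-back intensities and
  shrinks within-bin variance whenever the two images share pixel-level
  structure (self-registration being the extreme case); jitter removes
  that asymmetry.  The jitter is a fixed constant, not a per-run random
  draw: identical inputs give bit-identical transforms;
* dof = 9 runs dof = 6 first and refines with three log-scales, skipping
  the coarsest level when warm-started.

Sampling density is the accuracy knob: at the 16 k default, sampling noise
displaces the optimum by roughly 0.1–0.2° / 0.05 mm on 2 mm phantoms —
ample for ≥ 95%-overlap placement (observed ≥ 99.9%) and fast enough for
many-seed property tests; at 100 k samples the built-in agrees with a
SimpleITK registry to < 0.2% induced voxel overlap.  A registration that
fails to improve on the identity transform is returned with
`converged=False` and a warning, never silently.

## Overlap metrics

All metrics share one construction — average the relevant masks pixelwise,
count pixels strictly above the selected threshold, divide by the
denominator mask's count:

* accuracy: numerator (subject + template)/2, denominator template;
* between-subject (per timepoint): numerator mean of subject masks,
  denominator template;
* within-subject (per subject): numerator mean across timepoints;
  denominator **template voxel by default** — the defining text specifies
  the denominator only for the first two metrics, and sharing one
  denominator semantics keeps the three comparable; `denominator="first"`
  switches to the subject's first-timepoint voxel.

Tissue composition resamples GM/WM/CSF partial-volume maps onto the mask
grid (trilinear), sums each tissue inside the thresholded region, and
normalizes by the three-tissue total, so the percentages sum to 100 by
construction (reported conservation tolerance ±0.5).  CV% is
100·SD/mean with the n−1 sample SD.

Acquired-voxel geometry comes only from acquisition metadata: standard MR
Spectroscopy volume-localization DICOM fields (slab thickness (0018,9104),
slab orientation (0018,9105), mid-slab position (0018,9106); three
orthonormal slabs, coordinates taken in the subject frame as stored) or
the documented JSON sidecar.  Vendor-private headers (e.g. Siemens CSA)
are out of scope; real Siemens exports should be converted to the sidecar,
minding the LPS↔RAS sign convention of the first two axes.  Parsers never
return partial records.

## Synthetic phantom

`make_phantom` builds a T1-like head: nested ellipsoids (outer CSF shell,
GM ribbon at normalized radius 0.72–0.88, WM core) with two CSF ventricles
and two off-center blobs that break every rotational symmetry — without
them, registration of a concentric phantom is ill-posed.  Tissue
partial-volume maps come from the same analytic geometry (half-pixel soft
edges), so ground-truth tissue fractions are computable to arbitrary
precision.  Intensities are WM 1.0 > GM 0.7 > CSF 0.25 in arbitrary units,
times a mild low-order cosine bias field (1–3%), plus Gaussian noise with
σ = 2% of WM by default.  Profiles: 128³ at 1.5 mm (default) and 96³ at
2.0 mm ("quick"), both spanning a 192 mm field of view sized so
extreme-repositioning transforms (up to ~26 mm / ~17°) keep the head
inside; `perturb_subject` warns with an estimated clipped fraction
otherwise.  Identical seeds give bit-identical studies.

What the phantom does **not** emulate: cortical folding, skull/scalp
layers, susceptibility or coil profiles, pathology.  Phantom-based passes
demonstrate the pipeline's geometric correctness and the registry's
behaviour on clean, high-contrast anatomy; accuracy on real heads is
bounded by real registration quality, not established by these tests.

## Problem sizes used in the test suite

Property tests run on the quick phantom profile: self-registration on 3
phantoms, rigid parameter recovery over 8 random poses (median error
< 0.5 mm / 0.5°), and the end-to-end loop (phantom → prescribe → acquire →
reconstruct → accuracy ≥ 95%) over 10 seeds cycling through the three
extreme-repositioning transforms, using a 12 k-sample quick registration
profile.  These sizes are the package's chosen balance between statistical
coverage and a test suite that runs in minutes on one CPU; raising them
changes no default behaviour.

## Known limitations

* Euler-angle signs relative to any specific scanner host are unverified;
  only internal consistency is guaranteed.
* 12-dof (shear) transforms and nonlinear warps are out of scope; subjects
  with strong morphological deviation from the template (atrophy, tumor,
  injury) will degrade registration-based placement.
* Voxels are treated as perfect cuboids; RF-pulse edge roll-off is
  ignored for overlap purposes.
* The built-in registry is tuned for clean T1-like contrast; heavily
  biased or low-contrast images may need a plugged-in backend.
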