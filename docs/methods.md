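# Methods

## The procedure

`segsense` performs local sensitivity analysis of a segmentation model: a
single input image is transformed in a controlled, parametrized way across a
grid of parameter values, the model predicts on every transformed image, and
the effect on the prediction is reported qualitatively (overlay series,
animated GIFs) and quantitatively (per-class Dice curves against a ground
truth).  The analysis treats the model as a black box: its only required
interface is a prediction function mapping a grayscale image to an integer
label mask of the same shape, optionally preceded by a size-preparation
function.  No access to training data, gradients, or internals is needed,
which is what makes the probe framework-agnostic.

The central bookkeeping rule is the **mask co-transformation policy**.  Each
registered transform declares whether the ground-truth mask must travel with
the image:

* **geometric** transforms (rotate, dihedral flips, crop, zoom, resize) move
  anatomy, so the truth mask is transformed identically and Dice is computed
  in the transformed frame;
* **intensity** transforms (brightness, contrast, k-space spikes) leave
  geometry alone, so scoring uses the original, untouched mask.

Scoring in the transformed frame (rather than inverse-mapping predictions
back to the original frame) avoids a second resampling of the prediction and
makes the identity transform exactly neutral.

## Dice convention

For class c, Dice = 2|A∩B| / (|A| + |B|) over the supports A = {pred = c},
B = {truth = c}.  Degenerate cases: a class absent from both masks scores 1;
a class present in exactly one scores 0.  The one-empty→0 rule is what makes
a totally failed segmentation read as 0 across all classes.  Background
(class index 0) is excluded from reports by default.  The implementation is
cross-checked in the test suite against an independent double-loop
pixel-counting oracle, exactly, on seeded random masks.

## Transforms: numerical choices

* Images are float arrays normalized to [0, 1] on load (min–max; a constant
  image maps to all zeros as the divide-by-zero guard).  This makes
  brightness/contrast parameters dimensionless and model-independent.
* Interpolation is bilinear for images and nearest-neighbor for masks —
  nearest-neighbor is the only choice that preserves integer labels and can
  never invent a class.
* Rotations are clockwise in the raster display convention (origin top-left).
  Multiples of 90° are executed as exact axis permutations, not
  interpolation, so quarter-turn findings are bit-reproducible; the dihedral
  group (k = 0..7: quarter-turn count plus optional up/down flip) is exact by
  the same mechanism.
* Off-canvas regions created by rotation, zoom-out or oversized crops are
  filled with 0 — black background and the background class, matching MR
  appearance.
* Brightness is an additive shift clipped to [0, 1]; contrast is an affine
  gain about mid-gray 0.5, clipped.  Both are the simplest conventions on
  the normalized scale.
* Default grids: rotation 0–360° in 45° steps; dihedral 0–7; resize
  {16, 32, 64, 100, 128, 256, 320, 512} px (spanning collapse, stable and
  collapse regimes); brightness −0.5..0.5 step 0.125; contrast
  {0.25, 0.5, 1, 2, 4}; zoom {0.5, 0.75, 1, 1.25, 1.5, 2}; crop fractions
  {1, 0.75, 0.5, 0.25} of the short side.  Crop and resize have no
  sample-independent neutral value; `registry_with_size_neutrals` fills them
  per sample (crop at the short side, resize at the current size).

## k-space spike artifacts

A spike artifact is simulated by adding a single complex spike to the
centered 2-D DFT of the image at a fractional offset from the k-space center
along one frequency axis (offset 0 = DC, 0.5 = edge), with magnitude
`intensity_rel` times the maximum k-space magnitude of the original image
(for ordinary images, the DC coefficient).  Reconstruction takes the
magnitude of the inverse transform — mirroring MR magnitude reconstruction —
and clips to [0, 1].  Consequences used as tests: zero intensity is the
identity up to FFT round-trip error; a DC spike adds a near-constant offset;
an off-center spike produces stripes whose dominant non-DC spatial frequency
equals the injected coordinate; corruption energy (pre-clip L2 of the
difference) is monotone in intensity.

Two deliberate choices: a *single* spike is injected (not a conjugate-
symmetric pair), which produces the characteristic oblique stripes; and the
intensity reference is the k-space maximum rather than the image-domain
maximum, making `intensity_rel` invariant to image scaling.  Users wanting
the image-domain reference can scale `intensity_rel` by
`max|image| · N / max|K|` themselves; those wanting a strictly real
corruption can add the mirrored spike.

## The phantom and its oracles

The synthetic phantom emulates a short-axis cardiac slice at the level of
geometry only: an LV blood-pool disk (default radius 16 px), a myocardial
annulus around it (outer radius 24 px), and a lateral RV blob (radius 12 px,
offset 30 px), on a 128×128 canvas with the heart placed right of the image
center, plus seeded additive Gaussian noise (SD 0.02), clipped to [0, 1].
The paired mask is the exact rasterization of the same geometry with classes
BG/LV/MY/RV.  It does **not** emulate realistic MR contrast, coil profiles,
partial-volume texture or anatomy; passing tests therefore demonstrate
correctness of the *pipeline* (co-transformation, scoring, sweep mechanics),
not performance claims about real images or real models.

Structure mean intensities (BG 0.05, MY 0.35, LV 0.65, RV 0.95) satisfy two
constraints: they are pairwise separated by more than 4× the noise SD, so
nearest-mean classification is a valid oracle; and spatially adjacent large
structures are adjacent in intensity, so bilinear blending at their
boundaries crosses at most a neighbor's decision bin and spurious
third-class rings stay negligible under oblique rotation.  Background is the
lowest intensity so that zero-filled regions introduced by geometric
transforms classify as background.

Two analytic models close the test loop:

* `threshold_oracle` assigns each pixel the class of the nearest structure
  mean.  Per-pixel thresholding commutes with geometric transforms, so it is
  the *positive control*: its rotation/flip/zoom curves are flat (empirically
  min ≥ 0.97 on the default phantom, limited only by interpolation at
  non-quarter angles).  It is intentionally brightness- and
  contrast-sensitive — shifting intensities across its fixed decision
  boundaries — so intensity sweeps produce the characteristic sharp peak at
  the neutral parameter value.
* `right_biased_oracle` additionally suppresses all foreground in the left
  image half, a hard positional prior.  It reproduces, by construction, the
  failure mode of a model that keeps expecting the heart on one side even
  when the image is rotated by 180°: its LV Dice collapses from ≈1 at 0° to
  0 at 180°, giving a curve range ≥ 0.3 while the equivariant control stays
  ≤ 0.05.  Together the two oracles verify that the engine measures model
  properties rather than pipeline artifacts.

## Size preparation and the truth mask

When a model declares `prepare_size`, the engine applies it to each
transformed image before prediction.  If that changes the shape, the truth
mask is carried through the *model's own* preparation: each class indicator
image is passed through `prepare_size` and the per-pixel argmax taken.  This
keeps the truth aligned whether the preparation pads, crops or resamples
(pure nearest-neighbor resampling of the mask would silently misalign a
padding-style preparation); all-zero regions such as padding argmax to
background.  Preparations that are not monotone per channel (e.g. heavy
nonlinear intensity remapping) could in principle perturb the argmax, but
such functions are intensity-only and do not change shape, in which case the
truth is used untouched.

## Determinism and degenerate inputs

Sweeps are eager, sequential and free of hidden randomness: two runs with
identical inputs produce bit-identical curves, and the CLI writes
byte-identical CSVs across reruns.  The only randomness in the package is
the phantom's seeded noise generator.  Degenerate cases are defined rather
than rejected: a constant image normalizes to zeros, 1×1 resizes are legal
(Dice degenerates to the empty-class conventions), and zoom/crop precondition
violations (non-positive parameters) raise parameter errors.

## Problem sizes

All shipped analyses run on 128×128 phantoms with 9-point rotation grids,
8-element dihedral grids and 5–9-point intensity grids — sizes at which the
full test suite and the acceptance script each complete in well under a
minute on a single CPU while exercising every code path end to end.

## Known limitations

* Single-image, local interpretability only: no batch mode over image sets,
  and no scalar sensitivity indices — curves are descriptive.
* 2-D only; DICOM/NIfTI support is restricted to single slices and
  orientation metadata is deliberately not auto-applied (orientation
  sensitivity is a thing one measures with this tool, and auto-reorientation
  would hide it).
* Dice is the only metric; the `ClassScores` container is metric-agnostic,
  so boundary metrics could be added without changing the engine.
* The spike simulation covers single-spike artifacts only — no motion,
  ghosting, wrap-around or bias-field models.
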