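# Methods

This note records the models, conventions and numerical choices behind
`xrh`, in the spirit of a methods section: what each stage assumes, which
parameters matter, and what the synthetic phantoms do and do not emulate.

## Imaging model and conventions

The toolkit operates on reconstructed μCT volumes of unstained FFPE tissue
blocks. Gray values are proportional to X-ray attenuation, which for these
specimens orders the three materials present in every field of view as
air < paraffin wax < soft tissue. No attempt is made to model acquisition or
reconstruction; volumes enter the pipeline already reconstructed.

Conventions fixed across all modules:

- volumes are indexed `data[z][y][x]`, zero-based; the XY plane (fixed `z`)
  is the plane parallel to the histology cassette, so scrolling in `z`
  emulates serial physical sectioning;
- voxels are isotropic with size in μm (`8.48` in the default fixtures,
  a realistic value for cassette-scale soft-tissue μCT); the physical
  coordinate of a voxel centre is `index × voxel_size_um`;
- raw volumes are headerless little-endian binaries and always travel with
  a JSON sidecar (shape, dtype, voxel size, calibration state). Nothing is
  guessed from file contents;
- 16-bit data are unsigned with full range [0, 65535];
- each volume carries a calibration state (`raw` → `preprocessed` →
  `calibrated`) so stages can refuse inputs in the wrong state.

## Preprocessing

A fixed three-step chain conditions reconstructed 32-bit volumes:

1. **3D median filter**, cubic window of half-width `radius` (default 1,
   i.e. a 3×3×3 window). A radius-1 cubic window is the smallest
   neighbourhood that actually denoises; the radius is exposed as a
   parameter.
2. **Per-slice 2D unsharp mask**, `(I − w·G_σ(I)) / (1 − w)` with
   σ = 2 px and weight w = 0.6 by default. The normalisation by `1 − w`
   keeps flat regions (wax, air plateaus) at their mean value, so later
   histogram-based calibration is not biased by the sharpening step. The
   weight is a free parameter; 0.6 is a conventional default for
   unsharp-mask sharpening of CT slices.
3. **Linear windowing to 16 bit**: gray values in `(lo, hi)` (default
   `(−50, 100)`, bracketing air, wax and soft tissue in reconstructed FFPE
   data) map linearly onto [0, 65535], clamped outside, rounded half-up.
   Round-half-up makes quantization deterministic and bit-exactly testable.

Both filters use edge replication at borders, which avoids introducing
out-of-range values near the block edges.

## Gray-value calibration

Each scan's reference materials give a **contrast factor**
`CF = (I_wax − I_air)/I_wax`; a sample is aligned to a dedicated wax-phantom
scan by the **calibration factor** `k = CF_phantom / CF_sample`. The sample
volume is multiplied by `k` and offset by `k·I_air,sample`, driving the air
mean to 0. Two consequences worth stating explicitly:

- the calibrated wax level equals `CF_phantom × I_wax,sample` (derivable by
  substituting the definitions), which is what "transferring the phantom's
  contrast" means operationally;
- self-calibration of the phantom has `k = 1` exactly and only shifts by
  the air offset.

Material levels come either from caller-supplied ROI masks (exact means) or
from the histogram of the central z-slice: the histogram is smoothed
(Gaussian, σ = 2 bins over 256 bins), modes are found by peak detection,
air is the lowest-gray mode and wax the next, and each material's level is
the mean gray value of the voxels in its mode's basin (split at midpoints
between peak positions). A scan whose central slice shows fewer than two
modes is rejected rather than guessed at.

Clipping: stored 16-bit calibrated volumes are rounded and clipped to
[0, 65535], so stored gray values are always non-negative with air at 0.
Float volumes keep sub-zero noise excursions: clamping a zero-mean noisy
air population would bias its mean upward by ~σ/√(2π), silently breaking
the air-zero property the calibration exists to provide. Clipping is
therefore the storage layer's job, not the calibration's.

**Stability reporting** summarises per-specimen mean gray values of wax and
tissue across calibrated scans by grand mean, SEM (sd of specimen means /
√n) and maximum percent fluctuation `max|mean_i − grand|/grand × 100`. A
stable, well-calibrated protocol keeps wax fluctuation below ~1% and tissue
below ~2% (tissue is inherently more variable, being electron-density
inhomogeneous).

## Morphometry

Segmentation is absolute thresholding within a volume of interest;
the threshold is a **required** parameter everywhere, including the CLI,
because cross-specimen comparability hinges on applying the identical
absolute threshold to every calibrated data set — the protocol constrains
the procedure, not the number.

**Local thickness** follows the maximal-inscribed-sphere definition: the
thickness at a point is the diameter of the largest sphere containing the
point and fitting entirely within the structure. The implementation is the
classical Euclidean-distance-transform → distance-ridge → sphere-painting
pipeline with one fixed digital-geometry convention:

- EDT(c) is the distance from foreground voxel c to the nearest background
  *voxel centre*, with everything outside the grid treated as background
  (realised by a one-voxel background ring before the transform);
- the maximal ball at c has radius `EDT(c) − 0.5` and covers voxels q with
  `‖q − c‖ < EDT(c)`;
- thickness(p) = max over covering balls of `2·(EDT(c) − 0.5)`, in μm.

Under this convention an isolated voxel is exactly one voxel thick, a
full-width slab of t voxels is t voxels thick away from its lateral faces,
and digital balls/rods of nominal diameter d (voxel inclusion
`‖q − c‖ ≤ d/2`) recover d within one voxel — the residual error is
digitization, not implementation. The distance ridge is a conservative
reduction: a ball is dropped only when a 26-neighbour's ball provably
contains it (`EDT(n) ≥ EDT(c) + ‖n − c‖`), so painting the surviving balls
yields the same map as painting all of them. The test suite checks the
whole pipeline voxel-for-voxel against an exhaustive brute-force sphere
oracle on dozens of random fixtures.

Thickness statistics use the plain mean and SD over foreground voxels (on a
voxel grid the volume-weighted arithmetic mean *is* the plain voxel mean),
plus a fixed-bin-width histogram (default one voxel = 8.48 μm) whose counts
sum to the foreground voxel count. Volume fraction is the exact count ratio
foreground/VOI. `section_counts` is desk arithmetic comparing physical
sectioning (`⌊depth/interval⌋` slides) with virtual sectioning
(`⌊depth/voxel⌋` one-voxel slices): a 1 mm block at a typical 4 μm
microtome interval yields 250 physical sections, while a single 8 μm-voxel
scan yields 125 virtual sections.

## Rendering

MIP keeps the brightest voxel along each ray. Axis-aligned projections are
exact per-column maxima; oblique directions first resample the volume onto
a rotated grid with trilinear interpolation, then project. Rotating MIPs
step the volume through uniform angles about a principal axis (frame 0 is
the plain MIP along the fixed perpendicular projection axis); played as a
loop they restore the depth cue a single MIP lacks. Cubic-spline
("bicubic") interpolation is reserved for 2D slice resampling, matching its
role in histology coregistration; volume rotation uses the cheaper, 
separable trilinear scheme.

Oblique reslicing samples `image[i, j] = V(origin + i·s·v + j·s·u)` with an
orthonormal in-plane basis (u = columns left→right, v = rows top→bottom).
When every sample coordinate falls on the voxel lattice (within 1e-9) the
values are gathered directly, so lattice-aligned planes are bit-identical
to stored slices; otherwise cubic-spline or trilinear interpolation is
used (the trilinear path reproduces linear gray fields exactly).
Out-of-volume samples are 0 — the calibrated gray value of air.

## Histology coregistration

The registration mirrors the manual bench protocol: at least three landmark
features from the histology slide are located in the volume; a total-least-
squares plane is fitted (normal = smallest principal direction); the
matching virtual section is extracted with bicubic interpolation, together
with candidate slices at offsets along the plane normal. Candidate ranking
by normalized cross-correlation against the (luminance-converted) histology
image is available, but slice choice is assisted, never silently automatic.
The fitted in-plane basis is made deterministic by aligning u with the
lattice axis most parallel to the plane (preference x, y, z), and
axis-aligned planes snap their origin to the lattice so stored slices are
reproduced bit-exactly.

The elastic step is a landmark-interpolating **thin-plate spline**:
`f(x) = a₀ + A·x + Σᵢ wᵢ·U(‖x − xᵢ‖)` with `U(r) = r² log r`, solved as the
standard dense bordered system per output dimension, with a regularization
weight λ (λ = 0 interpolates exactly; λ > 0 trades landmark fidelity for
smoothness). The affine/radial split is exposed deliberately: when all
pairs satisfy one affine map the radial weights vanish, a sharp internal
check on the solver. Image resampling uses the inverse-direction spline
(target → source) with bicubic sampling, per channel for colour slides.
Collinear landmarks degrade the spline system to an affine-only
least-squares fit, with a warning — off-line behaviour is then
underdetermined and no elastic claim is made. The registration report gives
per-landmark residuals (0 for the interpolating spline) and the
displacement magnitude field `‖f(x) − x‖`, i.e. how far the section had to
be unwrapped toward its undistorted state.

## Synthetic phantoms

The generators emulate exactly the structure the pipeline contracts depend
on — three gray-level populations plus additive Gaussian noise — and
nothing else. They do **not** model CT noise texture (rings, streaks, beam
hardening), partial-volume blur at material interfaces, stain variability,
or anatomically realistic tissue; passing tests demonstrate the
correctness of the algorithms under the stated gray-level model, not
robustness to scanner artifacts.

- **Calibration phantom**: wax cylinder (radius 0.35·min(nx, ny)) in air.
- **Geometric phantoms**: balls/slabs/rods of tissue gray in a wax block,
  each carrying its analytic thickness (ball d, slab t, rod d) and the
  exact counted volume fraction. Ball/rod voxel inclusion is
  `‖q − c‖ ≤ d/2`, whose axis span is exactly d voxels for odd d.
- **Foam phantoms**: Gaussian-blurred white noise (σ_vox =
  feature_scale_um / (4·voxel_size)) thresholded at the exact count
  quantile for the target volume fraction, so the achieved VF is known by
  construction, independent of any morphometry code. Periodic blur
  boundaries keep the field stationary.
- **Histology pairs**: a bicubic virtual section, mapped through a
  monotone eosin-like RGB palette, deformed by a known smooth displacement
  field and lightly noised. The default field is a 3 px-amplitude sinusoid
  with period equal to the image size — a low-order, smooth surrogate for
  sectioning distortion that a ~12-landmark interpolating spline is able
  to represent; ground truth carries the plane, the field and landmark
  pairs (a feature at x in the histology image sits at x + d(x) in the CT
  slice).

Default gray levels (air 0, wax 30419, tissue 40289 on the calibrated
16-bit scale) are representative stable values for calibrated FFPE scans;
a raw-scale mode (arbitrary float means) serves the preprocessing and
calibration tests. All generators are bit-reproducible under
(seed, parameters), and every ground-truth quantity is computed by direct
counting or analytic formula, never by the code under test.

## Numerical choices and degenerate inputs

- Quantization rounds half-up and clamps; windowing rejects non-finite
  input rather than propagating NaN.
- Histogram peak detection requires two modes; constant slices raise.
- Thickness of an empty foreground, empty VOI, non-positive bin widths,
  zero projection directions, non-orthonormal plane bases, out-of-bounds
  MPR points and already-calibrated inputs all raise `ValueError` with the
  offending quantity named; suspicious-but-legal inputs (threshold outside
  the data range, non-physical I_wax ≤ I_air) warn and proceed.
- Problem sizes in tests and the acceptance script (≤ 64³ volumes, ≤ 20³
  oracle fixtures, 50-fixture batteries) are chosen so the exhaustive
  oracles stay exact and the whole suite runs in well under a minute of
  compute per module; the algorithms themselves are size-agnostic.

## Known limitations

- The wax-referenced calibration corrects contrast relative to each scan's
  own material levels; it does not model detector nonlinearity or spatial
  gain variation within a scan.
- Local thickness is voxel-quantised; sub-voxel structures are reported at
  one voxel, and digitization error near curved boundaries is up to about
  one voxel (the documented tolerance).
- The thin-plate-spline warp is landmark-driven only; no intensity-based
  refinement is attempted, so accuracy between landmarks degrades for
  deformations rougher than the landmark spacing can represent.
- MIP/MPR rendering emits arrays and image files; interactive scene
  composition (hybrid 2D/3D fusion views) is left to external viewers.
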