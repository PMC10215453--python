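# Methods

## Measurement model

The quantity of interest is the change in Eustachian-tube (ET) lumen air
content produced by balloon dilation, measured on CT. The method assumes:

* pre- and post-dilation volumes of the same ear share a rigid anatomy, so
  a plane defined by three bony landmarks (medial pterygoid plate,
  contralateral pterygoid plate/hamulus, sphenoid spine) selects the same
  anatomical section in both states;
* the three landmarks are coplanar with the ET longitudinal axis, so the
  plane contains the lumen along its length;
* on 8-bit display images, air, soft tissue and bone occupy disjoint
  gray-value ranges that can be calibrated per scan from reference regions
  (nasopharyngeal air, surrounding tissue, petrous bone);
* the balloon's radiopaque marker bands and tip are identifiable, anchoring
  the ROI construction and the length measurements.

Air content is the count of air-classified pixels inside a ROI, summed over
the 25-image stack (center ± 12 images at the native 0.625 mm slice
spacing). Two air ranges are carried everywhere: *strict* (the range of
pure-air references, typically 0–16) and *partial* (widened to a ceiling of
31 to admit partial-volume pixels on the lumen wall). The partial count is
the headline measure; both are reported. The dilation metric is
`100 · (N_post − N_pre) / N_pre`, rounded half-up to integers in per-ear
tables; column summaries are the mean and the sample standard deviation
(n−1), computed on the rounded per-ear values and rounded only at display
time. The n−1 convention is required: the reference dataset's printed
dispersions are reproduced by the sample SD and not by the population SD
(asserted in the test suite).

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| display window | level 40 HU, width 400 HU | soft-tissue window for HU→8-bit conversion; keeps air ≈ 0 and cortical bone saturated at 255, preserving the three-range separability |
| slice step | 0.625 mm | native acquisition spacing; the stack steps at acquisition resolution |
| in-plane pixel | min(native row, col spacing) | isotropic reslicing avoids direction-dependent width bias |
| stack half-count | 12 | 25 images cover the lumen's out-of-plane extent with margin |
| small-box half-width | ceil(3.5 mm / pixel) | half the 7 mm inflated balloon diameter, so the box covers the balloon body at any resolution |
| long-box trim | 5 px per end | fixed construction rule |
| partial-volume ceiling | 31 (gray value) | upper edge of the partial-volume air tail on 8-bit images; configurable |
| calibration trim | 0.1 % per bin | min/max of raw reference samples is noise-fragile; bins holding <0.1 % of a sample are discarded before taking [min, max]; clean samples are unaffected |
| landmark triangle area | > 1 mm² | smaller triangles are treated as annotation errors at CT resolution |

## Coordinate and orientation conventions

Voxel indices are 0-based voxel centers in (slice, row, column) order;
the axial slice index grows cranial→caudal. Landmark files must declare
`"coordinate_convention": "zyx0"` and are refused otherwise. The in-plane
vertical of the reslicing frame follows the projected torus→balloon-tip
axis when those points are annotated (placing the nasopharynx at the top of
the image, the orientation the ROI rules assume), otherwise the longest
landmark-triangle edge; the plane normal's sign is fixed cranial-positive,
which makes the frame invariant under landmark permutation. Resliced pixel
values are kept continuous (float) internally and quantized half-up only
when histogrammed or exported, avoiding a second quantization on top of the
acquisition's.

## The synthetic phantom

The phantom emulates the structures the pipeline interacts with, not a
head: a tissue background; an oblique straight ET lumen of 25 mm whose
elliptical cross-section tapers linearly between three width knots
(nasopharyngeal opening 3.5 mm, mid-balloon level 3.0 mm, isthmus 2.0 mm,
then constant through the bony portion); a nasopharyngeal air funnel beyond
the torus; a petrous-bone-like block past the posterior lumen end; and, in
the during-dilation state, the balloon with two marker bands at the ends of
its full-diameter cylindrical segment. The cartilaginous/bony junction sits
at 0.6 of the lumen length and coincides with the widest balloon level, so
the torus→widest and widest→tip distances equal the cartilaginous (15 mm)
and bony (10 mm) lengths. Default grid: 52 × 160 × 64 voxels at
0.625 × 0.3125 × 0.3125 mm.

Default widths were chosen so that **every measured structure is resolved
at scan resolution** (≥ ~3 voxels across at the 0.625 mm slice spacing):
threshold counting is blind to sub-resolution channels, and the reference
experiment's images show visibly measurable lumens at all three levels
before dilation (all printed pre-dilation widths are nonzero). Intensities
(air 5, tissue 64, bone 235, balloon 120, marker 245) sit inside the
calibrated reference ranges so default densitometry classifies the phantom
correctly; the balloon-wall value has no in-vivo reference statistics and
is a free parameter between tissue and bone.

Dilation multiplies the mid-level width by `dilation_factor`; the end
levels receive a fixed share of the mid-level excess (11 % at the
nasopharyngeal opening, 53 % at the isthmus, scaled from the reference
dataset's mean per-level width increases), concentrating dilation at
mid-lumen the way the balloon's cylindrical segment does. A closed-form
integral of the width profile gives the true air-volume increase of any
axial region; inverting it (Brent's method) yields the factor that produces
a target increase, either over the whole lumen (compare with the longest
box) or over the marker-to-marker span (compare with the small box — the
two regions differ because dilation is concentrated).

Partial volume is simulated by supersampled rendering (default 3× per axis)
followed by block averaging, producing the intermediate-value tail above
the pure-air range; zero-mean Gaussian noise (default SD 5 gray levels) is
added afterwards and the result clamped to [0, 255]. All randomness comes
from the mandatory seed; volumes are bit-reproducible.

**What the phantom does not emulate** — and hence what passing tests do not
show about real scans: anatomical shape variation and landmark annotation
error (phantom landmarks are exact, so reslicing-plane mismatch between
states is absent); curved lumen centerlines; tissue elasticity and recoil;
scanner noise spectra, beam hardening and metal artifacts; contrast medium.
Recovery results on the phantom bound the method's geometric and
densitometric errors, not its sensitivity to annotation quality.

## Ground-truth comparison and the mask-space oracle

True air counts are voxel-center mask cardinalities. The pipeline's counts
live in resliced space, so the independent check reslices the binary
ground-truth mask with the same trilinear scheme and thresholds it at the
classification-equivalent level `θ = (tissue − (bound + 0.5)) / (tissue −
air)`: in a two-material region the intensity is affine in the air
fraction, interpolation commutes with affine maps, and the θ-thresholded
mask count equals the intensity-route count exactly for noise-free,
partial-volume-free phantoms (this identity is asserted in the tests). With
noise and partial volume the routes diverge by design and agree only
approximately.

Whole-lumen percent increases are compared against the longest box (the one
ROI spanning the whole lumen); the small box is compared against the
cylinder-span ground truth. Threshold counting erodes a tube by a fixed
boundary layer, which slightly inflates measured percent increases at large
dilations (the pre-state loses relatively more boundary than the post
state); the recovery experiments in the test suite and acceptance script
quantify this at the default conditions.

## Numerical choices

* Rounding is half-up throughout (`floor(x + 0.5)`), matching integer table
  entries; Python/NumPy banker's rounding is never used on reported values.
* All gray-range bounds are inclusive on both ends.
* Degenerate inputs raise early with specific messages: `"mixed series"`,
  `"incomplete geometry"`, `"degenerate plane"`, `"rotate first"`,
  `"no room to extend"`, `"undefined baseline"`, `"reference regions not
  separable"`; pipeline failures carry the stage name and ear id.
* Out-of-volume reslice samples read 0; analysis ROIs are constructed
  inside the covered region, so the zeros never enter a measurement.
* The longest-box exclusion test rejects any overlap between the candidate
  box and an exclusion mask (checked row by row as the box grows, including
  the starting box).
* The total lumen length (torus→tip) is an independent measurement, not the
  sum of the two part distances; the reference per-ear data themselves are
  inconsistent with strict additivity, so no additivity invariant is
  enforced.

## Problem sizes

The test suite and acceptance script run phantoms at the default
52 × 160 × 64 grid. The stochastic recovery experiment uses 10 phantom
pairs with configured whole-lumen increases evenly spanning 20–100 %, and
the five-ear experiment tunes the cylinder-span increase to the reference
small-ROI column; one additional noise-free phantom verifies exactness.
Randomized oracle checks use 100–200 draws per rule.

## Known limitations

* Landmarks and balloon anchor points are inputs (manual annotation or
  phantom ground truth); there is no automatic detection on real scans.
* Enhanced multi-frame DICOM, gantry tilt and non-axial acquisitions are
  unsupported.
* Widths are horizontal air runs on rotated images: a strongly curved or
  incompletely verticalized lumen would bias them.
* The 8-bit pathway discards HU standardization; HU analysis is supported
  only upstream via windowing, and counts are not comparable across
  different window settings.
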