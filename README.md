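# etquant

CT-based quantification of Eustachian-tube (ET) balloon dilation.

Balloon dilation of the Eustachian tube (BDET) is an endoscopic treatment
for ET dysfunction: a catheter balloon (16 mm long, 7 mm inflated / 3 mm
deflated diameter) is inflated inside the cartilaginous ET. Objective
outcome measures are scarce — the ET is a narrow, normally closed, obliquely
oriented canal that is hard to see on axial CT. `etquant` implements an
image-analysis pipeline that quantifies the structural effect of dilation
from pre- and post-procedure CT volumes:

1. **Oblique reslicing** — a viewing plane through the ET longitudinal axis
   is anchored on three bony landmarks (medial pterygoid plate, the
   contralateral pterygoid plate/hamulus, and the sphenoid spine), which
   makes pre- and post-dilation stacks geometrically comparable. The center
   image plus 12 images toward cranial and caudal (25 in total) are
   extracted by trilinear interpolation and rotated so the lumen runs
   vertically, nasopharynx up.
2. **Balloon-guided ROIs** — three nested vertical boxes: *small* (between
   the balloon's radiopaque marker bands, covering the full-diameter
   cylindrical segment), *longest* (extended equally toward the torus tip
   and the balloon tip without entering bone or the nasopharyngeal air
   column), and *long* (the longest box trimmed by exactly 5 px per end).
3. **Densitometry** — air/tissue/bone gray-value ranges are calibrated from
   reference regions (on 8-bit images typically air 0–16, tissue 42–88,
   bone 214–255, with the air range widened to 0–31 for partial-volume
   pixels on the lumen wall). The dilation measure is the percent increase
   in air-classified pixels inside each ROI summed over the 25 images:
   `100 · (N_post − N_pre) / N_pre`.
4. **Morphometry** — lumen widths at the nasopharyngeal opening, the
   mid-balloon level and the isthmus (maximal air run along the level's
   image row), and straight-line distances torus→tip, torus→widest balloon
   level, widest→tip, in px and mm.

Because no scan data accompany the reference cadaver experiment, the
package ships a **parametric synthetic head phantom** (`etquant.phantom`)
with a tapering oblique ET lumen, nasopharyngeal air funnel, petrous-bone
block, inflatable balloon with marker bands, partial-volume rendering and
Gaussian noise — with exact ground truth (masks, counts, widths, landmark
coordinates), so every stage of the pipeline is testable end to end.

## Worked example

```python
from etquant import PhantomSpec, PipelineConfig, analyze_ear

spec = PhantomSpec(seed=3)           # default: mid-lumen dilation factor 1.72
a = analyze_ear("ear1", spec, PipelineConfig(ears={}))
r = a.record
print(r.density_ranges)
print(r.percent_increase["partial"])
print(r.widths_pre_px, r.widths_post_px)
print(r.distances_px)
```

prints (abridged):

```
DensityRanges(air_strict=(0, 18), air_partial=(0, 31), tissue=(48, 84), bone=(218, 249))
{'small': 167.3, 'longest': 101.5, 'long': 109.3}
(10.0, 9.0, 6.0) (12.0, 16.0, 8.0)
(80.0, 48.0, 32.0)
```

Reading this: the density calibration recovered ranges close to the 8-bit
reference values; air content in the longest box roughly doubled (+101.5%
measured vs. a true whole-lumen increase of +95.1% for this phantom); the
small box, which covers only the strongly dilated balloon segment, shows a
larger regional increase (+167%). The mid-level width grew from 9 to 16 px
(the configured factor is 1.72), and the 80 px lumen splits into 48 px
(torus→widest, the cartilaginous part) and 32 px (widest→tip, the bony
part) — at 0.3125 mm/px: 25 mm, 15 mm and 10 mm.

The same pipeline is scriptable from the shell:

```sh
etquant phantom --seed 3 --out scratch/ear1            # DICOM series + ground truth
etquant quantify --config run.yaml --out scratch/run   # report.json / report.csv + QC overlays
etquant reproduce-tables                               # summary stats of the built-in
                                                       # five-ear reference dataset
```

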