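# Methods

## Dose model

All dose computation reduces to three closed forms, applied per axial slice:

* **Water-equivalent diameter.** `D_w = 2·√[((CT̄/1000)+1)·A/π]`, where CT̄
  is the mean CT number (HU) and A the area (cm²) of the body ROI. The ROI
  is the automated body contour: union of all non-background tissue labels,
  hole-filled (so internal air such as the trachea contributes to the mean,
  matching outer-body contouring practice) and reduced to the largest
  connected component (dropping couch or clothing fragments). A uniform
  water disc therefore returns its geometric diameter exactly, and an
  all-air ROI returns 0.
* **Corrected effective diameter.** One central chord per body axis (not an
  average over parallel rays): the lateral (LAT) chord runs through the mask
  centroid along the principal axis, the anterior–posterior (AP) chord along
  the orthogonal minor axis. Each chord is split into per-tissue segment
  runs; a run of class *s* and length *l* contributes `ρe(s)·l` with
  relative electron densities lung 0.3, soft tissue 1.0, bone 1.2. Then
  `D_eff^corr = √(AP^corr · LAT^corr)`.
* **Conversion factor and SSDE.** `f(D) = 3.704369·exp(−0.03671937·D)`
  (32-cm PMMA body phantom, 120 kVp), applied identically to `D_w` and
  `D_eff^corr`; `SSDE = f·CTDIvol`. f is strictly decreasing and exceeds 1
  for all diameters below ln(3.704369)/0.03671937 ≈ 35.7 cm. The CTDIvol
  reference phantom is metadata only; no other kVp coefficient family is
  provided. Internally everything is kept at full floating precision;
  rounding to one decimal happens only in the CSV reporting layer.

## Geometry extraction

The class-map raster uses 0-based `(row, col)` indices with row 0 anterior;
pixel spacing may be anisotropic and is honoured per direction — centroid,
principal axes and chord lengths are all computed in physical millimetres.
LAT is identified with the major axis and AP with the minor axis (thoraces
are wider than deep); when the axis ratio is within 1% of unity the
directions tie-break to the image column/row axes. Because the axes follow
the anatomy, rotating a slice by 90° leaves the (AP, LAT) measurement pair
unchanged while the underlying chords swap image orientation.

Chords are sampled at 0.5-pixel steps with nearest-neighbour label lookup,
bounding each run-length error at about half a pixel; consecutive equal
labels merge into runs, and the run sum equals the within-body chord length
to within one pixel. Background samples inside the body (internal air) are
scored as lung, the closest attenuation class available — the segmenter has
no dedicated air class. Alternatives such as ellipse-fit or bounding-box
axes were considered; centroid chords were chosen as the closest analogue
of a manual caliper measurement and are what the analytic phantom oracle
models.

## Segmentation

Two segmenters share one contract (a per-pixel map over background / lung /
other tissue / bone):

* **Threshold reference.** Body = HU > −400 (hole-filled, largest
  component); within the body, lung < −300 HU, bone > +150 HU, tissue
  otherwise. Thresholds are config-exposed; the defaults bracket both the
  phantom HU assignments (by ≥ 100 HU) and standard tissue ranges, so on
  noiseless phantoms the output equals the generator's ground truth pixel
  for pixel.
* **U-Net.** Encoder of five residual convolution stages (two 3×3
  convolutions plus an identity/1×1-projected shortcut; 2×2 max-pool stride
  2 between stages; widths 8·{1,2,4,8,8} by default), a symmetric 2×
  nearest-neighbour up-sampling path with skip concatenations, and a final
  1×1 convolution + softmax. Implemented in NumPy (im2col convolutions,
  hand-written backward passes, Adam), which makes training bit-for-bit
  reproducible for a fixed seed — the seed drives the holdout split, weight
  initialisation and shuffling. Inputs are normalised by clipping HU to
  [−1000, +1000] and scaling to [0, 1]: a fixed physical window, independent
  of the data. Loss is unweighted per-pixel multi-class cross entropy.
  Desk-scale defaults: 128×128 inputs, 30 epochs, batch 4, learning rate
  1e-3, 20% holdout, no pre-trained encoder (a config hook allows swapping
  widths/depth). Optimiser and learning-rate choices are this package's
  own; checkpoints are single `.npz` files carrying weights plus config.

Evaluation uses the per-class Jaccard index (IoU) and its four-class mean.
A class absent from both prediction and truth scores 1.0, so slices that
genuinely lack a tissue (e.g. no bone on a phantom) do not zero the mean;
reports note this convention.

## Synthetic phantoms

The generator emulates a non-contrast axial thoracic slice from exact
primitives in cm coordinates: an elliptical soft-tissue body (0 HU) on air
(−1000 HU), two lung ellipses (−700 HU) mirrored about the AP axis and
centred on the LAT chord, and a posterior vertebral bone disc (+300 HU) on
the AP chord — so both measurement chords cross non-tissue classes, as in a
real thorax. Optional Gaussian HU noise (seeded) models quantum mottle.

Ground truth is computed from the geometry, never the raster: region areas
(πab) give the area-weighted mean HU and hence a closed-form `D_w`; exact
chord–region intersections give the corrected dimensions (tangential
configurations are rejected as ambiguous). Rasterisation error is therefore
measurable — body-pixel counts converge to the analytic area within 2% at
1 mm pixels for adult-size bodies, and the threshold pipeline recovers
`D_w` within 1% and `D_eff^corr` within 2%.

Cohorts are sampled scale-free (aspect ratio 0.60–0.72, relative lung and
bone sizes) and each phantom is rescaled so its analytic `D_eff^corr` lands
uniformly in 15.9–26.7 cm — the adult thoracic span the conversion-factor
table covers — with CTDIvol uniform in 4.2–10.5 mGy. What the phantoms do
**not** model: anatomical texture, ribs and sternum, contrast enhancement,
tube-current modulation or reconstruction effects, truncated fields of
view, and paediatric sizes. Passing tests on phantoms therefore validate
the geometry→dose chain and the learning machinery, not clinical
segmentation accuracy on patient images.

## Study conditions used by the test suite

The analytic-recovery check runs 100 noiseless phantoms at 1 mm pixels on a
480² raster (wide enough for the largest sampled bodies). The training
check uses 50 phantoms at 128² (3.8 mm pixels, σ = 20 HU noise), 30 epochs,
20% holdout, fixed seed, and requires holdout mean IoU ≥ 0.90 plus
end-to-end diameter recovery within 5% on fresh phantoms — the network's
boundary error at coarse pixels dominates that budget. Noise robustness of
the threshold segmenter is checked at σ = 20 HU (per-class IoU ≥ 0.95).

## Numerical choices and degenerate inputs

* Chord endpoints are located by marching from the centroid at 0.25-pixel
  steps; axis ties resolve to image axes as above.
* `D_w` demands mean CT ≥ −1000 HU and area ≥ 0; diameters and run lengths
  are validated non-negative; `f ≤ 0` and unknown tissue classes are
  errors. An empty segmentation (no non-background pixels) raises rather
  than returning zeros.
* Every `DoseResult` asserts `SSDE = f × CTDIvol` to 1e-9; slices without
  CTDIvol carry diameters and factors but no SSDE (reported as empty cells,
  with a warning), and a CLI `--ctdi-vol` override takes precedence over
  the DICOM tag or sidecar.
* Per-slice failures in batch computation are logged and skipped; the
  report records the surviving slices.

## Known limitations

Single-slice analysis only (no whole-scan D_w profile); no truncated-FOV
compensation; the bone class means vertebral body only; agreement numbers
obtained on synthetic cohorts characterise the pipeline's internal
consistency, not patient-population values.
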