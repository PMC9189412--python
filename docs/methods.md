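# Methods

## The segmentation model and its assumptions

The labeling pipeline treats a single-spike photo as a two-layer scene:
a near-neutral board and a strongly colored spike. Two color-space
properties carry all the signal:

1. **Spike vs. board.** The board is close to gray, so its HSV saturation
   S = (max−min)/max is near zero, while glumes, rachis and awns are
   strongly colored. Otsu's threshold on the S channel therefore separates
   spike from board without tuning. The spike is taken to be the class
   with the higher mean saturation; the largest 8-connected component is
   kept and enclosed holes are filled, so the mask is always a single
   clean silhouette.
2. **Spikelet vs. boundary.** Within the spike, spikelet bodies (glumes)
   have *lower* blue-chroma than the tissue between spikelets. On the Cb
   relief each body is a catchment basin, so a watershed flood segments
   the spike into candidate spikelet regions. Cb is computed with the
   full-range ITU-R BT.601 transform Cb = 128 − 0.168736·R − 0.331264·G +
   0.5·B; only relative Cb contrast matters downstream, so the choice of
   full-range versus studio-swing coefficients does not affect the
   segmentation.

The method assumes exactly one spike per image, near-vertical, on a
uniform contrasting board, photographed at the grain filling stage when
glume/boundary contrast is high. It does not model occlusion by awns,
overlapping spikes, or senescent (low-chroma) tissue.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| canonical frame | 256 × 1021 | px | fixed working resolution; makes area thresholds scale-free |
| ROI pad | 20 | px | margin added around the coarse spike box before resampling |
| h_min | 3 | gray levels | minima-depth suppression; basins shallower than this merge |
| area_min, area_max | 1000, 5000 | px | accepted basin pixel count (inclusive) |
| ratio_min, ratio_max | 1.0, 2.5 | — | accepted MER long/short side ratio (inclusive) |
| bilateral (win, σ_range, σ_spatial) | 9 px, 50 levels, 5 px | — | edge-preserving smoothing of the Cb image |
| confidence cut | 0.75 | — | strict lower bound when relabeling with a detector |
| NMS IoU | 0.6 | — | suppression threshold among detections |
| match IoU | 0.5 | — | TP criterion for evaluation |

Notes on the less obvious choices:

* **Resampling.** The crop is resized to exactly 256 × 1021 with Pillow's
  bicubic kernel regardless of input size. A fixed output size was chosen
  over a fixed scale factor because the area filter bounds (1,000–5,000
  px) are only meaningful at one scale.
* **"Local minimum threshold" = h-minima.** Minima suppression is a
  grayscale reconstruction-by-erosion of (surface + h) above the surface.
  The transform removes every regional minimum of dynamic depth < h and
  shallows the rest by up to h; it is *not* idempotent (each application
  can raise deep floors by h), which is why the tests assert the bound
  `f ≤ H(f) ≤ f + h` and the depth rule rather than idempotence.
* **Watershed domain.** Background pixels are set above the gray ceiling
  before flooding, and the flood is masked to the spike, so no basin can
  leak onto the board. Ridge pixels (watershed lines) stay unlabeled;
  region areas are basin pixel counts, not box areas.
* **MER.** Implemented as the axis-aligned tight bounding rectangle of a
  basin, because labels are stored as upper-left corner plus width/height.
  Both filter intervals are inclusive at their bounds.
* **Filter area = region pixels.** The 1,000–5,000 test uses the basin's
  pixel count rather than its rectangle area; the rectangle only feeds the
  side-ratio test. The two disagree most for diagonal or concave regions,
  where the pixel count is the better proxy for spikelet size.
* **Box ordering.** Output boxes are sorted top-to-bottom then
  left-to-right so repeated runs produce byte-identical XML.
* **Otsu.** Implemented over the 256-bin histogram with the cut defined
  by classes ≤ t and > t; ties break toward the smallest t. The tests
  check it against an exhaustive 256-candidate search.
* **VOC dialect.** On disk, boxes are 1-based inclusive
  (xmin = x+1, ymin = y+1, xmax = x+w, ymax = y+h); the conversion lives
  only in the two XML functions, so there is exactly one place an
  off-by-one could exist.
* **Split rule.** Per wheat line, a seeded uniform permutation assigns
  floor(0.8·n) images to training; with 100 images per line this is the
  80/20 split used to train the original detector.
* **R² definition.** The denominator is the total sum of squares of the
  *manual* counts, so R² can go negative for a predictor worse than the
  manual mean. This literal form is kept deliberately.
* **Degenerate evaluation inputs.** Precision/recall with zero
  denominators return 0 with a flag rather than raising, so one empty
  image cannot abort a batch; AP with zero ground truths is an error
  because the sweep is undefined.
* **AP integration.** All-point interpolation: the precision monotone
  envelope integrated over recall, with score ties broken by input order.
  Whether an 11-point variant was used originally is unknowable from the
  published description; the all-point form is the current convention and
  is what the brute-force oracle in the tests anchors.

## The synthetic generator

`spikelet.synthgen` renders the scene the pipeline assumes: a vertical
rachis strip with `n_pairs` pairs of elliptical spikelets (semi-axes
28 × 18 px at canonical scale, vertical pitch = ellipse height + 39 px
gap), an apical spikelet on top, optionally a smaller sterile basal
spikelet (flagged, excluded from countable ground truth, and deliberately
below the area filter), and thin awn strokes. Defaults give
2·9 + 1 = 19 countable spikelets, the typical count for the wheat lines
the method was designed around; synthetic "manual" counts in the count
study are drawn from 17–23.

Color is specified per wheat-line preset (four palettes differing in hue
and brightness, one deliberately more uniform). Every palette must
satisfy, and is checked for, the ordering

    Cb(body) < Cb(rachis dip) < Cb(rachis ridge),
    ridge − dip ≥ h_min,   ridge − body ≥ h_min + 2,

so each body is a suppressible-noise-proof basin. Two rendering choices
matter for fidelity of the test conditions:

* **Inter-row rachis dips.** Rachis segments *between* spikelet rows get
  a shallow Cb dip, so they form their own small basins (a few hundred
  px) that the area filter removes. Without them, those segments would be
  flooded from adjacent spikelet basins and stretch the spikelet
  rectangles. Real spikes achieve the same effect by having almost no
  exposed rachis between spikelets.
* **Detached awns.** Awn strokes start a few pixels off the spikelet
  body, so they are dropped by the largest-component rule instead of
  elongating basins. This mirrors the observation that awn regions are
  eliminated by the MER filters, but it means the generator does not
  model awn *occlusion* of spikelets — the main real-world failure mode —
  so passing recovery tests says nothing about heavily awned overlap.

Additive Gaussian pixel noise (σ in gray levels) is the only degradation
model; illumination gradients, shadows, JPEG artifacts, defocus and
perspective are not emulated. All randomness flows from the single seed
in the parameter set; the same seed reproduces images bit-for-bit.
The raw-scale render is the same scene at an integer scale factor
(default 3) with a board margin; ground-truth boxes are defined in the
canonical frame.

## Problem sizes

The test suite and the reproduction script run the full pipeline on 20
synthetic spikes per noise condition (380 spikelets each at σ = 0 and
σ = 5), 8 spikes for the AP computation, a 680-image synthetic count
study, 100 random images for the Otsu oracle comparison, and 50 random
instances for the AP oracle comparison. These sizes make every stage's
behavior measurable while keeping a full run on one CPU within a few
minutes.

## Known limitations

* The watershed labeler is intentionally imperfect on hard cases —
  merged basins under very low boundary contrast, missed spikelets
  removed by the filters — as in the original semi-automatic workflow,
  where a detector retrained on the rough labels and two manual
  correction passes close the gap.
* No sterile-spikelet classifier: sterile basal spikelets are represented
  only as flagged ground truth and manual-correction edits.
* The published headline accuracies of the full system (per-line RMSE
  0.54–0.77, rRMSE 3.34–4.94 %, R² 0.67–0.84, AP@0.5IOU 0.9582) belong to
  a trained Faster RCNN evaluated on 680 real test images that were never
  deposited; they are not reproducible here and are not targets of this
  package's checks. The synthetic count study reports the same statistics
  under a stated ±1 error model instead.
* The generator's realism limits are listed above; results on synthetic
  scenes bound what the pipeline can do under its stated assumptions, not
  its accuracy on arbitrary field photos.
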