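# spikelet

Semi-automatic labeling and counting of wheat spikelets in single-spike
color images.

The number of spikelets per spike is a yield-related phenotypic trait in
wheat (*Triticum aestivum* L.) breeding, and counting them by hand is slow.
When a detached spike is photographed on a uniform board at the grain
filling stage, the spikelets can be segmented without any training data by
exploiting two color-space facts: the spike is far more saturated (HSV S)
than the board, and the glumes of spikelet bodies have lower blue-chroma
(YCbCr Cb) values than the pixels on the boundaries between spikelets.
This package implements that unsupervised labeling pipeline, the dataset
machinery needed to turn its output into detector training data, and the
standard evaluation protocols for the resulting detections and counts:

1. **Preprocess** — locate the spike (Otsu on the saturation channel,
   largest connected component), crop the region of interest with a pad,
   and resample bicubically to a fixed 256 × 1,021 canonical frame so all
   later area thresholds live at one scale.
2. **Spike mask** — binarize the S channel at the Otsu threshold
   (spike = high-saturation class), keep the largest 8-connected
   component, fill holes.
3. **Autolabel** — compute the Cb channel, enhance contrast with a
   bilateral filter, zero the background, suppress regional minima of
   dynamic depth < 3 (h-minima transform), flood a marker-controlled
   watershed inside the mask, and keep each basin's minimum enclosed
   rectangle (MER) iff the basin area is in [1,000, 5,000] px and the MER
   long/short side ratio is in [1, 2.5]. Survivors are the spikelet labels,
   written as Pascal-VOC XML.
4. **Dataset ops** — seeded per-line 80/20 train/validation splits, strict
   > 0.75 confidence relabeling by any detector behind a small interface,
   logged manual-correction edits, per-line count tables.
5. **Evaluation** — detection: greedy IoU ≥ 0.5 matching,
   recall = TP/(TP+FN), precision = TP/(TP+FP), AP@0.5IOU by all-point
   precision-envelope integration, NMS at IoU 0.6; counting: for manual
   counts *tᵢ* and automatic counts *dᵢ*,
   RMSE = √(Σ(tᵢ−dᵢ)²/n), rRMSE = √(Σ((tᵢ−dᵢ)/tᵢ)²/n),
   R² = 1 − Σ(tᵢ−dᵢ)²/Σ(tᵢ−t̄)², plus the signed-error histogram.
6. **Synthetic spikes** — a generator that renders a near-vertical rachis
   with paired elliptical spikelets (plus optional apical/sterile
   spikelets and thin awns) with exact ground-truth boxes and masks, so
   every stage is testable without field images or a trained network.

Training of the deep detector itself (a Faster RCNN in the original
system) is out of scope; its published training constants are recorded in
`src/spikelet/_dcnn_reference.py` and any detector can be plugged in via
`spikelet.detectors.DetectorInterface`.

## Worked example

```python
from spikelet import (SyntheticSpikeParams, generate_spike, autolabel_image,
                      average_precision, Detection)
from spikelet.detecteval import iou

sample = generate_spike(SyntheticSpikeParams(seed=7, noise_sigma=5.0))
ann = autolabel_image(sample.canonical)
print(f"ground-truth spikelets: {len(sample.countable_boxes)}")
print(f"watershed labels:       {len(ann.boxes)}")
recovered = sum(any(iou(g, b) >= 0.5 for b in ann.boxes)
                for g in sample.countable_boxes)
print(f"recovered at IoU>=0.5:  {recovered}")
dets = [[Detection(box=b, score=1.0) for b in ann.boxes]]
print(f"AP@0.5IOU:              {average_precision(dets, [sample.countable_boxes]).ap:.4f}")
```

prints

```
ground-truth spikelets: 19
watershed labels:       19
recovered at IoU>=0.5:  19
AP@0.5IOU:              1.0000
```

i.e. on a noisy synthetic spike with 9 spikelet pairs plus the apical
spikelet, the unsupervised pipeline finds all 19 spikelets, each box
overlapping its ground truth at IoU ≥ 0.5, giving a perfect
precision-recall sweep.

The same stages are available from the shell:

```sh
spikelet synth --n 20 --seed 7 --out data/        # images + masks + XML truth
spikelet autolabel --in data/ --out labels/       # watershed VOC labels
spikelet dataset split --ann labels/ --frac 0.8 --seed 1 --out split.json
spikelet eval-detect --gt data/ --pred preds.csv  # precision/recall/AP
spikelet eval-count --counts counts.csv           # RMSE / rRMSE / R²
```

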