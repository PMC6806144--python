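# lycheevision

Monocular-vision detection of round fruits (lychees) in orchard-style RGB
imagery. The pipeline:

1. **Illumination compensation** — CLAHE applied to the HSV value channel
   only (hue/saturation preserved), with a grid search selecting the tile
   count and clip limit by mean segmentation overlap against reference
   masks (`lycheevision.preprocess`).
2. **Foreground segmentation** — relative red–blue chromatic map
   `(R − B)/B`, Otsu thresholding on the 256-bin quantized map, and
   morphological cleanup into connected regions
   (`lycheevision.segmentation`).
3. **Region status classification** — each region is labeled isolated,
   occluded, or overlapped from the relation between its Hough circles
   and its equivalent-area circle (`lycheevision.status`).
4. **Cluster splitting** — overlapped regions are split into individual
   fruit circles by scanning the centroid-to-boundary distance per degree,
   finding minimum–maximum–minimum extremum triplets, and fitting the
   circumcircle through each triplet (`lycheevision.polar_split`).
5. **False-positive filtering** — candidate circles pass a pixel-area
   gate (800–1700 px) and a histogram-intersection-kernel SVM over 59-bin
   uniform-LBP texture histograms (`lycheevision.texture_filter`).
6. **Evaluation** — greedy one-to-one circle-IoU matching and
   precision/recall/F1 reporting (`lycheevision.metrics`).

A seeded synthetic-scene generator (`lycheevision.synthetic`) renders
textured fruit discs — isolated, foliage-occluded, or fused in compact
clusters — under three illumination regimes with exact ground truth, so
every stage is testable without any external dataset.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: metric
arithmetic against published evaluation-table rows, geometric oracles
(equivalent-area radius, polar distances, circumcircle vs least-squares
fit), an exhaustive-scan Otsu oracle, parameter-recovery rates for the
status classifier (≥ 90 % over 50 seeded regions) and the cluster
splitter (≥ 85 % over 100 seeded clusters), LBP/HIK structural
properties, and directional ablations (CLAHE never decreases pooled
recall; the texture filter never decreases pooled precision).

## CLI

```sh
lychee synth --out-dir scenes/ --n-scenes 5 --seed 3        # scene PNG + truth JSON
lychee preprocess --in img.png --out out.png --blocks 10 --clip 0.015
lychee segment --in img.png --out-mask mask.png --erode 3 --dilate 3
lychee classify --mask mask.png --out regions.json
lychee split --mask mask.png --out circles.json --smooth 9 --prominence 2
lychee train-svm --pos pos_dir/ --neg neg_dir/ --out model.json
lychee detect --in img.png --out dets.json [--config cfg.yaml] [--model model.json]
lychee filter --model model.json --detections dets.json --img img.png --out kept.json
lychee evaluate --scene-dir scenes/ [--model model.json] --iou 0.4
lychee evaluate --detections dets.json --truth truth.json
```

Pipeline defaults live in `lycheevision.config.PipelineConfig` and
round-trip through YAML (`--config`).

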