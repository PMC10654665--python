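# cephalo

Two-stage detection of 23 cephalometric landmarks from facial-profile images,
with a full evaluation stack and a synthetic-data generator.

* **Stage 1 — heatmap regression.** A high-resolution multi-branch
  convolutional backbone (parallel streams at 1/4 .. 1/32 resolution with
  cross-branch exchange units) regresses one Gaussian heatmap per landmark.
  Heatmaps are decoded by argmax with a quarter-pixel offset toward the
  larger axis neighbour.
* **Stage 2 — coordinate refinement.** Two independent three-layer
  perceptrons (23 → 500 → 23), one per axis, refine the decoded coordinates
  using inter-landmark structure.  They are trained in alternation with the
  backbone: each *cycle* is one backbone epoch followed by 100 refiner
  epochs, with refiner parameters persisting across cycles.
* **Evaluation.** Radial errors (MRE, SD, per-axis Δx/Δy), successful
  detection rate at 2.0/2.5/3.0/4.0 mm, eight clinical measures
  (ANB/SNB/SNA/ODI/APDI/FHI/FMA/MW) with three-way face-type classification,
  and the successful classification rate (SCR) over image sets.
* **Synthetic data.** A geometric shape model (template + low-rank
  deformation modes + jitter) in a 1200×1200 px space at 0.35 mm/px,
  rendered toy profile images with a distinct local texture per landmark,
  and structured stage-1 noise (low-rank correlated + independent), standing
  in for the private clinical dataset.

The neural networks are implemented in NumPy with a small reverse-mode
autodiff tape (`cephalo.autodiff` / `cephalo.nn`) — no GPU framework is
required.  Default network sizes are desk-scale (base width 8, one
multi-resolution block per stage) so everything trains in minutes on one
CPU; the full-scale widths/depths (18/36/72/144 channels, blocks 1/4/3) are
available via `BackboneConfig.full_scale()`.

## Command line

```bash
cephalo generate --n 50 --seed 1 --side 64 --out data/      # synthetic fixture dataset
cephalo train --data data/ --cycles 20 --out run/           # alternating cycle training
cephalo predict --data data/ --model run/ --out pred.csv    # stage-1 + refined landmarks
cephalo evaluate --pred pred.csv --gt data/annotations.csv --role refined --out-prefix eval
cephalo measure  --pred pred.csv --gt data/annotations.csv --out-prefix meas
```

Datasets are PNG images plus annotations in two interchangeable formats:
the imglab/Dlib XML "parts" dialect and a landmark CSV
(`image_id, index, name, x_px, y_px, role`).  Coordinates are real-valued
pixels, pixel-center model, origin top-left, y down.

## Layout

```
src/cephalo/
  core.py         landmark/scheme/space types, angles, distances, crops
  heatmaps.py     Gaussian encode + sub-pixel argmax decode + L2 loss
  autodiff.py     reverse-mode tape on NumPy arrays
  nn.py           Conv/BN/Linear modules and Adam
  backbone.py     high-resolution multi-branch heatmap network
  refiner.py      per-axis 23-500-23 MLPs
  training.py     alternating cycle schedule + ablation evaluation
  metrics.py      MRE / SD / Δx / Δy / SDR reporting
  measures.py     eight clinical measures, classification, SCR
  synthetic.py    shape model, renderer, structured noise
  annotations.py  imglab XML and landmark CSV I/O
  datasets.py     on-disk dataset layout
  cli.py          command-line interface
```
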