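# foramcurve

How many manually segmented specimens does a 3D segmentation network need?

`foramcurve` is a desk-scale, fully self-contained pipeline for studying
training-set sufficiency in volumetric image segmentation.  Synthetic
chambered-shell phantoms (trochospiral multi-chamber geometries with a
bright calcite-like wall, a partially sediment-filled cavity and imaging
noise) stand in for micro-CT scans of planktonic foraminifera.  The
pipeline covers:

- **`stackio`** — paired 16-bit grey / 8-bit label multipage-TIFF I/O with a
  fixed label convention (0 background, 1 external wall, 2 internal cavity)
  and plain-text sidecar metadata.
- **`phantom`** — the synthetic-specimen generator and population sampler
  (train/validation/test splits, per-specimen parameter variation,
  a configurable low-contrast sediment-infill dial).
- **`augment`** — the six axis-order orientations (`xyz`, `yzx`, `zyx`,
  `xzy`, `yxz`, `zxy`) used as label-preserving data augmentation.
- **`segnet`** — a small 3D U-Net implemented in pure NumPy (im2col + BLAS
  convolutions with hand-written backprop), trained patch-wise by SGD with
  Nesterov momentum, early stopping on whole-volume validation Dice,
  replicate training and median-network selection.  No deep-learning
  framework is required.
- **`metrics`** — multi-label Dice (foreground scope by default) and
  volumetric traits (total volume, percentage calcite).
- **`shape`** — marching-cubes surface extraction, vertex-clustering
  decimation, Taubin smoothing, ICP/Procrustes population alignment and
  kernel-PCA shape scores; PLY/OBJ mesh I/O.
- **`experiments`** — the learning-curve sweep (training-set sizes × the
  original/augmented arms × replicates), the Dice-vs-size quasibinomial
  logit GLM, the early-stopping vs full-run comparison, manual-vs-network
  agreement regressions, and minimum-specimen determination.

## Command line

```sh
foramcurve synth   --out data/                     # synthetic population + manifest
foramcurve augment --in data/train --out data/aug  # 6 orientations per stack
foramcurve train   --train data/train --val data/val --config cfg.yaml --out model/
foramcurve evaluate --model model/ --data data/test --out metrics.csv
foramcurve curve   --out results/                  # the full learning-curve experiment
```

YAML configs override the desk-scale defaults; all of the full-scale
protocol values (64³ patches scaled to 256³, stride 32, batch 24, SGD
lr 0.01 / decay 1e-6 / momentum 0.9 + Nesterov, patience 25 within 200
epochs, 3 replicates) are expressible through `TrainConfig`.

## Notes on scale

Everything defaults to desk scale: 24³ phantom volumes, 8³–16³ patches and
a 2-level, 4-channel U-Net, so that a full learning-curve sweep (sizes
1–2–4–8, both arms, 3 replicates) runs in under 10 minutes on one CPU.
The full-scale protocol values remain available in configuration but are
not runnable without GPU-class resources.

The shape stage deliberately replaces deformation-based landmark-free
morphometry with a simpler correspondence-free pipeline (closest-point
displacement features + kernel PCA) that preserves its analytical role:
comparable low-dimensional shape scores for manually and automatically
segmented specimens.
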