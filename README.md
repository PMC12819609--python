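# afcnet

A U-shaped polyp-segmentation network built from three bespoke blocks, with
its full evaluation/training protocol and a synthetic endoscopy-image
generator, so everything runs offline on one CPU:

- **MDCA** — multi-scale depthwise strip-convolution attention: a 5×5
  depthwise-separable pre-conv feeds parallel 1×k/k×1 strip branches
  (k ∈ {7, 11, 21}); their sum gates the block input elementwise and a
  concat-fusion restores the channel width.
- **MAFF** — cross-scale bilinear alignment plus six cascaded **AMFH**
  mixers, each a learnable blend `|w(x+y) + (1−w)(x−y)|` with its ratio
  squashed to (0, 1).
- **UFR** — a GRU-style gated top-down decoder (update/reset gates, candidate
  via tanh), with a 1×1 head, ×4 bilinear upsampling and a logistic output.

The package also provides the confusion-count metrics (Dice, IoU, recall,
ACC, TNR), the combined BCE + Dice loss, a fixed four-seed training protocol
(42, 8, 36, 120) with mean/spread aggregation and Welch t-tests, an ablation
harness over the four module variants, and manifest split/merge utilities
(90/10 split with floor rounding; cross-dataset merging).

The network runs on a small internal numpy autodiff layer (`afcnet.nd`) —
no deep-learning framework is required. A `tiny_test` backbone ships for
CPU-scale work; the large pretrained backbones referenced in the literature
are rejected with a clear configuration error when unavailable.

## CLI

```sh
afcnet synth --out data/ --n 64 --size 96 --seed 0     # synthetic dataset + manifest
afcnet split data/manifest.tsv --fraction 0.9 --seed 0 --out splits/
afcnet merge splits/train.tsv other/train.tsv --out merged.tsv
afcnet train splits/train.tsv --config config.yaml --out runs/
afcnet eval runs/seed42.npz splits/test.tsv --out eval.json
afcnet ablate splits/train.tsv splits/test.tsv --out ablation/ \
    --backbone tiny_test --width 16 --input-size 96 --max-steps 300
afcnet summarize runs/report.json
```

Config files are flat `key: value` text mirroring the training
hyperparameters (epochs, batch_size, learning_rate, seeds, backbone_name,
common_width, input_size, ...). Manifests are TSV (`image`, `mask`,
`split`); logs are line-delimited JSON; reports are JSON plus TSV tables;
checkpoints are single `.npz` files embedding the model config.

## Layout

```
src/afcnet/
  nd/          numpy autodiff: tensors, conv2d, bilinear resize, BN, Adam
  mdca.py      strip-convolution attention block
  maff.py      cross-scale alignment + adaptive add/subtract fusion
  ufr.py       gated decoder
  assembly.py  backbones, model config, ablation variants, param accounting
  metrics.py   confusion metrics, combined loss, seed stats, Welch test
  synthdata.py seeded endoscopy-like frame/mask generator
  data.py      manifests, split/merge, paired augmentation, loading
  training.py  multi-seed trainer, evaluation, ablation harness
  cli.py       command-line surface
```
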