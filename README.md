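# plasmacount

Counting CD138-positive (plasma) and CD138-negative nucleated cells on
stained bone-marrow images. Cells annotated by a single center point are
learned as dilated-disc semantic segmentation by a small fully-convolutional
encoder–decoder network; cell centroids are recovered as peaks of smoothed
class pseudoprobability heatmaps, matched against ground truth by linear sum
assignment, and scaled to whole slides by shift-and-stitch tiled inference.
A synthetic IHC-like image generator with known ground-truth centroids makes
the entire pipeline testable without clinical data.

The neural network (convolutions, batchnorm, bilinear upsampling, SGD,
backprop) is implemented in pure NumPy, so the package has no deep-learning
framework dependency; the snapshot-analysis web service runs on the stdlib
WSGI stack.

## Layout

| module | purpose |
| --- | --- |
| `plasmacount.synthetic` | synthetic patch/slide generator with ground truth |
| `plasmacount.annotations` | point annotations, label rasters, dilation, padded tile export, point TSV I/O |
| `plasmacount.network` | NumPy fully-convolutional encoder–decoder, normalizer, checkpoints |
| `plasmacount.training` | augmentation, weighted cross-entropy, SGD epochs, grid search, macro-F1 model selection |
| `plasmacount.detection` | heatmap smoothing (3×3 median + Gaussian), min-distance peak calling, cross-class merge |
| `plasmacount.evaluation` | assignment matching (15 px gate), 3-class confusion matrix, macro-F1, plasma %, report midpoints, ICC(A,1) |
| `plasmacount.wsi` | tiling plan, padded-window inference with reflection, mask gating, stitching, summaries |
| `plasmacount.interface` | CLI and snapshot-analysis WSGI service |

## CLI

One console script with subcommands:

```sh
plasmacount synth patch --config cfg.yaml --out outdir/
plasmacount synth slide --config cfg.yaml --out outdir/
plasmacount train --config cfg.yaml --out run/
plasmacount detect --image patch.png --checkpoint run/checkpoint.npz --out dets.tsv
plasmacount evaluate --truth truth.tsv --pred dets.tsv --threshold 15
plasmacount wsi --slide slide.tiff --mask mask.png --checkpoint run/checkpoint.npz --out wsiout/
plasmacount serve --checkpoint run/checkpoint.npz --port 5000
```

A minimal experiment config (YAML):

```yaml
scene: {width: 128, height: 128, n_positive: 5, n_negative: 15, seed: 0}
n_patches: 25
hyperparams: {learning_rate: 0.05, class_weights: [0.2, 1.0, 1.0], max_epochs: 30, batch_size: 5}
network: {encoder_channels: [12, 24]}
augmentation: {}
```

The service exposes `POST /analyze` (raw image body or multipart `image`
field) returning counts, plasma-cell percentage and a base64 overlay, and
`GET /health`.

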