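# facelesion

Which parts of a face does a convolutional classifier actually need to
recognize who it is looking at?  `facelesion` answers that by *lesioning*
facial features at the input of a small identity classifier — zeroing an
exact-area rectangle over a feature, or blurring just that region with
increasing severity — and measuring what happens to accuracy, to the
model's Grad-CAM attention, and to the interaction between features.  It
is aimed at computational cognitive-neuroscience work on face perception
(feature importance hierarchies, attention redirection, holistic
processing) where one wants the full occlusion-sensitivity pipeline to be
reproducible on a laptop CPU, without photographic datasets, GPUs, or
landmark detectors.

The package ships its own synthetic parametric face generator with
ground-truth landmarks, so every experiment is a planted-signal study: you
decide how much identity information each feature carries, and the
pipeline must recover it.

## Method

* **Closed-set identification.** A small residual network (strided stem,
  three residual blocks of widths 16/32/64, global average pooling, one
  C-unit FC layer) is trained on intact images with softmax cross-entropy
  `L(y,z) = −(1/N) Σᵢ Σⱼ yᵢⱼ log(exp zᵢⱼ / Σₖ exp zᵢₖ)`.
* **Exact-area masking.** A feature's keypoint bounding box is grown to a
  rectangle of exactly 800 pixels (400 for the smaller eyebrows) and set
  to zero, so importance comparisons are not confounded by region size.
  Size-matched randomly placed rectangles (uniform over interior
  positions, mutually non-overlapping) control for generic occlusion.
* **Graded blur.** Region-restricted convolution with the normalized
  Gaussian kernel `G(i,j) = exp(−(i²+j²)/2σ²)/(2πσ²)`, σ ∈ {2, 8, 10, 20},
  a graded lesion between "intact" and "fully masked".
* **Grad-CAM emphasis.** Channel weights are spatially averaged
  target-class score gradients at the last conv block; the rectified
  weighted activation sum, upsampled and scaled to 0–255, is averaged over
  a feature's region (mean = size-normalized emphasis).  Redirection is
  the change of a masked feature's own region emphasis.
* **Statistics.** Paired percentile bootstrap (N = 1,000) for accuracy
  differences; feature importance by accuracy drop; pairwise
  super-additivity `excess = drop_AB − (drop_A + drop_B)` as a holistic
  -processing probe; error-set overlap between conditions.

See `docs/methods.md` for the model, the generator's planted-signal
design, and all numerical choices.

## Worked example

Generate the default desk-scale study (32 identities × 50 images,
planted informativeness eyebrows : eyes : mouth : nose = 2 : 1 : 0.5 :
0.25), train, and rank features by masking:

```sh
python analysis/01_generate_dataset.py --seed 0
python analysis/02_train_classifier.py --seed 0
python analysis/03_mask_importance.py  --seed 0
```

which prints (seed 0):

```
rendered 1600 images (1120 train / 480 val, 32 identities) -> scratch/run0/data/manifest.csv
final intact validation accuracy: 0.633 (chance 0.031); checkpoint -> scratch/run0/model
                      condition   n  accuracy_pct  drop_pct  p_vs_none
                           none 480     63.333333  0.000000        NaN
random:eyebrows+eyes+nose+mouth 480     11.458333 51.875000   0.001998
                  mask:eyebrows 480     17.916667 45.416667   0.001998
                      mask:eyes 480     17.916667 45.416667   0.001998
                      mask:nose 480     46.875000 16.458333   0.001998
                     mask:mouth 480     42.083333 21.250000   0.001998
importance order (most important first): eyebrows > eyes > mouth > nose
  eyebrows vs eyes: diff=+0.000 p=0.9950
  eyes vs mouth: diff=+0.242 p=0.0020
  mouth vs nose: diff=+0.048 p=0.0799
```

Reading the table: the intact model sits at 63% (20× chance); every
single-feature mask drops accuracy significantly (p ≈ 0.002, the bootstrap
floor at N = 1,000), and the recovered order matches the planting —
eyebrows, despite their smaller 400 px mask, hurt as much as the 800 px
eye mask (the two high-signal features are statistically tied at this
desk scale), with mouth and nose clearly behind.  The random-placement
control shows the generic cost of equal-area occlusion at matched total
area (its matched comparison is the all-features-masked condition).  `04_blur_curves.py` traces accuracy across blur
severities down to the full mask, `05_emphasis_redirection.py` writes the
Grad-CAM emphasis and redirection tables, `06_holistic_pairs.py` the
pairwise super-additivity and error-overlap report, and
`07_redundancy_study.py` contrasts super-additivity between independent
(r = 0) and redundant (r = 0.8) planted feature geometry.

The same pipeline is scriptable through one CLI with a YAML run config
(see `configs/desk.yaml`):

```sh
facelesion generate --config configs/desk.yaml --out data/ --seed 0
facelesion train    --config configs/desk.yaml --data data/ --out model/ --seed 0
facelesion analyze  --config configs/desk.yaml --data data/ \
                    --checkpoint model/model.npz --out results/ --seed 0
```

Externally produced data are accepted in the same layout: PNG images plus
per-image JSON keypoint sidecars `{feature: [[x, y], ...]}` (0-based pixel
coordinates, x = column) and a `manifest.csv` with `path, identity, split`.

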