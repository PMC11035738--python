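# Desk-scale run: 32 identities x 50 images, planted feature importance
# eyebrows > eyes > mouth > nose, small residual backbone, 15 epochs.
generator:
  n_identities: 32
  images_per_identity: 50
  image_size: 112
  informativeness: {eyebrows: 2.0, eyes: 1.0, mouth: 0.5, nose: 0.25}
  within_jitter: 0.6
  noise_sd: 0.05
  redundancy: 0.0
classifier:
  epochs: 15
  learning_rate: 0.03
  batch_size: 64
areas: {eyebrows: 400, eyes: 800, nose: 800, mouth: 800}
bootstrap:
  n_iter: 1000
emphasis_images: 32
heatmap_exports: 4
include_blur: true
include_pairs: true
seed: 0
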