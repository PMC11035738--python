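"""Grad-CAM heatmaps and region-emphasis statistics.

Grad-CAM weights each channel of the last convolutional layer's activation
by the spatial mean of the target-class score gradient with respect to that
channel, sums the weighted channels, rectifies (negative values to zero),
bilinearly upsamples to the input grid, and min-max scales to 0-255.

Two emphasis statistics are built on the heatmap:

* region emphasis — the mean heatmap value inside a feature's region.
  Using the mean (not the sum) normalizes by region size, so the 800 px
  eye/nose/mouth regions are directly comparable with the 400 px eyebrow
  region.
* emphasis shift — the change in a masked feature's region emphasis
  between the lesioned and the intact image, both measured over the intact
  image's feature region and stratified by whether the lesioned image was
  still recognized.  A negative shift reads as the model redirecting its
  attention away from the masked feature toward intact ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classifier import FaceClassifier
from .lesion import (DEFAULT_AREAS, FeatureRegion, LesionSpec, apply_lesion,
                     region_from_keypoints)
from .synthetic import FaceSample


@dataclass
class Heatmap:
    grid: np.ndarray     # (H, W) float, 0..255
    target_class: int
    is_zero: bool = False  # pre-scaling map was identically zero


@dataclass
class EmphasisRecord:
    feature: str
    weight: float        # mean heatmap value in the region, 0..255
    image_id: int
    condition: str


@dataclass
class RedirectionRecord:
    feature: str
    delta: float         # lesioned-minus-intact region weight, -255..255
    stratum: str         # "true" | "false" | "all"


def _bilinear_upsample(grid: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Pixel-center-aligned bilinear interpolation to (out_h, out_w)."""
    in_h, in_w = grid.shape
    rows = (np.arange(out_h) + 0.5) * in_h / out_h - 0.5
    cols = (np.arange(out_w) + 0.5) * in_w / out_w - 0.5
    rr, cc = np.meshgrid(np.clip(rows, 0, in_h - 1),
                         np.clip(cols, 0, in_w - 1), indexing="ij")
    return ndimage.map_coordinates(grid, [rr, cc], order=1, mode="nearest")


def gradcam_raw(model: FaceClassifier, image: np.ndarray,
                target_class: int) -> np.ndarray:
    """Pre-scaling Grad-CAM map on the last-conv grid (rectified, unscaled)."""
    n_classes = model.config.n_classes
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} out of range 0..{n_classes - 1}")
    x = model.preprocess([image])
    net = model.net
    net.forward(x, train=False, capture_index=model.feature_index)
    acts = net.captured[0]  # (K, h, w)
    dscore = np.zeros((1, n_classes), dtype=np.float32)
    dscore[0, target_class] = 1.0
    dacts = net.backward_to_capture(dscore, model.feature_index)[0]
    alphas = dacts.mean(axis=(1, 2))                     # gradient GAP per channel
    cam = np.maximum((alphas[:, None, None] * acts).sum(axis=0), 0.0)
    return cam.astype(np.float64)


def gradcam(model: FaceClassifier, image: np.ndarray,
            target_class: int) -> Heatmap:
    """0-255 scaled Grad-CAM heatmap aligned to the input image grid."""
    cam = gradcam_raw(model, image, target_class)
    h, w = np.asarray(image).shape[:2]
    up = _bilinear_upsample(cam, h, w)
    top, lo = up.max(), up.min()
    if top <= 0.0 or top == lo:
        # identically zero or constant map: no localization signal
        return Heatmap(grid=np.zeros((h, w)), target_class=target_class,
                       is_zero=True)
    grid = (up - lo) / (top - lo) * 255.0
    return Heatmap(grid=grid, target_class=target_class)


def region_emphasis(heatmap: Heatmap, region: FeatureRegion) -> float:
    """Mean heatmap value over the region (size-normalized emphasis)."""
    sy, sx = region.slices
    patch = heatmap.grid[sy, sx]
    if patch.size == 0:
        raise ValueError("region does not intersect the heatmap")
    return float(patch.mean())


def emphasis_shift(model: FaceClassifier, sample: FaceSample, feature: str,
                   lesion: LesionSpec, target_class: int | None = None,
                   area_config: dict[str, int] | None = None) -> RedirectionRecord:
    """Masked-minus-intact emphasis over the intact feature region.

    The correctness stratum comes from the model's prediction on the
    lesioned image versus the sample's true identity.  A ``none`` lesion
    contrasts the intact image with itself (delta 0, stratified normally).
    """
    if lesion.kind != "none" and feature not in lesion.features:
        raise ValueError(f"lesion {lesion.label!r} does not perturb {feature!r}")
    areas = DEFAULT_AREAS if area_config is None else area_config
    target = sample.identity_id if target_class is None else target_class
    region = region_from_keypoints(sample.keypoints[feature], areas[feature],
                                   sample.image.shape, feature=feature)
    intact_w = region_emphasis(gradcam(model, sample.image, target), region)
    lesioned_img = apply_lesion(sample, lesion, area_config)
    lesioned_w = region_emphasis(gradcam(model, lesioned_img, target), region)
    pred = int(np.argmax(model.scores([lesioned_img])[0]))
    stratum = "true" if pred == sample.identity_id else "false"
    return RedirectionRecord(feature=feature, delta=lesioned_w - intact_w,
                             stratum=stratum)
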