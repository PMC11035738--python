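"""Feature lesioning: exact-area masks, randomized control masks, and
region-restricted Gaussian blur.

A feature's lesion region is an axis-aligned rectangle that covers all of
the feature's keypoints and, whenever geometrically possible, has an exact
fixed pixel area (800 px by default; 400 px for the smaller eyebrows), so
that importance comparisons across features are not confounded by the
amount of occluded area.  Rectangles are half-open ``[x0, x0+w) x
[y0, y0+h)`` in 0-based pixel coordinates with x = column.

Blur lesions convolve the whole image with a normalized, truncated
Gaussian kernel

    G(i, j) = 1 / (2 pi sigma^2) * exp(-(i^2 + j^2) / (2 sigma^2))

(reflective border handling) and paste the blurred values back only inside
the feature region, so region-edge pixels are averaged with their true
neighbors.  The graded severity levels used in the experiments are
sigma in {2, 8, 10, 20}; a full zero-mask sits past the strongest blur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import FEATURES, FaceSample

#: default lesion areas in pixels: uniform 800, smaller 400 for eyebrows
DEFAULT_AREAS = {"eyebrows": 400, "eyes": 800, "nose": 800, "mouth": 800}

#: blur severity levels 1-4
SIGMA_LEVELS = (2.0, 8.0, 10.0, 20.0)


@dataclass
class FeatureRegion:
    feature: str                      # feature name or "random"
    rect: tuple[int, int, int, int]   # (x0, y0, width, height), half-open
    target_area: int
    actual_area: int
    exact: bool = True                # False when target area was unachievable

    @property
    def slices(self) -> tuple[slice, slice]:
        x0, y0, w, h = self.rect
        return slice(y0, y0 + h), slice(x0, x0 + w)


@dataclass
class GaussianKernel:
    sigma: float
    size: int
    weights: np.ndarray  # (size, size), sums to 1


@dataclass
class LesionSpec:
    kind: str                                  # mask | blur | random_mask | none
    features: tuple[str, ...] = ()
    sigma: float | None = None                 # blur only
    seed: int | None = None                    # random_mask only

    def __post_init__(self):
        if self.kind not in ("mask", "blur", "random_mask", "none"):
            raise ValueError(f"unknown lesion kind: {self.kind!r}")
        self.features = tuple(self.features)
        for f in self.features:
            if f not in FEATURES:
                raise ValueError(f"unknown feature: {f!r}")
        if self.kind == "blur" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("blur lesion requires sigma > 0")

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "none"
        feats = "+".join(self.features)
        if self.kind == "blur":
            return f"blur:{feats}:sigma={self.sigma:g}"
        if self.kind == "random_mask":
            return f"random:{feats}"
        return f"mask:{feats}"


def blur_level_sigma(level: int) -> float:
    """Map severity level 1-4 to sigma in {2, 8, 10, 20}."""
    if not 1 <= level <= 4:
        raise ValueError("blur level must be 1..4")
    return SIGMA_LEVELS[level - 1]


def _clip_rect(x0: int, y0: int, w: int, h: int, shape) -> tuple[int, int, int, int]:
    hh, ww = shape[:2]
    x1, y1 = min(x0 + w, ww), min(y0 + h, hh)
    x0, y0 = max(x0, 0), max(y0, 0)
    return x0, y0, max(x1 - x0, 0), max(y1 - y0, 0)


def _place_covering(c: float, w: int, lo: int, hi: int) -> int:
    """Left edge of a width-w interval centered near c and covering [lo, hi]."""
    x0 = int(round(c - w / 2.0))
    x0 = min(x0, lo)
    x0 = max(x0, hi + 1 - w)
    return x0


def region_from_keypoints(points, target_area: int, image_shape,
                          feature: str = "feature") -> FeatureRegion:
    """Smallest-keypoint-covering rectangle inflated to an exact pixel area.

    Starts from the minimal axis-aligned bounding rectangle of the points.
    If its area already exceeds ``target_area`` the bounding rectangle is
    returned flagged inexact.  Otherwise the rectangle is grown to a
    divisor pair (w, h) of ``target_area`` with w, h at least the bounding
    box dimensions, picking the pair closest in aspect to the
    aspect-preserving scaled box; when no divisor pair covers, the smallest
    covering area >= target is used (flagged inexact).  Image-boundary
    clipping happens last and is recorded in ``actual_area``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need >= 2 (x, y) points")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate keypoints: all points identical")
    xs, ys = pts[:, 0], pts[:, 1]
    bx0, bx1 = math.floor(xs.min()), math.ceil(xs.max())
    by0, by1 = math.floor(ys.min()), math.ceil(ys.max())
    w0, h0 = bx1 - bx0 + 1, by1 - by0 + 1
    cx, cy = (bx0 + bx1) / 2.0, (by0 + by1) / 2.0

    if w0 * h0 > target_area:
        x0, y0, w, h = _clip_rect(bx0, by0, w0, h0, image_shape)
        return FeatureRegion(feature, (x0, y0, w, h), target_area,
                             w * h, exact=False)

    # aspect-preserving scale of the bounding box up to the target area
    s = math.sqrt(target_area / (w0 * h0))
    tw, thh = w0 * s, h0 * s
    best = None
    for h in range(h0, target_area + 1):
        if target_area % h:
            continue
        w = target_area // h
        if w < w0:
            break
        dev = abs(math.log((w / h) / (tw / thh)))
        if best is None or dev < best[0]:
            best = (dev, w, h)
    if best is not None:
        _, w, h = best
        exact = True
    else:
        # no divisor pair covers: smallest covering area >= target
        w, h = math.ceil(tw), math.ceil(thh)
        w, h = max(w, w0), max(h, h0)
        # greedy trim of the slack dimension while staying covering and >= target
        while w > w0 and (w - 1) * h >= target_area:
            w -= 1
        while h > h0 and w * (h - 1) >= target_area:
            h -= 1
        exact = (w * h == target_area)
    x0 = _place_covering(cx, w, bx0, bx1)
    y0 = _place_covering(cy, h, by0, by1)
    x0, y0, wc, hc = _clip_rect(x0, y0, w, h, image_shape)
    return FeatureRegion(feature, (x0, y0, wc, hc), target_area,
                         wc * hc, exact=exact and wc * hc == target_area)


def apply_mask(image: np.ndarray, region: FeatureRegion) -> np.ndarray:
    """Zero all channels inside the region; everything else is untouched."""
    out = image.copy()
    sy, sx = region.slices
    out[sy, sx, ...] = 0.0
    return out


def rects_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


def sample_random_regions(templates: list[FeatureRegion], image_shape,
                          seed, max_retries: int = 200,
                          max_restarts: int = 200) -> list[FeatureRegion]:
    """Place each template's w x h rectangle uniformly at random.

    Placements are restricted to fully interior positions (the edge
    threshold: no boundary clipping) and drawn sequentially, rejecting any
    draw that overlaps an already-placed rectangle (staged randomization).
    A stage that exhausts its retries (large rectangles can paint the image
    into a corner) restarts the whole staged sequence with fresh draws.
    Deterministic given the seed.
    """
    hh, ww = image_shape[:2]
    for t in templates:
        _, _, w, h = t.rect
        if w > ww or h > hh:
            raise ValueError(f"template {t.feature} ({w}x{h}) does not fit "
                             f"in a {ww}x{hh} image")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        placed: list[FeatureRegion] = []
        for t in templates:
            _, _, w, h = t.rect
            for _ in range(max_retries):
                x0 = int(rng.integers(0, ww - w + 1))
                y0 = int(rng.integers(0, hh - h + 1))
                rect = (x0, y0, w, h)
                if not any(rects_overlap(rect, p.rect) for p in placed):
                    placed.append(FeatureRegion("random", rect, w * h, w * h))
                    break
            else:
                break  # stage failed: restart the whole sequence
        if len(placed) == len(templates):
            return placed
    raise RuntimeError(
        f"could not place {len(templates)} non-overlapping random masks "
        f"after {max_restarts} staged attempts")


def gaussian_kernel(sigma: float) -> GaussianKernel:
    """Truncated Gaussian kernel of size k = 2*ceil(3*sigma) + 1, renormalized."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = math.ceil(3 * sigma)
    k = 2 * half + 1
    ij = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ij ** 2) / (2.0 * sigma ** 2)) / math.sqrt(2.0 * math.pi * sigma ** 2)
    weights = np.outer(g1, g1)
    weights /= weights.sum()
    return GaussianKernel(sigma=sigma, size=k, weights=weights)


def blur_image(image: np.ndarray, sigma: float) -> np.ndarray:
    """Whole-image convolution with the normalized truncated Gaussian.

    The 2-D kernel is an exact outer product, so the convolution is run
    separably along each axis; borders reflect (symmetric padding).
    """
    kern = gaussian_kernel(sigma)
    g1 = kern.weights.sum(axis=1)  # normalized 1-D factor
    out = np.asarray(image, dtype=np.float64)
    out = ndimage.convolve1d(out, g1, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, g1, axis=1, mode="reflect")
    return out.astype(image.dtype, copy=False)


def blur_region(image: np.ndarray, region: FeatureRegion, sigma: float) -> np.ndarray:
    """Replace pixels inside the region with their fully blurred values."""
    blurred = blur_image(image, sigma)
    out = image.copy()
    sy, sx = region.slices
    out[sy, sx, ...] = blurred[sy, sx, ...]
    return out


def regions_for_sample(sample: FaceSample, features,
                       area_config: dict[str, int] | None = None
                       ) -> list[FeatureRegion]:
    areas = DEFAULT_AREAS if area_config is None else area_config
    regs = []
    for f in features:
        if f not in sample.keypoints:
            raise ValueError(f"sample has no keypoints for feature {f!r}")
        regs.append(region_from_keypoints(sample.keypoints[f], areas[f],
                                          sample.image.shape, feature=f))
    return regs


def apply_lesion(sample: FaceSample, spec: LesionSpec,
                 area_config: dict[str, int] | None = None,
                 random_seed=None) -> np.ndarray:
    """Apply one lesion condition to a sample's image.

    Multi-feature specs apply the perturbation independently per feature;
    ``kind="none"`` returns the image unchanged (a copy).  ``random_seed``
    overrides the spec seed for randomized masks (e.g. a per-image seed).
    """
    img = sample.image.copy()
    if spec.kind == "none":
        return img
    regions = regions_for_sample(sample, spec.features, area_config)
    if spec.kind == "mask":
        for r in regions:
            img = apply_mask(img, r)
    elif spec.kind == "blur":
        blurred = blur_image(sample.image, spec.sigma)
        for r in regions:
            sy, sx = r.slices
            img[sy, sx, ...] = blurred[sy, sx, ...]
    elif spec.kind == "random_mask":
        seed = random_seed if random_seed is not None else (spec.seed or 0)
        for r in sample_random_regions(regions, img.shape, seed):
            img = apply_mask(img, r)
    return img
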