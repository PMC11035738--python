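"""Parametric synthetic face generator with ground-truth feature keypoints.

Renders identity-labeled, face-like grayscale images: an elliptical head
outline plus four features (eyebrows, eyes, nose, mouth) whose geometry is
drawn per identity.  How much each feature tells identities apart is
controlled by a per-feature ``informativeness`` scale on the
between-identity variance; within-identity variation comes from geometric
jitter and additive pixel noise.  A ``redundancy`` knob correlates all
feature parameters through a shared identity factor, planting
non-independence between features.

Every render returns exact keypoints for each feature (the four corners of
the feature's ink bounding box plus its centroid), standing in for
detector-produced facial landmarks.  Coordinates are 0-based pixels,
x = column, origin at the top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

FEATURES = ("eyebrows", "eyes", "nose", "mouth")

# Geometry parameter table at the reference 112 px image size:
# (feature, name, base, between-identity sd unit, lower clip, upper clip).
# Clip bounds keep every feature strictly inside the head outline and keep
# feature ink boxes small enough that the exact-area mask contract (800 px,
# 400 px for eyebrows) is achievable on every render.
_PARAM_SPECS = [
    ("face", "face_ax", 40.0, 1.0, 37.0, 43.0),
    ("face", "face_ay", 48.0, 1.0, 45.0, 51.0),
    ("eyebrows", "brow_thickness", 2.4, 0.35, 0.8, 4.2),
    ("eyebrows", "brow_angle", 0.0, 0.06, -0.22, 0.22),
    ("eyebrows", "brow_height", 24.0, 1.0, 20.5, 27.5),
    ("eyes", "eye_spacing", 16.0, 1.2, 12.5, 19.0),
    ("eyes", "eye_radius", 3.8, 0.5, 2.4, 5.2),
    ("nose", "nose_width", 5.0, 0.9, 2.8, 7.5),
    ("nose", "nose_length", 11.0, 1.4, 7.5, 14.5),
    ("mouth", "mouth_width", 13.0, 1.6, 8.5, 17.5),
    ("mouth", "mouth_curve", 2.0, 1.0, -0.8, 4.8),
]
# Pixel-unit parameters scale with image size; angles do not.
_UNSCALED = {"brow_angle"}

_BG, _SKIN, _INK = 0.55, 0.65, 0.15


def default_informativeness() -> dict[str, float]:
    """Planted per-feature identity signal: eyebrows >> eyes >> mouth >> nose."""
    return {"eyebrows": 2.0, "eyes": 1.0, "mouth": 0.5, "nose": 0.25}


@dataclass
class GeneratorConfig:
    n_identities: int
    images_per_identity: int
    image_size: int = 112
    informativeness: dict[str, float] = field(default_factory=default_informativeness)
    within_jitter: float = 0.6
    noise_sd: float = 0.05
    redundancy: float = 0.0
    split_ratio: tuple[float, float] = (0.7, 0.3)
    seed: int = 0

    def validate(self) -> None:
        if self.n_identities < 2:
            raise ValueError("n_identities must be >= 2")
        if self.images_per_identity < 2:
            raise ValueError("images_per_identity must be >= 2")
        if set(self.informativeness) != set(FEATURES):
            missing = set(FEATURES) - set(self.informativeness)
            extra = set(self.informativeness) - set(FEATURES)
            raise ValueError(
                f"informativeness keys must be exactly {sorted(FEATURES)}; "
                f"missing={sorted(missing)} extra={sorted(extra)}")
        if any(v < 0 for v in self.informativeness.values()):
            raise ValueError("informativeness values must be nonnegative")
        if not (0.0 <= self.redundancy <= 1.0):
            raise ValueError("redundancy must be in [0, 1]")
        if self.within_jitter < 0 or self.noise_sd < 0:
            raise ValueError("within_jitter and noise_sd must be nonnegative")
        if min(self.split_ratio) <= 0 or abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio must be positive and sum to 1")
        if self.image_size < 48:
            raise ValueError("image_size must be >= 48")


@dataclass
class IdentityParams:
    identity_id: int
    values: dict[str, float]


@dataclass
class FaceSample:
    image: np.ndarray            # (H, W) float32 in [0, 1]
    identity_id: int
    keypoints: dict[str, list[tuple[int, int]]]
    split_tag: str = ""          # "train" | "val" | ""


@dataclass
class SplitDataset:
    samples: list[FaceSample]
    n_identities: int

    def subset(self, tag: str) -> list[FaceSample]:
        return [s for s in self.samples if s.split_tag == tag]

    @property
    def train(self) -> list[FaceSample]:
        return self.subset("train")

    @property
    def val(self) -> list[FaceSample]:
        return self.subset("val")


def train_count(n_items: int, train_frac: float) -> int:
    """Training-set size for an n-item pool at the given fraction.

    Deterministic round-half-up: floor(frac * n + 0.5).  At the 7:3 ratio a
    52,000-item pool yields 36,400 training items.
    """
    return math.floor(train_frac * n_items + 0.5)


def sample_identities(config: GeneratorConfig) -> list[IdentityParams]:
    """Draw per-identity geometry parameter sets.

    Between-identity SD of each feature's parameters is the table unit times
    ``informativeness[feature]``; with redundancy r every feature parameter
    loads on one shared identity factor with weight r and on its own factor
    with weight sqrt(1 - r^2), so r = 0 gives independent features and r = 1
    makes all feature geometry a function of a single latent.
    """
    config.validate()
    if all(v == 0 for v in config.informativeness.values()):
        raise ValueError("informativeness is all zero: no identity signal")
    rng = np.random.default_rng([config.seed, 0])
    r = config.redundancy
    own_w = math.sqrt(1.0 - r * r)
    scale = config.image_size / 112.0
    out = []
    for ident in range(config.n_identities):
        z_common = rng.normal()
        values: dict[str, float] = {}
        for feat, name, base, sd, lo, hi in _PARAM_SPECS:
            z = rng.normal()
            if feat == "face":
                # head outline varies mildly and independently of the
                # feature informativeness knobs
                v = base + sd * z
            else:
                info = config.informativeness[feat]
                v = base + sd * info * (r * z_common + own_w * z)
            v = min(max(v, lo), hi)
            if name not in _UNSCALED:
                v *= scale
            values[name] = v
        out.append(IdentityParams(identity_id=ident, values=values))
    return out


def _jitter_params(identity: IdentityParams, config: GeneratorConfig,
                   rng: np.random.Generator) -> dict[str, float]:
    scale = config.image_size / 112.0
    vals = {}
    for feat, name, base, sd, lo, hi in _PARAM_SPECS:
        v = identity.values[name]
        if name not in _UNSCALED:
            v = v / scale  # back to reference units for clipping
        v = v + config.within_jitter * sd * rng.normal()
        v = min(max(v, lo), hi)
        if name not in _UNSCALED:
            v *= scale
        vals[name] = v
    return vals


def _render_geometry(vals: dict[str, float], size: int):
    """Rasterize outline + features; returns (image, per-feature ink masks)."""
    h = w = size
    cx = cy = (size - 1) / 2.0
    s = size / 112.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - cx, yy - cy

    img = np.full((h, w), _BG, dtype=np.float64)
    ax, ay = vals["face_ax"], vals["face_ay"]
    e_outer = (dx / ax) ** 2 + (dy / ay) ** 2
    interior = e_outer <= 1.0
    img[interior] = _SKIN
    ring_w = 1.8 * s
    e_inner = (dx / (ax - ring_w)) ** 2 + (dy / (ay - ring_w)) ** 2
    img[interior & (e_inner > 1.0)] = _INK

    masks: dict[str, np.ndarray] = {}

    # eyebrows: two tilted bars above the eyes (mirror symmetric tilt)
    th = vals["brow_thickness"]
    ang = vals["brow_angle"]
    bh = vals["brow_height"]
    spacing = vals["eye_spacing"]
    radius = vals["eye_radius"]
    brow_cx = min(max(spacing, 13.0 * s), 18.0 * s)
    half_len = min(max(radius + 2.2 * s, 3.8 * s), 6.0 * s)
    m = np.zeros((h, w), dtype=bool)
    for side in (-1.0, 1.0):
        bx = dx - side * brow_cx
        by = dy + bh
        tilt = math.tan(ang) * bx * side
        m |= (np.abs(bx) <= half_len) & (np.abs(by - tilt) <= th / 2.0)
    masks["eyebrows"] = m

    # eyes: two filled disks
    ey = dy + 10.0 * s
    m = np.zeros((h, w), dtype=bool)
    for side in (-1.0, 1.0):
        ex = dx - side * spacing
        m |= ex * ex + ey * ey <= radius * radius
    masks["eyes"] = m

    # nose: triangle outline, apex above, base below
    nw, nl = vals["nose_width"], vals["nose_length"]
    apex = (cx, cy - 2.0 * s)
    bl = (cx - nw / 2.0, cy - 2.0 * s + nl)
    br = (cx + nw / 2.0, cy - 2.0 * s + nl)
    m = np.zeros((h, w), dtype=bool)
    for p, q in ((apex, bl), (apex, br), (bl, br)):
        px, py = p
        qx, qy = q
        vx, vy = qx - px, qy - py
        denom = vx * vx + vy * vy
        t = np.clip(((xx - px) * vx + (yy - py) * vy) / denom, 0.0, 1.0)
        dist2 = (xx - (px + t * vx)) ** 2 + (yy - (py + t * vy)) ** 2
        m |= dist2 <= (0.85 * s) ** 2
    masks["nose"] = m

    # mouth: curved bar (parabolic arc)
    mw, mc = vals["mouth_width"], vals["mouth_curve"]
    my = dy - 26.0 * s
    curve = mc * ((dx / mw) ** 2 - 0.5)
    masks["mouth"] = (np.abs(dx) <= mw) & (np.abs(my - curve) <= 0.9 * s)

    for feat in FEATURES:
        img[masks[feat]] = _INK
    return img, masks, interior


def _keypoints_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    ys, xs = np.nonzero(mask)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    cxp, cyp = int(round(xs.mean())), int(round(ys.mean()))
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (cxp, cyp)]


def _add_clutter(img: np.ndarray, masks: dict[str, np.ndarray],
                 rng: np.random.Generator, size: int) -> np.ndarray:
    """Per-draw dark elliptical blobs emulating photo nuisance structure.

    Real face photographs carry uninformative dark regions (hair, shadows,
    eyeglass frames); a classifier trained on them learns that compact dark
    blobs are non-diagnostic, which is what makes small occluding masks a
    graded rather than catastrophic perturbation.  Blobs are drawn under
    the features (features are rasterized last), so they never remove
    feature information and keypoints stay exact.
    """
    s = size / 112.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    protected = np.zeros((size, size), dtype=bool)
    for m in masks.values():
        protected |= m
    n_blobs = 2 + int(rng.poisson(2.0))
    for _ in range(n_blobs):
        bx, by = rng.uniform(0, size, 2)
        rx_, ry_ = rng.uniform(3.0, 10.0, 2) * s
        val = rng.uniform(0.05, 0.35)
        blob = ((xx - bx) / rx_) ** 2 + ((yy - by) / ry_) ** 2 <= 1.0
        img[blob & ~protected] = val
    return img


def render_face(identity: IdentityParams, config: GeneratorConfig,
                draw_index: int, max_retries: int = 20) -> FaceSample:
    """Render one jittered, noisy draw of an identity.

    Deterministic in (config.seed, identity_id, draw_index).  Geometric
    jitter that would push a feature outside the head outline is resampled
    up to ``max_retries`` times, then raised.
    """
    rng = np.random.default_rng([config.seed, 1, identity.identity_id, draw_index])
    for _ in range(max_retries):
        vals = _jitter_params(identity, config, rng)
        img, masks, interior = _render_geometry(vals, config.image_size)
        if all(bool(np.all(interior[m])) and m.any() for m in masks.values()):
            break
    else:
        raise RuntimeError(
            f"could not place features inside the outline after {max_retries} "
            f"retries (identity {identity.identity_id}, draw {draw_index})")
    if config.within_jitter > 0:
        img = _add_clutter(img, masks, rng, config.image_size)
        for feat in FEATURES:
            img[masks[feat]] = _INK
    if config.within_jitter > 0:
        # photometric within-identity variation (illumination/contrast),
        # scaled by the same knob as the geometric jitter
        gain = 1.0 + 0.12 * config.within_jitter * rng.normal()
        offset = 0.06 * config.within_jitter * rng.normal()
        img = (img - 0.5) * gain + 0.5 + offset
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    keypoints = {feat: _keypoints_from_mask(masks[feat]) for feat in FEATURES}
    return FaceSample(image=img, identity_id=identity.identity_id,
                      keypoints=keypoints)


def generate_dataset(config: GeneratorConfig) -> SplitDataset:
    """Render the full identity-balanced dataset with a per-identity split.

    Each identity contributes ``images_per_identity`` renders, split
    train/val at ``split_ratio`` with round-half-up on the training count
    and a seeded shuffle deciding which draws land in which split.
    """
    config.validate()
    n = config.images_per_identity
    n_train = train_count(n, config.split_ratio[0])
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"images_per_identity={n} at ratio {config.split_ratio} leaves "
            "an empty split; every identity needs >=1 image in each split")
    identities = sample_identities(config)
    samples: list[FaceSample] = []
    for ident in identities:
        order = np.random.default_rng([config.seed, 2, ident.identity_id]) \
            .permutation(n)
        tags = {int(d): ("train" if pos < n_train else "val")
                for pos, d in enumerate(order)}
        for d in range(n):
            s = render_face(ident, config, d)
            s.split_tag = tags[d]
            samples.append(s)
    return SplitDataset(samples=samples, n_identities=config.n_identities)
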