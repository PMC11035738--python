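"""A small residual convolutional identity classifier.

Closed-set identification: C identities, a conv backbone ending in global
average pooling and one C-unit fully connected layer, trained with softmax
cross-entropy

    L(y, z) = -(1/N) sum_i sum_j y_ij log(exp(z_ij) / sum_k exp(z_ik))

on intact images only; lesioned images appear exclusively at evaluation
time.  Inputs are grayscale renders replicated across three channels and
normalized with the ImageNet per-channel mean/SD constants.

The default backbone is a deliberately small stand-in for the large
residual networks used in production face recognition: a strided stem
convolution followed by three residual blocks of widths 16/32/64.  Depth
and widths are configurable for larger budgets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp

from . import nn
from .lesion import LesionSpec, apply_lesion
from .synthetic import FaceSample, SplitDataset

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)


@dataclass
class ClassifierConfig:
    n_classes: int
    input_size: int = 112
    channel_means: tuple[float, ...] = IMAGENET_MEAN
    channel_sds: tuple[float, ...] = IMAGENET_SD
    stem_channels: int = 16
    stem_kernel: int = 5
    stem_stride: int = 4
    blocks: tuple[tuple[int, int], ...] = ((16, 1), (32, 2), (64, 2))
    epochs: int = 15
    learning_rate: float = 0.03
    momentum: float = 0.9
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(m <= 0 for m in self.channel_means) or any(s <= 0 for s in self.channel_sds):
            raise ValueError("normalization constants must be positive")
        stride_total = self.stem_stride
        for _, s in self.blocks:
            stride_total *= s
        if self.input_size % stride_total:
            raise ValueError(
                f"input_size {self.input_size} is not divisible by the total "
                f"backbone stride {stride_total}")


@dataclass
class ScoreMatrix:
    z: np.ndarray  # (N, C) unnormalized scores
    y: np.ndarray  # (N, C) one-hot labels


@dataclass
class ConditionResult:
    condition: str
    correct: np.ndarray    # (N,) bool
    predicted: np.ndarray  # (N,) int

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.correct))

    @property
    def n(self) -> int:
        return int(self.correct.size)


def cross_entropy(scores: ScoreMatrix) -> float:
    """Mean softmax cross-entropy, computed with log-sum-exp stabilization."""
    z = np.asarray(scores.z, dtype=np.float64)
    y = np.asarray(scores.y)
    if z.ndim != 2 or y.shape != z.shape or z.shape[0] < 1:
        raise ValueError("z and y must be matching (N, C) matrices, N >= 1")
    if not np.all(np.isfinite(z)):
        raise ValueError("scores must be finite")
    onehot = np.isin(y, (0, 1)).all() and np.all(y.sum(axis=1) == 1)
    if not onehot:
        raise ValueError("labels must be one-hot rows")
    lse = logsumexp(z, axis=1)
    true_z = (z * y).sum(axis=1)
    return float(np.mean(lse - true_z))


class FaceClassifier:
    """Backbone + head with capture hooks for Grad-CAM."""

    def __init__(self, config: ClassifierConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng([config.seed, 10])
        layers: list[nn.Layer] = [
            nn.Conv2d(3, config.stem_channels, config.stem_kernel,
                      config.stem_stride, pad=config.stem_kernel // 2, rng=rng),
            nn.BatchNorm2d(config.stem_channels),
            nn.ReLU(),
        ]
        cin = config.stem_channels
        for cout, stride in config.blocks:
            layers.append(nn.ResidualBlock(cin, cout, stride, rng=rng))
            cin = cout
        # index of the last convolutional layer's output (Grad-CAM target)
        self.feature_index = len(layers) - 1
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Linear(cin, config.n_classes, rng=rng))
        self.net = nn.Sequential(layers)

    # ---- input pipeline -------------------------------------------------
    def preprocess(self, images) -> np.ndarray:
        """Stack (H, W) grayscale images to normalized (N, 3, H, W) float32."""
        arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
        if arr.ndim == 3:  # replicate grayscale across channels
            arr = np.repeat(arr[:, None, :, :], 3, axis=1)
        mean = np.asarray(self.config.channel_means, dtype=np.float32)
        sd = np.asarray(self.config.channel_sds, dtype=np.float32)
        return (arr - mean[None, :, None, None]) / sd[None, :, None, None]

    def scores(self, images, batch_size: int = 128) -> np.ndarray:
        """Eval-mode class scores for a list/array of grayscale images."""
        outs = []
        for i in range(0, len(images), batch_size):
            x = self.preprocess(images[i:i + batch_size])
            outs.append(self.net.forward(x, train=False))
        return np.concatenate(outs, axis=0)

    # ---- persistence ----------------------------------------------------
    def save(self, path) -> None:
        state = self.net.state_arrays()
        cfg = asdict(self.config)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "FaceClassifier":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        for k in ("channel_means", "channel_sds", "split_ratio"):
            if k in cfg and isinstance(cfg[k], list):
                cfg[k] = tuple(cfg[k])
        cfg["blocks"] = tuple(tuple(b) for b in cfg["blocks"])
        model = cls(ClassifierConfig(**cfg))
        model.net.load_state_arrays({k: data[k] for k in data.files
                                     if k != "__config__"})
        return model


def build_model(config: ClassifierConfig) -> FaceClassifier:
    """Deterministically initialized classifier per the config seed."""
    return FaceClassifier(config)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(model: FaceClassifier, dataset: SplitDataset,
          config: ClassifierConfig | None = None):
    """SGD-momentum training on intact training images.

    Returns ``(model, history)`` where history is a list of dicts with
    per-epoch mean training loss and intact-validation accuracy.  Fully
    deterministic given the config seed (init and shuffling).  Aborts on a
    non-finite loss.
    """
    config = config or model.config
    train_samples = dataset.train
    val_samples = dataset.val
    labels = sorted({s.identity_id for s in dataset.samples})
    if len(labels) != config.n_classes or labels != list(range(len(labels))):
        raise ValueError(
            f"dataset identities {len(labels)} (must be contiguous 0..C-1) do "
            f"not match n_classes={config.n_classes}")
    x_all = model.preprocess([s.image for s in train_samples])
    y_all = np.array([s.identity_id for s in train_samples], dtype=np.int64)
    n = len(train_samples)
    rng = np.random.default_rng([config.seed, 11])
    opt = nn.SGDMomentum(model.net, lr=config.learning_rate,
                         momentum=config.momentum)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            logits = model.net.forward(xb, train=True)
            probs = _softmax(logits.astype(np.float64))
            loss = float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-300)))
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss={loss}")
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(np.float32)
            model.net.zero_grads()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_res = evaluate(model, val_samples, LesionSpec(kind="none"))
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_accuracy": val_res.accuracy})
    return model, history


def evaluate(model: FaceClassifier, samples: list[FaceSample],
             lesion: LesionSpec, area_config: dict[str, int] | None = None,
             batch_size: int = 128) -> ConditionResult:
    """Score lesioned copies of the samples and record per-image correctness.

    Randomized control masks get an independent placement per image, derived
    deterministically from the spec seed and the image index.  Prediction is
    argmax with lowest-index tie-break.
    """
    if len(samples) == 0:
        raise ValueError("no samples to evaluate")
    images = []
    for i, s in enumerate(samples):
        if lesion.kind == "random_mask":
            images.append(apply_lesion(s, lesion, area_config,
                                       random_seed=[lesion.seed or 0, i]))
        else:
            images.append(apply_lesion(s, lesion, area_config))
    z = model.scores(images, batch_size=batch_size)
    predicted = np.argmax(z, axis=1)
    truth = np.array([s.identity_id for s in samples], dtype=np.int64)
    return ConditionResult(condition=lesion.label,
                           correct=predicted == truth, predicted=predicted)
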