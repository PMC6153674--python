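"""Binary ablation classifier: architecture variants and training loop.

The classifier is a small strided convolutional network with a pooling head
and a two-way softmax.  Three head variants adapt a stride-32 classification
backbone to the input resolution, as studied for residual networks on
fetoscopic frames:

``downsample224``
    Inputs are downsampled to 224x224; the final 7x7 feature map is
    globally average-pooled (the stock head geometry).
``avg448``
    Inputs stay at 448x448; the average-pooling kernel is enlarged to cover
    the full 14x14 feature map.
``maxavg448``
    Inputs stay at 448x448; the original 7x7 average pool is kept and a max
    pool is added, acting as a single "maximum over averages" head: 7x7
    block means (giving 2x2) followed by a spatial max.
``small_cnn``
    A desk-scale three-layer network on 64x64 inputs with the same
    score contract, trainable on one CPU in minutes.

The published fine-tuning recipe for the full-size residual network
(30000 iterations, learning rate 1e-5, batch size 4) is preserved as
:data:`PAPER_TRAIN`; :data:`DESK_TRAIN` is the small-scale default.

Scores are softmax probabilities, so the two class scores of every
prediction sum to one and score comparisons between inference passes are
well-posed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from . import nn
from .data import AnnotatedDataset, rotate_pixels
from .types import ClassScores, Frame

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "PAPER_TRAIN",
    "DESK_TRAIN",
    "VARIANT_INPUT_SIZE",
    "resize_input",
    "pool_avg_full",
    "pool_max_of_avg",
    "build_model",
    "train",
    "BinaryClassifier",
]

VARIANT_INPUT_SIZE = {
    "downsample224": 224,
    "avg448": 448,
    "maxavg448": 448,
    "small_cnn": 64,
}


@dataclass(frozen=True)
class BackboneConfig:
    variant: str = "small_cnn"
    n_outputs: int = 2
    pretrained: bool = False

    def __post_init__(self):
        if self.variant not in VARIANT_INPUT_SIZE:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANT_INPUT_SIZE)}"
            )
        if self.n_outputs != 2:
            raise ValueError("the binary ablation classifier outputs exactly 2 labels")


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 1000
    learning_rate: float = 0.01
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("iterations, learning_rate and batch_size must be positive")


# Published fine-tuning recipe for the pretrained full-size network.
PAPER_TRAIN = TrainConfig(iterations=30000, learning_rate=1e-5, batch_size=4, seed=0)
# Desk-scale default for the small CPU-trainable network.
DESK_TRAIN = TrainConfig(iterations=1000, learning_rate=0.01, batch_size=8, seed=0)


def resize_input(frame: Frame | np.ndarray, variant: str) -> np.ndarray:
    """Scale a frame to the variant's input resolution.

    Returns an ``(S, S, 3)`` float32 array in [0, 1] (224 for
    ``downsample224``, 448 for the 448 variants, 64 for ``small_cnn``).
    Bilinear interpolation; an input already at the target size passes
    through unchanged apart from the intensity rescaling to [0, 1].
    """
    pixels = frame.pixels if isinstance(frame, Frame) else frame
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("frames must be square")
    target = VARIANT_INPUT_SIZE[variant]
    img = pixels.astype(np.float32)
    if np.issubdtype(pixels.dtype, np.integer):
        img = img / 255.0
    if pixels.shape[0] == target:
        return img
    out = sktransform.resize(
        img, (target, target), order=1, mode="constant", cval=0.0,
        preserve_range=True, anti_aliasing=pixels.shape[0] > target,
    )
    return out.astype(np.float32)


def pool_avg_full(feature_map: np.ndarray) -> np.ndarray:
    """Global average pool: channel-wise mean over a square C x K x K map."""
    if feature_map.ndim != 3 or feature_map.shape[1] != feature_map.shape[2]:
        raise ValueError(f"expected a square C x K x K map, got {feature_map.shape}")
    return feature_map.mean(axis=(1, 2))


def pool_max_of_avg(feature_map: np.ndarray) -> np.ndarray:
    """Maximum-over-averages pool for doubled input resolution.

    Keeps the original 7x7 average-pooling kernel (stride 7) and takes the
    spatial maximum of the resulting block means, collapsing a C x 14 x 14
    map through C x 2 x 2 to a C-vector.
    """
    if feature_map.ndim != 3 or feature_map.shape[1] != feature_map.shape[2]:
        raise ValueError(f"expected a square C x K x K map, got {feature_map.shape}")
    c, k, _ = feature_map.shape
    if k % 7:
        raise ValueError(f"spatial size {k} not divisible by the 7x7 kernel")
    blocks = feature_map.reshape(c, k // 7, 7, k // 7, 7).mean(axis=(2, 4))
    return blocks.reshape(c, -1).max(axis=1)


def _feature_stack(variant: str, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    """Strided conv stack ending at the variant's final feature map."""
    if variant == "small_cnn":
        widths = [3, 16, 32, 64]  # 64 -> 32 -> 16 -> 8
    else:
        widths = [3, 8, 16, 32, 32, 64]  # stride-32 overall: 448 -> 14, 224 -> 7
    layers: list[nn.Layer] = []
    for cin, cout in zip(widths[:-1], widths[1:]):
        layers.append(nn.Conv2d(cin, cout, k=3, stride=2, pad=1, rng=rng))
        layers.append(nn.ReLU())
    return nn.Sequential(layers), widths[-1]


class BinaryClassifier:
    """Convolutional ablation-vs-not classifier with a pooling head.

    ``forward_batch`` maps ``(N, S, S, 3)`` float images in [0, 1] to
    ``(N, 2)`` softmax probabilities ``[P(ablation), P(not-ablation)]``.
    Inference is deterministic: equal input arrays give bitwise-equal
    scores, which the channel-swap pipeline's symmetry guarantees use.
    """

    def __init__(self, cfg: BackboneConfig, init_seed: int = 0):
        if cfg.pretrained:
            raise RuntimeError(
                "no pretrained weights are available for this backbone; "
                "train from scratch (pretrained=False) or supply a checkpoint"
            )
        self.cfg = cfg
        self.init_seed = init_seed
        rng = np.random.default_rng(init_seed)
        self.features, n_channels = _feature_stack(cfg.variant, rng)
        self.n_channels = n_channels
        if cfg.variant == "maxavg448":
            self.head = nn.Sequential([nn.BlockAvgPool(7), nn.SpatialMax()])
        else:
            self.head = nn.Sequential([nn.GlobalAvgPool()])
        self.fc = nn.Linear(n_channels, cfg.n_outputs, rng=rng)
        self.trained = False

    @property
    def input_size(self) -> int:
        return VARIANT_INPUT_SIZE[self.cfg.variant]

    # --- inference -----------------------------------------------------
    def forward_batch(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        # Per-image standardisation: fetoscope light sources range from very
        # bright to very dim between procedures, so absolute intensity is a
        # confound (ablation frames are the brightest); normalising each
        # image to zero mean / unit variance forces chromatic and structural
        # cues instead.  The statistic pools all pixels and channels, so it
        # is invariant under a green/blue channel swap and preserves the
        # swap's score symmetry bitwise.
        x = np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32)
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True)
        x = (x - mu) / (sd + np.float32(1e-6))
        fm = self.features.forward(x, train=train)
        pooled = self.head.forward(fm, train=train)
        logits = self.fc.forward(pooled, train=train)
        return logits

    def pool(self, feature_map: np.ndarray) -> np.ndarray:
        """Apply this variant's pooling head to one C x K x K feature map."""
        if self.cfg.variant == "maxavg448":
            return pool_max_of_avg(feature_map)
        return pool_avg_full(feature_map)

    def score_frame(self, frame: Frame | np.ndarray) -> ClassScores:
        if not self.trained:
            raise RuntimeError("model is untrained; call train() or load a checkpoint")
        img = resize_input(frame, self.cfg.variant)
        probs = nn.softmax(self.forward_batch(img[None]))
        return ClassScores(float(probs[0, 0]), float(probs[0, 1]))

    # --- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, (p, _) in enumerate(self.features.parameters() + self.fc.parameters()):
            arrays[f"p{i}"] = p
        meta = dict(asdict(self.cfg), init_seed=self.init_seed, trained=self.trained)
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BinaryClassifier":
        blob = np.load(path, allow_pickle=False)
        meta = json.loads(str(blob["meta"]))
        cfg = BackboneConfig(meta["variant"], meta["n_outputs"], meta["pretrained"])
        model = cls(cfg, init_seed=meta["init_seed"])
        params = model.features.parameters() + model.fc.parameters()
        for i, (p, _) in enumerate(params):
            p[:] = blob[f"p{i}"]
        model.trained = meta["trained"]
        return model


def build_model(cfg: BackboneConfig, init_seed: int = 0) -> BinaryClassifier:
    """Construct the binary classifier for the requested variant."""
    return BinaryClassifier(cfg, init_seed=init_seed)


def train(
    model: BinaryClassifier,
    train_set: AnnotatedDataset,
    cfg: TrainConfig = DESK_TRAIN,
    rotate: bool = True,
) -> pd.DataFrame:
    """Train the classifier with cross-entropy; returns the loss trace.

    Every layer is trainable.  Each sampled image receives a fresh uniform
    random rotation per visit (when ``rotate``), so repeated epochs see new
    orientations.  The training set should be class-balanced (see
    :func:`fetseg.data.balanced_subsample`); an imbalanced set triggers a
    warning, a single-class or empty set is an error.  Deterministic for a
    fixed ``cfg.seed``.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    labels = np.array([f.label.binary for f in train_set.frames])
    if labels.all() or not labels.any():
        raise ValueError("training set contains a single class; need both labels")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if abs(n_pos - n_neg) > 0.1 * len(labels):
        warnings.warn(
            f"training set is imbalanced ({n_pos} ablation vs {n_neg} not-ablation); "
            "consider balanced_subsample()",
            stacklevel=2,
        )
    X = np.stack([resize_input(f, model.cfg.variant) for f in train_set.frames])
    # class index 0 = ablation (positive), 1 = not-ablation
    y = np.where(labels, 0, 1)

    rng = np.random.default_rng(cfg.seed)
    params = model.features.parameters() + model.fc.parameters()
    opt = nn.SGDMomentum(params, learning_rate=cfg.learning_rate)
    losses = np.empty(cfg.iterations, dtype=np.float64)
    n = len(X)
    for it in range(cfg.iterations):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        batch = X[idx]
        if rotate:
            batch = np.stack(
                [rotate_pixels(im, float(rng.uniform(0, 360))) for im in batch]
            )
        logits = model.forward_batch(batch, train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
        dpool = model.fc.backward(dlogits)
        dfm = model.head.backward(dpool)
        model.features.backward(dfm)
        opt.step()
        losses[it] = loss
    model.trained = True
    return pd.DataFrame({"iteration": np.arange(cfg.iterations), "loss": losses})
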