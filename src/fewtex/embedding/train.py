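"""Preprocessing, augmentation and two-stage transfer training.

The training recipe follows the transfer-learning schedule used for the
classification stages: Adam, cross-entropy, batch size 32, up to 30
epochs with an early-stop policy, initial learning rate 0.001 decayed by
x0.1 every 7 epochs, and crop / rotation / flip / color augmentation on
the training split only.  Stage B trains backbone + head + a binary
classifier on a surrogate task; stage C swaps in a ternary classifier
(retaining all other weights) and continues training on the target task.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from fewtex.embedding import nn

__all__ = [
    "PreprocSpec", "HeadSpec", "TrainConfig", "EmbeddingVector", "Extractor",
    "preprocess", "augment", "build_model", "train_classifier_stage",
    "truncate_to_extractor", "extract_embedding", "extract_embeddings",
    "save_model", "load_model",
]


@dataclasses.dataclass(frozen=True)
class PreprocSpec:
    """Resize + per-image min-max normalization contract.

    Defaults follow the reference recipe: bilinear resize to 331x331 and
    min-max normalization to (-1, 1).  Desk-scale training overrides
    ``target_size`` (the normalization range stays fixed).
    """

    target_size: tuple[int, int] = (331, 331)
    normalize_range: tuple[float, float] = (-1.0, 1.0)


@dataclasses.dataclass(frozen=True)
class HeadSpec:
    """Four fully connected layers ending in the 64-d embedding."""

    layer_widths: tuple[int, ...] = (1024, 512, 128, 64)
    classifier_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.layer_widths) != 4 or self.layer_widths[-1] != 64:
            raise ValueError("head must have exactly four widths ending in 64")
        if self.classifier_classes < 2:
            raise ValueError("classifier needs at least 2 classes")


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    lr_init: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 7
    seed: int = 0
    val_fraction: float = 0.2
    image_size: tuple[int, int] = (64, 64)
    augmentation: dict = dataclasses.field(
        default_factory=lambda: {"crop": True, "rotation": True, "flip": True, "color": True}
    )

    def lr_at(self, epoch: int) -> float:
        """lr(e) = lr_init * decay^floor((e-1)/every), epochs counted from 1."""
        if epoch < 1:
            raise ValueError("epochs are counted from 1")
        return self.lr_init * self.lr_decay_factor ** ((epoch - 1) // self.lr_decay_every)


@dataclasses.dataclass(frozen=True)
class EmbeddingVector:
    values: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        if self.values.shape != (64,):
            raise ValueError(f"embedding must have 64 values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite values")


def preprocess(image, spec: PreprocSpec = PreprocSpec()) -> np.ndarray:
    """Bilinear resize then per-image min-max normalization.

    A constant image maps to the midpoint of the normalization range
    (all zeros for the default (-1, 1)).
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    if pixels.size == 0:
        raise ValueError("cannot preprocess an empty image")
    if pixels.shape != tuple(spec.target_size):
        pixels = resize(pixels, spec.target_size, order=1, anti_aliasing=False)
    lo, hi = pixels.min(), pixels.max()
    a, b = spec.normalize_range
    if hi == lo:
        return np.full(spec.target_size, (a + b) / 2.0)
    return (pixels - lo) / (hi - lo) * (b - a) + a


def _hflip(x: np.ndarray) -> np.ndarray:
    return x[:, ::-1].copy()


def augment(image: np.ndarray, config: TrainConfig, seed: int) -> np.ndarray:
    """Seeded train-time augmentation: crop, rotation, flip, color jitter.

    Random crop keeps 80–100 % of each side (resized back), rotation is
    uniform in +/-15 degrees, horizontal flip fires with p = 0.5, and
    color jitter rescales contrast by +/-10 % and shifts brightness by
    +/-10 % of the value range.  With every toggle off the function is the
    identity.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(image, dtype=float)
    h, w = x.shape
    aug = config.augmentation
    if aug.get("crop", False):
        scale = rng.uniform(0.8, 1.0)
        ch, cw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        x = resize(x[r0:r0 + ch, c0:c0 + cw], (h, w), order=1, anti_aliasing=False)
    if aug.get("rotation", False):
        angle = rng.uniform(-15.0, 15.0)
        x = ndimage.rotate(x, angle, reshape=False, order=1, mode="nearest")
    if aug.get("flip", False):
        if rng.uniform() < 0.5:
            x = _hflip(x)
    if aug.get("color", False):
        contrast = rng.uniform(0.9, 1.1)
        brightness = rng.uniform(-0.1, 0.1) * 2.0  # fraction of the (-1,1) range
        x = x * contrast + brightness
    return x


def build_model(backbone: nn.Backbone, head: HeadSpec, seed: int = 0) -> nn.Model:
    """Assemble backbone + four-layer head + classifier with seeded init."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    prev = backbone.feature_dim
    widths = head.layer_widths
    for wdt in widths[:-1]:
        layers += [nn.Dense(prev, wdt, rng=rng), nn.ReLU()]
        prev = wdt
    # final embedding layer is linear to keep the metric space unsquashed
    layers.append(nn.Dense(prev, widths[-1], rng=rng, relu_gain=False))
    classifier = nn.Dense(widths[-1], head.classifier_classes, rng=rng, relu_gain=False)
    return nn.Model(backbone, layers, classifier, widths)


def _stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train_classifier_stage(
    images: list,
    labels: list[int] | np.ndarray,
    backbone: nn.Backbone | None = None,
    head: HeadSpec = HeadSpec(),
    config: TrainConfig = None,
    model: nn.Model | None = None,
) -> tuple[nn.Model, dict]:
    """Train (or continue training) the classification model on one stage.

    Pass ``backbone``+``head`` to start from scratch (stage B) or an
    existing ``model`` — typically after :func:`~fewtex.embedding.nn.swap_classifier`
    — to continue on a new task (stage C).  Minimizes softmax
    cross-entropy with Adam under the step learning-rate schedule; stops
    early when validation loss fails to improve for ``patience`` epochs
    and restores the best-validation weights.

    Returns ``(model, history)`` with per-epoch ``lr``, ``train_loss``
    and ``val_loss``.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if model is None:
        if backbone is None:
            raise ValueError("provide either a backbone+head or an existing model")
        model = build_model(backbone, head, seed=config.seed)
    n_classes = model.classifier.w.shape[1]
    if labels.max() >= n_classes:
        raise ValueError(f"label {labels.max()} out of range for {n_classes}-way classifier")

    spec = PreprocSpec(target_size=config.image_size)
    base = np.stack([preprocess(img, spec) for img in images])

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(labels, config.val_fraction, rng)
    x_val = base[val_idx][:, None, :, :]
    y_val = labels[val_idx]

    opt = nn.Adam(model.parameters(), lr=config.lr_init)
    history = {"lr": [], "train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    stale = 0
    aug_seed_root = np.random.SeedSequence([config.seed, 7919])

    for epoch in range(1, config.max_epochs + 1):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(train_idx)
        epoch_losses = []
        aug_rng_seed = int(aug_seed_root.generate_state(epoch)[-1] % (2**31))
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            xb = np.stack([
                augment(base[i], config, seed=(aug_rng_seed + int(i)) % (2**31))
                for i in batch_idx
            ])[:, None, :, :]
            yb = labels[batch_idx]
            logits = model.forward_logits(xb)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (lr={opt.lr:g}); aborting"
                )
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        val_loss, _ = nn.softmax_cross_entropy(model.forward_logits(x_val), y_val)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [getattr(p["layer"], p["name"]).copy() for p in model.parameters()]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_weights is not None:
        for p, wgt in zip(model.parameters(), best_weights):
            setattr(p["layer"], p["name"], wgt)
    return model, history


class Extractor:
    """Truncated model exposing the 64-d embedding layer."""

    def __init__(self, model: nn.Model, preproc: PreprocSpec):
        if model.embedding_dim != 64:
            raise ValueError(f"model's final head layer has {model.embedding_dim} units, need 64")
        self.model = model
        self.preproc = preproc

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        return self.model.forward_features(batch)


def truncate_to_extractor(model: nn.Model, image_size: tuple[int, int] = (64, 64)) -> Extractor:
    """Drop the classifier; the 64-unit activation becomes the embedding."""
    return Extractor(model, PreprocSpec(target_size=image_size))


def extract_embedding(extractor: Extractor, image) -> EmbeddingVector:
    """Deterministic inference-mode embedding of one image (no augmentation)."""
    x = preprocess(image, extractor.preproc)[None, None, :, :]
    values = extractor(x)[0]
    return EmbeddingVector(values=values, sample_id=getattr(image, "sample_id", ""))


def extract_embeddings(extractor: Extractor, images: list, batch_size: int = 32) -> np.ndarray:
    """Batched embedding extraction; row order follows the input order."""
    out = []
    for start in range(0, len(images), batch_size):
        xb = np.stack([
            preprocess(img, extractor.preproc) for img in images[start:start + batch_size]
        ])[:, None, :, :]
        out.append(extractor(xb))
    return np.concatenate(out, axis=0)


def save_model(model: nn.Model, path: str | Path, image_size: tuple[int, int]) -> None:
    """Serialize weights + architecture metadata to an .npz checkpoint."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"p{i:03d}"] = getattr(p["layer"], p["name"])
    channels = [layer.out_ch for layer in model.backbone.layers if isinstance(layer, nn.Conv2d)]
    meta = {
        "channels": channels,
        "head_widths": list(model.head_widths),
        "n_classes": int(model.classifier.w.shape[1]),
        "image_size": list(image_size),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> tuple[nn.Model, tuple[int, int]]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    backbone = nn.TinyConvBackbone(seed=0, channels=tuple(meta["channels"]))
    head = HeadSpec(layer_widths=tuple(meta["head_widths"]), classifier_classes=meta["n_classes"])
    model = build_model(backbone, head, seed=0)
    for i, p in enumerate(model.parameters()):
        setattr(p["layer"], p["name"], data[f"p{i:03d}"])
    return model, tuple(meta["image_size"])
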