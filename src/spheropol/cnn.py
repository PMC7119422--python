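"""Convolutional-network classification of RGB equatorial projections.

Spheroid projections reduced to 8-bit RGB (basolateral green, nuclei blue,
apical marker or actin red) are classified at fine granularity (regular,
inverse, aggregate, multilumen) by a small convolutional network.  Training
follows the reference schedule: stochastic gradient descent with momentum
(SGDM, momentum 0.9), learning rate 3e-3, batch size 80, 15 epochs, with an
internal stratified hold-out tracking accuracy per epoch.  Class imbalance
is handled by augmentation — random rotation (45-315 degrees) and scaling
(0.4-1.2) of the originals until every label reaches the target count
(600 by default).

The backbone is a compact three-stage convnet (~40k parameters) written in
numpy (im2col convolutions with full backpropagation), so training is
deterministic for a fixed seed and runs on one CPU; the classification head
can be retrained alone (``fine_tune="head"``) or together with the
convolutional stages (default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import ProjectiveTransform, resize, warp

from .types import FINE_LABELS, PolarityLabel, RGBImage


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CNNTrainingConfig:
    """Training schedule of the network head (reference defaults)."""

    epochs: int = 15
    batch_size: int = 80
    learning_rate: float = 3e-3
    momentum: float = 0.9
    input_size: Tuple[int, int] = (96, 96)
    label_set: Tuple[str, ...] = FINE_LABELS
    seed: int = 0
    fine_tune: str = "all"  # "all" trains every layer, "head" only the dense head

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.fine_tune not in ("all", "head"):
            raise ValueError("fine_tune must be 'all' or 'head'")


@dataclass(frozen=True)
class AugmentationConfig:
    """Rotation/scaling augmentation used to balance the label classes."""

    rotation_range_deg: Tuple[float, float] = (45.0, 315.0)
    scale_range: Tuple[float, float] = (0.4, 1.2)
    target_per_label: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_range_deg[0] > self.rotation_range_deg[1]:
            raise ValueError("rotation range must be well ordered")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ValueError("scale range must be well ordered and positive")
        if self.target_per_label < 1:
            raise ValueError("target_per_label must be >= 1")


# --------------------------------------------------------------------------
# augmentation


def _rotate_scale(pixels: np.ndarray, angle_deg: float, scale: float) -> np.ndarray:
    """Rotate and scale an (H, W, 3) uint8 image about its centre."""
    if angle_deg == 0.0 and scale == 1.0:
        return pixels.copy()
    h, w = pixels.shape[:2]
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    a = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    sc = np.diag([scale, scale, 1.0])
    t_in = np.array([[1, 0, -c[0]], [0, 1, -c[1]], [0, 0, 1.0]])
    t_out = np.array([[1, 0, c[0]], [0, 1, c[1]], [0, 0, 1.0]])
    m = t_out @ rot @ sc @ t_in
    out = warp(
        pixels.astype(float),
        ProjectiveTransform(matrix=np.linalg.inv(m)),
        order=1,
        preserve_range=True,
        output_shape=pixels.shape,
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def augment(
    images: Sequence[RGBImage], cfg: AugmentationConfig = AugmentationConfig()
) -> List[RGBImage]:
    """Balance every label to exactly ``target_per_label`` images.

    Originals are retained (classes larger than the target are seeded
    subsamples); the remainder are rotated/scaled copies of randomly chosen
    originals with transforms drawn uniformly from the configured ranges.
    """
    by_label: Dict[str, List[RGBImage]] = {}
    for img in images:
        if img.label is None:
            raise ValueError("augment needs labelled images")
        by_label.setdefault(img.label.fine_label, []).append(img)
    for label, group in by_label.items():
        if not group:
            raise ValueError(f"empty label class {label!r}")

    rng = np.random.default_rng(cfg.seed)
    out: List[RGBImage] = []
    for label in sorted(by_label):
        group = by_label[label]
        if len(group) >= cfg.target_per_label:
            idx = rng.choice(len(group), size=cfg.target_per_label, replace=False)
            out.extend(group[i] for i in sorted(idx))
            continue
        out.extend(group)
        for j in range(cfg.target_per_label - len(group)):
            src = group[int(rng.integers(len(group)))]
            angle = float(rng.uniform(*cfg.rotation_range_deg))
            scale = float(rng.uniform(*cfg.scale_range))
            out.append(
                RGBImage(
                    pixels=_rotate_scale(src.pixels, angle, scale),
                    label=src.label,
                    image_id=f"{src.image_id}_aug{j}",
                )
            )
    return out


# --------------------------------------------------------------------------
# numpy layers (NHWC)


class _Layer:
    trainable = False
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv3x3(_Layer):
    """3x3 same-padding convolution via im2col."""

    trainable = True

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))  # He initialisation
        self.w = rng.normal(0.0, scale, size=(9 * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in = c_in

    def _cols(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        win = np.moveaxis(win, 3, 5)  # (N,H,W,3,3,C)
        return win.reshape(x.shape[0], x.shape[1], x.shape[2], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        cols = self._cols(x)
        self.cols = cols.reshape(-1, cols.shape[-1])
        out = self.cols @ self.w + self.b
        n, h, w, _ = x.shape
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = self.x_shape
        dflat = dout.reshape(-1, dout.shape[-1])
        self.grads[0][...] = self.cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.w.T).reshape(n, h, w, 3, 3, self.c_in)
        dxp = np.zeros((n, h + 2, w + 2, self.c_in), dtype=dout.dtype)
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class _ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _MaxPool2(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        # ties share the gradient equally
        mask = r == out[:, :, None, :, None, :]
        self.mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self.x_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        d = dout[:, :, None, :, None, :] * self.mask
        return d.reshape(n, h, w, c)


class _Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self.x_shape)


class _Dense(_Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _ConvNet:
    """Backbone (conv stages) plus dense classification head."""

    def __init__(self, input_size: Tuple[int, int], n_classes: int, seed: int):
        rng = np.random.default_rng(seed)
        h, w = input_size
        if h % 8 or w % 8 or h < 16 or w < 16:
            raise ValueError("input size must be a multiple of 8 and >= 16")
        self.backbone: List[_Layer] = [
            _Conv3x3(3, 8, rng),
            _ReLU(),
            _MaxPool2(),
            _Conv3x3(8, 16, rng),
            _ReLU(),
            _MaxPool2(),
            _Conv3x3(16, 32, rng),
            _ReLU(),
            _MaxPool2(),
        ]
        feat = (h // 8) * (w // 8) * 32
        self.head: List[_Layer] = [
            _Flatten(),
            _Dense(feat, 64, rng),
            _ReLU(),
            _Dense(64, n_classes, rng),
        ]
        self.n_classes = n_classes
        self.input_size = input_size

    @property
    def layers(self) -> List[_Layer]:
        return self.backbone + self.head

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray, depth: str = "all") -> None:
        layers = self.layers if depth == "all" else self.head
        d = dlogits
        for layer in reversed(layers):
            d = layer.backward(d)

    def trainable_layers(self, depth: str) -> List[_Layer]:
        pool = self.layers if depth == "all" else self.head
        return [l for l in pool if l.trainable]

    def state(self) -> List[np.ndarray]:
        return [p for l in self.layers if l.trainable for p in l.params]


class _SGDM:
    """Stochastic gradient descent with momentum (velocity form)."""

    def __init__(self, layers: List[_Layer], lr: float, momentum: float):
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for l in layers for p in l.params]

    def step(self) -> None:
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                v = self.velocity[i]
                v *= self.momentum
                v -= self.lr * g
                p += v
                i += 1


# --------------------------------------------------------------------------
# training and prediction


@dataclass
class CNNModel:
    """A trained network with its label set and training history."""

    net: _ConvNet
    classes: Tuple[str, ...]
    config: CNNTrainingConfig
    history: List[Dict[str, float]] = field(default_factory=list)

    def save(self, path_prefix) -> None:
        """Write weights (.npz) plus a JSON sidecar with the configuration."""
        weights = {f"w{i}": p for i, p in enumerate(self.net.state())}
        np.savez(f"{path_prefix}.npz", **weights)
        sidecar = {
            "classes": list(self.classes),
            "input_size": list(self.config.input_size),
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "learning_rate": self.config.learning_rate,
            "momentum": self.config.momentum,
            "seed": self.config.seed,
            "fine_tune": self.config.fine_tune,
            "history": self.history,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path_prefix) -> "CNNModel":
        with open(f"{path_prefix}.json") as fh:
            side = json.load(fh)
        cfg = CNNTrainingConfig(
            epochs=side["epochs"],
            batch_size=side["batch_size"],
            learning_rate=side["learning_rate"],
            momentum=side["momentum"],
            input_size=tuple(side["input_size"]),
            label_set=tuple(side["classes"]),
            seed=side["seed"],
            fine_tune=side["fine_tune"],
        )
        net = _ConvNet(cfg.input_size, len(side["classes"]), seed=cfg.seed)
        data = np.load(f"{path_prefix}.npz")
        for i, p in enumerate(net.state()):
            p[...] = data[f"w{i}"]
        return cls(net=net, classes=tuple(side["classes"]), config=cfg, history=side["history"])


def _prepare(images: Sequence[RGBImage], input_size: Tuple[int, int]) -> np.ndarray:
    """Stack images as float NHWC in [-0.5, 0.5], resized to the input size."""
    out = np.empty((len(images), *input_size, 3), dtype=np.float32)
    for i, img in enumerate(images):
        px = img.pixels.astype(float) / 255.0
        if px.shape[:2] != input_size:
            px = resize(px, input_size, order=1, anti_aliasing=True, preserve_range=True)
        out[i] = px - 0.5
    return out


def _stratified_split(
    labels: Sequence[str], holdout_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_val = max(1, int(round(holdout_fraction * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def retrain(
    images: Sequence[RGBImage],
    cfg: CNNTrainingConfig = CNNTrainingConfig(),
    holdout_fraction: float = 0.2,
    backbone: Optional[_ConvNet] = None,
) -> CNNModel:
    """Train the network on labelled RGB images.

    A stratified ``holdout_fraction`` of the images forms the internal
    validation set; the history records the mean training cross-entropy and
    the validation accuracy of every epoch.  Passing an existing
    ``backbone`` (e.g. from a previous training run) with
    ``cfg.fine_tune="head"`` retrains only the replaced dense head —
    the transfer-learning mode.
    """
    labels = []
    for img in images:
        if img.label is None:
            raise ValueError("training images must be labelled")
        labels.append(img.label.fine_label)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    missing = [c for c in cfg.label_set if c not in classes]
    if missing:
        raise ValueError(f"classes with zero training images: {missing}")

    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[l] for l in labels])
    x = _prepare(images, cfg.input_size)

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_split(labels, holdout_fraction, rng)
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_va, y_va = x[val_idx], y[val_idx]

    net = backbone or _ConvNet(cfg.input_size, len(classes), seed=cfg.seed)
    if backbone is not None and net.n_classes != len(classes):
        raise ValueError("backbone head does not match the number of classes")
    opt = _SGDM(net.trainable_layers(cfg.fine_tune), cfg.learning_rate, cfg.momentum)

    batch = min(cfg.batch_size, len(x_tr))
    model = CNNModel(net=net, classes=classes, config=cfg)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(perm), batch):
            sel = perm[start : start + batch]
            logits = net.forward(x_tr[sel])
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(float(-np.mean(np.log(probs[np.arange(len(sel)), y_tr[sel]] + eps))))
            dlogits = probs.copy()
            dlogits[np.arange(len(sel)), y_tr[sel]] -= 1.0
            dlogits /= len(sel)
            net.backward(dlogits, depth=cfg.fine_tune)
            opt.step()
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if len(x_va):
            val_pred = np.argmax(net.forward(x_va), axis=1)
            entry["val_accuracy"] = float(np.mean(val_pred == y_va))
        model.history.append(entry)
    return model


def predict_cnn(
    model: CNNModel, images: Sequence[RGBImage]
) -> Tuple[List[PolarityLabel], np.ndarray]:
    """Predict fine labels and class probabilities for a batch of images.

    Returns ``(labels, probabilities)`` where probabilities has one row per
    image in the order of ``model.classes`` and rows sum to 1; coarse
    groups follow from ``PolarityLabel.coarse_label``.
    """
    x = _prepare(images, model.config.input_size)
    probs_parts = []
    for start in range(0, len(x), 256):  # bounded memory
        probs_parts.append(_softmax(model.net.forward(x[start : start + 256])))
    probs = (
        np.concatenate(probs_parts, axis=0)
        if probs_parts
        else np.empty((0, len(model.classes)))
    )
    labels = [PolarityLabel(model.classes[i]) for i in np.argmax(probs, axis=1)]
    return labels, probs


def coarse_accuracy(
    model: CNNModel, images: Sequence[RGBImage], true_labels: Sequence[PolarityLabel]
) -> float:
    """Accuracy after collapsing fine labels to coarse polarity groups."""
    pred, _ = predict_cnn(model, images)
    agree = [
        p.coarse_label == t.coarse_label for p, t in zip(pred, true_labels)
    ]
    return float(np.mean(agree))
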