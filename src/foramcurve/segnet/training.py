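"""Patch-based training protocol for the 3D U-Net.

The protocol mirrors common volumetric-segmentation practice: volumes are
optionally cropped to their foreground bounding box and rescaled to a common
grid, cut into overlapping patches on a regular stride (the final window of
each axis snapped to the boundary so every voxel is covered), and the network
is optimised by mini-batch SGD on voxel-wise cross-entropy.  After every
epoch the whole-volume validation Dice (foreground labels) is recorded;
training stops when it has not improved within the patience window, and the
weights of the best epoch are returned.  Replicate trainings use distinct
derived seeds and the replicate with the median best validation Dice is
selected for downstream evaluation.

Everything is deterministic given the config seed (pure NumPy backend).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ..errors import (
    EvaluationError,
    GeometryError,
    SpecificationError,
    TrainingError,
)
from ..metrics import dice
from ..stackio import VolumePair
from .layers import SGD, softmax_cross_entropy
from .unet import UNet3D


@dataclass
class TrainConfig:
    """All training hyperparameters.

    Defaults are the full-scale reference protocol (64³ patches rescaled to
    a 256³ grid, stride 32, batch 24, SGD lr 0.01 / decay 1e-6 / momentum
    0.9 with Nesterov, patience 25 within a 200-epoch cap, 3 replicates).
    Use :meth:`desk_scale` for a configuration that trains in seconds on one
    CPU core.
    """

    patch_size_vox: tuple[int, int, int] = (64, 64, 64)
    target_scale_vox: tuple[int, int, int] | None = (256, 256, 256)
    stride_vox: int = 32
    batch_size: int = 24
    learning_rate: float = 0.01
    decay: float = 1e-6
    momentum: float = 0.9
    nesterov: bool = True
    patience_epochs: int = 25
    max_epochs: int = 200
    n_replicates: int = 3
    crop_to_foreground: bool = False
    class_weighting: bool = False
    #: cap on gradient steps per epoch (patches are subsampled); None means
    #: every epoch iterates over all patches exactly once
    steps_per_epoch: int | None = None
    seed: int = 0
    # architecture scale (width/depth are config choices, not protocol)
    base_channels: int = 8
    n_levels: int = 3
    n_classes: int = 3

    def __post_init__(self) -> None:
        self.patch_size_vox = tuple(int(v) for v in self.patch_size_vox)
        if self.target_scale_vox is not None:
            self.target_scale_vox = tuple(int(v) for v in self.target_scale_vox)
        if self.stride_vox > min(self.patch_size_vox):
            raise SpecificationError(
                f"stride_vox {self.stride_vox} must be <= min(patch_size_vox) "
                f"{min(self.patch_size_vox)}"
            )
        if self.patience_epochs > self.max_epochs:
            raise SpecificationError("patience_epochs must be <= max_epochs")
        positive = {
            "stride_vox": self.stride_vox,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "patience_epochs": self.patience_epochs,
            "max_epochs": self.max_epochs,
            "n_replicates": self.n_replicates,
            "base_channels": self.base_channels,
            "n_levels": self.n_levels,
        }
        for name, value in positive.items():
            if value <= 0:
                raise SpecificationError(f"{name} must be positive, got {value}")
        if self.decay < 0:
            raise SpecificationError("decay must be >= 0")
        div = 2 ** (self.n_levels - 1)
        if any(p % div for p in self.patch_size_vox):
            raise SpecificationError(
                f"patch_size_vox {self.patch_size_vox} must be divisible by "
                f"2**(n_levels-1) = {div}"
            )

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Tiny-CPU configuration: 16³ patches on the native grid, stride 8,
        batch 8, a 2-level 4-channel net, class-weighted loss, foreground
        cropping, 4 subsampled steps per epoch, patience 25 within 150
        epochs."""
        values = dict(
            patch_size_vox=(16, 16, 16),
            target_scale_vox=None,
            stride_vox=8,
            batch_size=8,
            learning_rate=0.01,
            momentum=0.95,
            patience_epochs=25,
            max_epochs=150,
            base_channels=4,
            n_levels=2,
            crop_to_foreground=True,
            class_weighting=True,
            steps_per_epoch=4,
        )
        values.update(overrides)
        return cls(**values)


@dataclass
class TrainedModel:
    """Network weights plus the training record needed downstream."""

    weights: list[np.ndarray]
    arch: dict
    history: list[float]
    best_epoch: int  #: 1-based epoch of the first maximum of history
    best_val_dice: float
    config: TrainConfig
    training_set_id: str = ""

    def network(self) -> UNet3D:
        net = UNet3D(**self.arch, seed=0)
        net.set_weights(self.weights)
        return net


# ---------------------------------------------------------------------------
# preprocessing and patch geometry
# ---------------------------------------------------------------------------

def _normalise(grey: np.ndarray) -> np.ndarray:
    """Fixed 16-bit intensity scaling to [-1, 1].

    A fixed map (rather than per-volume standardisation) keeps training and
    inference consistent when foreground cropping changes the intensity
    distribution seen at training time."""
    return (np.asarray(grey, dtype=np.float32) / 32767.5) - 1.0


def _foreground_bbox(labels: np.ndarray, min_size: tuple[int, int, int]) -> tuple:
    """Bounding-box slices of non-background voxels, grown to ``min_size``."""
    fg = np.argwhere(labels != 0)
    if fg.size == 0:
        return tuple(slice(0, s) for s in labels.shape)
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1
    slices = []
    for axis in range(3):
        need = min_size[axis] - (hi[axis] - lo[axis])
        if need > 0:
            lo[axis] = max(0, lo[axis] - need // 2)
            hi[axis] = min(labels.shape[axis], lo[axis] + min_size[axis])
            lo[axis] = max(0, hi[axis] - min_size[axis])
        slices.append(slice(int(lo[axis]), int(hi[axis])))
    return tuple(slices)


def _rescale(volume: np.ndarray, target: tuple[int, int, int], order: int) -> np.ndarray:
    if tuple(volume.shape) == tuple(target):
        return volume
    zoom = [t / s for t, s in zip(target, volume.shape)]
    out = ndimage.zoom(volume, zoom, order=order, mode="nearest", grid_mode=True)
    # zoom can be off by one voxel on awkward ratios; snap exactly
    if tuple(out.shape) != tuple(target):
        out = out[tuple(slice(0, t) for t in target)]
        pad = [(0, t - s) for t, s in zip(target, out.shape)]
        out = np.pad(out, pad, mode="edge")
    return out


def patch_origins(size: int, patch: int, stride: int) -> list[int]:
    """Window origins covering ``[0, size)``: regular stride with the final
    window snapped to the boundary."""
    if size < patch:
        raise GeometryError(f"axis of size {size} is smaller than patch {patch}")
    origins = list(range(0, size - patch + 1, stride))
    if origins[-1] != size - patch:
        origins.append(size - patch)
    return origins


def _prepare(pair: VolumePair, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    grey, labels = pair.grey, pair.labels
    if cfg.crop_to_foreground:
        box = _foreground_bbox(labels, cfg.patch_size_vox)
        grey, labels = grey[box], labels[box]
    if cfg.target_scale_vox is not None:
        grey = _rescale(np.asarray(grey, dtype=np.float32), cfg.target_scale_vox, 1)
        labels = _rescale(labels, cfg.target_scale_vox, 0)
    return _normalise(grey), np.asarray(labels, dtype=np.int64)


def extract_patches(
    pair: VolumePair, cfg: TrainConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sliding-window (grey, label) patches after crop/rescale preprocessing.

    Grey patches are normalised float32; the patch grid covers every voxel at
    least once.  Raises :class:`GeometryError` if the prepared volume is
    smaller than a patch in any axis.
    """
    grey, labels = _prepare(pair, cfg)
    p = cfg.patch_size_vox
    out = []
    for z in patch_origins(grey.shape[0], p[0], cfg.stride_vox):
        for y in patch_origins(grey.shape[1], p[1], cfg.stride_vox):
            for x in patch_origins(grey.shape[2], p[2], cfg.stride_vox):
                sl = (slice(z, z + p[0]), slice(y, y + p[1]), slice(x, x + p[2]))
                out.append((grey[sl], labels[sl]))
    return out


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _predict_prepared(net: UNet3D, grey: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Stitched argmax prediction on an already normalised grid."""
    p = cfg.patch_size_vox
    scores = np.zeros((cfg.n_classes,) + grey.shape, dtype=np.float32)
    coords = [
        (z, y, x)
        for z in patch_origins(grey.shape[0], p[0], cfg.stride_vox)
        for y in patch_origins(grey.shape[1], p[1], cfg.stride_vox)
        for x in patch_origins(grey.shape[2], p[2], cfg.stride_vox)
    ]
    for start in range(0, len(coords), cfg.batch_size):
        chunk = coords[start : start + cfg.batch_size]
        batch = np.stack(
            [
                grey[z : z + p[0], y : y + p[1], x : x + p[2]][None]
                for z, y, x in chunk
            ]
        ).astype(np.float32)
        logits = net.forward(batch)
        z0 = logits - logits.max(axis=1, keepdims=True)
        prob = np.exp(z0)
        prob /= prob.sum(axis=1, keepdims=True)
        for (z, y, x), pr in zip(chunk, prob):
            scores[:, z : z + p[0], y : y + p[1], x : x + p[2]] += pr
    return scores.argmax(axis=0).astype(np.uint8)


def predict(model: TrainedModel, grey: np.ndarray) -> np.ndarray:
    """Patchwise stitched inference on a raw greyscale grid.

    Overlapping patch scores are accumulated and the per-voxel argmax taken;
    output uses the standard label convention and matches the input shape.
    Note the stitched prediction is orientation-consistent only in
    expectation, not exactly.
    """
    cfg = model.config
    grey = np.asarray(grey)
    if grey.ndim != 3:
        raise GeometryError("predict expects a 3D grid")
    original_shape = grey.shape
    if cfg.target_scale_vox is not None:
        grey = _rescale(np.asarray(grey, dtype=np.float32), cfg.target_scale_vox, 1)
    for s, p in zip(grey.shape, cfg.patch_size_vox):
        if s < p:
            raise GeometryError(
                f"grid shape {original_shape} smaller than patch {cfg.patch_size_vox}"
            )
    labels = _predict_prepared(model.network(), _normalise(grey), cfg)
    if labels.shape != original_shape:
        labels = _rescale(labels, original_shape, 0)
    return labels


def _validation_dice(net: UNet3D, val_pairs: list[VolumePair], cfg: TrainConfig) -> float:
    scores = []
    for pair in val_pairs:
        grey = np.asarray(pair.grey, dtype=np.float32)
        if cfg.target_scale_vox is not None:
            grey = _rescale(grey, cfg.target_scale_vox, 1)
        pred = _predict_prepared(net, _normalise(grey), cfg)
        if pred.shape != pair.labels.shape:
            pred = _rescale(pred, pair.labels.shape, 0)
        scores.append(dice(pred, pair.labels))
    return float(np.mean(scores))


def train(
    train_pairs: list[VolumePair],
    val_pairs: list[VolumePair],
    cfg: TrainConfig,
    training_set_id: str = "",
) -> TrainedModel:
    """Train one network with early stopping on whole-volume validation Dice.

    Per-epoch validation Dice is appended to ``history``; training stops at
    ``max_epochs`` or once ``patience_epochs`` epochs have passed without
    improvement, and the weights of the best (first-maximum) epoch are
    returned.  Deterministic given ``cfg.seed``.
    """
    if not train_pairs:
        raise SpecificationError("training set is empty")
    if not val_pairs:
        raise SpecificationError("validation set is empty")
    if all(int(np.count_nonzero(p.labels)) == 0 for p in val_pairs):
        raise EvaluationError(
            "validation Dice undefined: no validation pair has foreground"
        )

    rng = np.random.default_rng(cfg.seed)
    net = UNet3D(
        in_channels=1,
        n_classes=cfg.n_classes,
        base_channels=cfg.base_channels,
        n_levels=cfg.n_levels,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    optimiser = SGD(
        net.params(),
        lr=cfg.learning_rate,
        momentum=cfg.momentum,
        decay=cfg.decay,
        nesterov=cfg.nesterov,
    )

    patches = [pt for pair in train_pairs for pt in extract_patches(pair, cfg)]
    X = np.stack([g[None] for g, _ in patches]).astype(np.float32)
    Y = np.stack([l for _, l in patches])
    class_weights = None
    if cfg.class_weighting:
        counts = np.bincount(Y.ravel(), minlength=cfg.n_classes).astype(np.float64)
        counts = np.maximum(counts, 1.0)
        class_weights = (Y.size / (cfg.n_classes * counts)).astype(np.float32)

    history: list[float] = []
    best_dice = -np.inf
    best_epoch = 0
    best_weights = net.get_weights()
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(patches))
        if cfg.steps_per_epoch is not None:
            order = order[: cfg.steps_per_epoch * cfg.batch_size]
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(X[idx])
            _, dlogits = softmax_cross_entropy(logits, Y[idx], class_weights)
            net.backward(dlogits)
            optimiser.step(net.grads())
        val = _validation_dice(net, val_pairs, cfg)
        history.append(val)
        if val > best_dice:
            best_dice = val
            best_epoch = epoch
            best_weights = net.get_weights()
        if epoch - best_epoch >= cfg.patience_epochs:
            break

    return TrainedModel(
        weights=best_weights,
        arch=net.arch,
        history=history,
        best_epoch=best_epoch,
        best_val_dice=float(best_dice),
        config=cfg,
        training_set_id=training_set_id,
    )


def train_replicates(
    train_pairs: list[VolumePair],
    val_pairs: list[VolumePair],
    cfg: TrainConfig,
    training_set_id: str = "",
) -> tuple[list[TrainedModel], TrainedModel]:
    """Train ``cfg.n_replicates`` networks with distinct derived seeds and
    select the one with the median best validation Dice.

    For even replicate counts the lower-middle model is selected; exact ties
    resolve by stable index order.
    """
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_replicates)
    models: list[TrainedModel] = []
    errors: list[Exception] = []
    for rep, seed in enumerate(seeds):
        rep_cfg = replace(cfg, seed=int(seed) % 2**31)
        try:
            models.append(
                train(train_pairs, val_pairs, rep_cfg, training_set_id=training_set_id)
            )
        except (SpecificationError, EvaluationError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(exc)
    if not models:
        raise TrainingError(f"all {cfg.n_replicates} replicates failed: {errors}")
    order = np.argsort([m.best_val_dice for m in models], kind="stable")
    median_model = models[int(order[(len(models) - 1) // 2])]
    return models, median_model
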