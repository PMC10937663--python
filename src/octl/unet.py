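"""U-Net segmentation of transparent vessels in OCT B-scans.

The learned segmenter is a symmetric encoder/decoder ("U") network: a
contracting path of paired 3x3 convolutions and 2x2 max pooling steps that
doubles the channel width while halving resolution, and an expansive path
of 2x2 transposed convolutions and paired 3x3 convolutions that restores
resolution, with skip connections concatenating each encoder feature map
into the decoder stage of the same resolution.  A final 1x1 convolution
maps to two classes (vessel / non-vessel); a pixel belongs to exactly one
class via the argmax.

With the default widths (32, 64, 128, 256) the deepest feature map carries
256 channels at 1/16 of the input resolution, so input B-scans must have
height and width divisible by 16 (prediction pads and un-pads
automatically).  Inputs are 8-bit grayscale B-scans scaled to [0, 1];
training minimizes the Dice loss of the softmax foreground probability
with the Adam optimizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .nn import Adam, Conv2d, MaxPool2, Param, ReLU, UpConv2
from .volume import OCTVolume, VesselMask

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "TrainHistory",
    "UNet",
    "build_unet",
    "to_uint8",
    "volume_vmax",
    "dice_loss",
    "split_dataset",
    "train",
    "predict",
    "bscans_from_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class UNetSpec:
    """Architecture description.

    ``widths`` are the encoder channel counts per resolution level; they
    must double level to level.  The deepest (bottleneck) feature keeps the
    last width at 1/16 resolution.
    """

    in_channels: int = 1
    n_classes: int = 2
    widths: tuple[int, ...] = (32, 64, 128, 256)
    kernel: int = 3

    def __post_init__(self) -> None:
        w = tuple(self.widths)
        if len(w) != 4 or any(w[i + 1] != 2 * w[i] for i in range(len(w) - 1)):
            raise ValueError("widths must be four channel counts doubling per level")
        if self.n_classes != 2:
            raise ValueError("the segmenter is binary: n_classes must be 2")
        self.widths = w

    @property
    def divisor(self) -> int:
        return 2 ** len(self.widths)      # four poolings -> /16


@dataclass
class TrainConfig:
    """Training protocol: Adam, Dice loss, no augmentation."""

    lr: float = 1e-4
    epochs: int = 150
    batch_size: int = 4
    split: tuple[float, float, float] = (0.5, 0.25, 0.25)
    seed: int = 0
    dice_eps: float = 1.0
    augment: bool = False
    stop_train_loss: Optional[float] = None   # early stop once reached
    stop_train_iou: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.augment:
            raise ValueError("augmentation is not part of the training protocol")


@dataclass
class TrainHistory:
    """Per-epoch Dice loss and mean-IOU accuracy for train/validation."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class UNet:
    """The network: explicit forward/backward over the layer graph."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.widths
        k = spec.kernel
        self.enc: list[list] = []
        in_ch = spec.in_channels
        for width in w:
            self.enc.append(
                [Conv2d(in_ch, width, k, rng), ReLU(), Conv2d(width, width, k, rng), ReLU()]
            )
            in_ch = width
        self.pools = [MaxPool2() for _ in w]
        deep = w[-1]
        self.bottleneck = [Conv2d(deep, deep, k, rng), ReLU(), Conv2d(deep, deep, k, rng), ReLU()]
        self.ups: list[UpConv2] = []
        self.dec: list[list] = []
        prev = deep
        for width in reversed(w):
            self.ups.append(UpConv2(prev, width, rng))
            self.dec.append(
                [Conv2d(2 * width, width, k, rng), ReLU(), Conv2d(width, width, k, rng), ReLU()]
            )
            prev = width
        self.final = Conv2d(w[0], spec.n_classes, 1, rng)

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for block in self.enc + [self.bottleneck] + self.dec:
            for layer in block:
                params.extend(layer.params)
        for up in self.ups:
            params.extend(up.params)
        params.extend(self.final.params)
        return params

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    @staticmethod
    def _run(block: list, x: np.ndarray) -> np.ndarray:
        for layer in block:
            x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(block: list, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class scores for a batch of (N, 1, H, W) inputs."""
        x = np.asarray(x, dtype=np.float32)
        h, w = x.shape[2:]
        d = self.spec.divisor
        if h % d or w % d:
            raise ValueError(
                f"input {h}x{w} not divisible by {d}; pad the B-scans first"
            )
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = self._run(block, x)
            skips.append(x)
            x = pool.forward(x)
        x = self._run(self.bottleneck, x)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run(block, x)
        return self.final.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips = []
        for up, block, ch in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)
        ):
            d = self._run_back(block, d)
            dskip, dup = d[:, :ch], d[:, ch:]
            dskips.append(dskip)
            d = up.backward(dup)
        d = self._run_back(self.bottleneck, d)
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = self._run_back(block, d)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct a U-Net from its architecture spec."""
    return UNet(spec or UNetSpec(), seed=seed)


def volume_vmax(vol: OCTVolume | np.ndarray) -> float:
    """Per-volume display ceiling: the 99.9th percentile in dB."""
    data = vol.data if isinstance(vol, OCTVolume) else np.asarray(vol)
    return float(np.percentile(data, 99.9))


def to_uint8(image: np.ndarray, vmax: float) -> np.ndarray:
    """Map [0, vmax] dB linearly to [0, 255] 8-bit gray.

    Negative values clip to 0 and values above ``vmax`` to 255; rounding is
    round-half-to-even (numpy's rint), so ``vmax/2`` maps to 128 for the
    default scale.  A constant image maps to all zeros with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if vmax <= 0 or np.ptp(image) == 0:
        warnings.warn("constant image; 8-bit conversion is all zeros")
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = np.clip(image / vmax, 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8)


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Dice loss ``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``.

    ``pred`` holds foreground probabilities in [0, 1]; ``target`` is
    binary.  Sums run over the whole array (batch-global), and ``eps = 1``
    keeps the loss defined when both are empty.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def _dice_grad(pred: np.ndarray, target: np.ndarray, eps: float) -> np.ndarray:
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum() + eps
    return -(2.0 * target * denom - (2.0 * inter + eps)) / denom**2


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_dice(
    logits: np.ndarray, target: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Dice loss of the softmax foreground channel, plus d(loss)/d(logits)."""
    probs = _softmax(logits.astype(np.float64))
    p1 = probs[:, 1]
    loss = dice_loss(p1, target, eps)
    dp1 = _dice_grad(p1, target, eps)
    dz1 = dp1 * p1 * (1.0 - p1)
    dlogits = np.stack([-dz1, dz1], axis=1).astype(np.float32)
    return loss, dlogits, probs


def split_dataset(
    n: int, fractions: tuple[float, float, float] = (0.5, 0.25, 0.25), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/validation/test index split.

    Group sizes are ``round(n * fraction)`` with the last group absorbing
    the rounding remainder; the permutation is deterministic per seed.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    sizes = [int(round(n * f)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    if min(sizes) < 0:
        raise ValueError("degenerate split sizes")
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return perm[:a], perm[a:b], perm[b:]


def _mean_iou(pred_masks: np.ndarray, targets: np.ndarray) -> float:
    """Mean per-image IOU (empty/empty pairs count as 1)."""
    ious = []
    for p, t in zip(pred_masks, targets):
        union = np.logical_or(p, t).sum()
        if union == 0:
            ious.append(1.0)
        else:
            ious.append(np.logical_and(p, t).sum() / union)
    return float(np.mean(ious))


def _prep_inputs(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W) B-scans -> float32 (N, 1, H, W) in [0, 1]."""
    x = np.asarray(images)
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    else:
        x = x.astype(np.float32)
    return x[:, None]


def train(
    model: UNet,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainHistory:
    """Train with Adam on the Dice loss; returns the full history.

    Per-epoch accuracy is the mean IOU over each group's B-scans (training
    accuracy from the within-epoch forward passes, validation from a full
    pass after each epoch).  The model is left at the weights of the best
    validation-accuracy epoch.  A NaN loss aborts with the epoch index.
    """
    cfg = cfg or TrainConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("need at least one training and one validation image")
    xt = _prep_inputs(train_images)
    yt = np.asarray(train_labels).astype(np.float32)
    xv = _prep_inputs(val_images)
    yv = np.asarray(val_labels).astype(np.float32)
    if xt.shape[2:] != yt.shape[1:]:
        raise ValueError("labels must match input B-scan size")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    hist = TrainHistory()
    best_state = model.state()
    best_acc = -1.0

    n = len(xt)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        epoch_iou = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits = model.forward(xt[idx])
            loss, dlogits, probs = softmax_dice(logits, yt[idx], cfg.dice_eps)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite Dice loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
            pred = np.argmax(logits, axis=1).astype(bool)
            epoch_iou.extend(
                [_mean_iou(pred[i : i + 1], yt[idx][i : i + 1]) for i in range(len(idx))]
            )
        train_loss = float(np.average(losses, weights=weights))
        train_acc = float(np.mean(epoch_iou))

        vl, va = _evaluate(model, xv, yv, cfg)
        hist.train_loss.append(train_loss)
        hist.val_loss.append(vl)
        hist.train_acc.append(train_acc)
        hist.val_acc.append(va)
        if va > best_acc:
            best_acc = va
            best_state = model.state()
            hist.best_epoch = epoch
        if cfg.stop_train_loss is not None and train_loss <= cfg.stop_train_loss:
            break
        if cfg.stop_train_iou is not None and train_acc >= cfg.stop_train_iou:
            break
    model.load_state(best_state)
    return hist


def _evaluate(
    model: UNet, x: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> tuple[float, float]:
    """Dice loss over the whole group plus its mean IOU (no updates)."""
    probs_fg = np.empty(y.shape, dtype=np.float64)
    preds = np.empty(y.shape, dtype=bool)
    for s in range(0, len(x), cfg.batch_size):
        logits = model.forward(x[s : s + cfg.batch_size])
        probs = _softmax(logits.astype(np.float64))
        probs_fg[s : s + cfg.batch_size] = probs[:, 1]
        preds[s : s + cfg.batch_size] = np.argmax(logits, axis=1).astype(bool)
    return dice_loss(probs_fg, y, cfg.dice_eps), _mean_iou(preds, y)


def bscans_from_volume(vol: OCTVolume) -> np.ndarray:
    """Split a flattened, cropped volume into B-scan images (ny, nz, nx)."""
    return np.transpose(vol.data, (1, 2, 0))


def _pad_to(img: np.ndarray, d: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape[-2:]
    ph = (-h) % d
    pw = (-w) % d
    pad = [(0, 0)] * (img.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(img, pad), (ph, pw)


def predict(
    model: UNet,
    volume: OCTVolume,
    vmax: float | None = None,
    batch_size: int = 4,
) -> VesselMask:
    """Segment every B-scan of a flattened, cropped volume.

    B-scans are converted to 8-bit with a volume-wide ceiling, padded to
    the nearest multiple of 16, classified, argmaxed (ties break toward
    non-vessel), and un-padded.  Returns a mask with provenance ``dl``.
    """
    if vmax is None:
        vmax = volume_vmax(volume)
    bscans = bscans_from_volume(volume)              # (ny, H, W)
    imgs = to_uint8(bscans, vmax)
    x = _prep_inputs(imgs)
    xp, (ph, pw) = _pad_to(x, model.spec.divisor)
    h, w = x.shape[2:]
    preds = np.empty((len(x), h, w), dtype=bool)
    for s in range(0, len(x), batch_size):
        logits = model.forward(xp[s : s + batch_size])
        cls = np.argmax(logits, axis=1).astype(bool)
        preds[s : s + batch_size] = cls[:, :h, :w]
    # (ny, nz, nx) -> (nx, ny, nz)
    mask = np.transpose(preds, (2, 0, 1))
    return VesselMask(
        data=mask,
        frame="flattened",
        provenance="dl",
        crop_um=volume.meta.get("crop_um"),
        physical_pitch_um=volume.physical_pitch_um,
    )


def save_checkpoint(
    path, model: UNet, cfg: TrainConfig | None = None, seed: int | None = None
) -> None:
    """Store architecture, weights, training config and seed in one file."""
    meta = {
        "spec": asdict(model.spec),
        "config": asdict(cfg) if cfg else None,
        "seed": seed,
    }
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[UNet, dict]:
    """Rebuild a U-Net from a checkpoint; returns (model, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec_d = dict(meta["spec"])
        spec_d["widths"] = tuple(spec_d["widths"])
        spec = UNetSpec(**spec_d)
        model = UNet(spec)
        n = len(model.parameters())
        state = [data[f"p{i}"] for i in range(n)]
    model.load_state(state)
    return model, meta
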