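"""Trainable encoder-decoder binarization of phase-contrast images.

The preprocessing contract: min-max normalization to [0, 1], centred
edge-reflection padding up to the square network input size, and a
bit-exact crop back to native resolution after prediction.  Training
keeps the parameter snapshot with the minimum validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from ..types import BinaryMask, DegenerateInputError, GrayImage, ParameterError
from . import nn

__all__ = [
    "NetConfig",
    "TrainPair",
    "TrainedModel",
    "normalize_minmax",
    "pad_reflect",
    "crop_center",
    "augment_pair",
    "build_and_train",
    "predict",
]


@dataclass
class NetConfig:
    """Architecture and training hyper-parameters of the segmenter."""

    input_size: int = 64
    depth: int = 2
    base_filters: int = 8
    max_epochs: int = 40
    augment: dict = field(
        default_factory=lambda: {"rotation": True, "flipping": True, "resizing": True}
    )
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 8
    val_fraction: float = 0.2
    patience: int = 10

    def __post_init__(self) -> None:
        if self.base_filters < 1:
            raise ParameterError("base_filters must be >= 1")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.input_size % 2 ** (self.depth - 1) != 0:
            raise ParameterError(
                f"input_size {self.input_size} must be divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}"
            )


@dataclass
class TrainPair:
    """A phase-contrast image with its ground-truth mask."""

    phase: GrayImage
    truth: BinaryMask

    def __post_init__(self) -> None:
        if self.phase.shape != self.truth.shape:
            raise ParameterError("phase image and truth mask dimensions differ")


@dataclass
class TrainedModel:
    """Snapshot of the segmenter at its minimum validation loss."""

    config: NetConfig
    params: nn.Params
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "best_epoch": self.best_epoch,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            config=NetConfig(**meta["config"]),
            params=params,
            train_loss=meta["train_loss"],
            val_loss=meta["val_loss"],
            best_epoch=meta["best_epoch"],
        )


# ---------------------------------------------------------------------------
# preprocessing


def normalize_minmax(img: GrayImage) -> GrayImage:
    """Rescale intensities affinely so the range is exactly [0, 1]."""
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    if hi <= lo:
        raise DegenerateInputError("cannot min-max normalize a constant image")
    return img.with_pixels((img.pixels - lo) / (hi - lo))


def _reflect_pad(arr: np.ndarray, pads: tuple[tuple[int, int], tuple[int, int]]
                 ) -> np.ndarray:
    """Mirror-reflection padding supporting pads wider than the array."""
    remaining = [list(p) for p in pads]
    out = arr
    while any(p > 0 for pair in remaining for p in pair):
        step = []
        for axis, pair in enumerate(remaining):
            limit = max(out.shape[axis] - 1, 1)
            take = [min(pair[0], limit), min(pair[1], limit)]
            pair[0] -= take[0]
            pair[1] -= take[1]
            step.append(tuple(take))
        mode = "reflect" if min(out.shape) > 1 else "edge"
        out = np.pad(out, step, mode=mode)
    return out


def _pad_amounts(shape: tuple[int, int], target: int) -> tuple[tuple[int, int],
                                                               tuple[int, int]]:
    h, w = shape
    top = (target - h) // 2
    left = (target - w) // 2
    return (top, target - h - top), (left, target - w - left)


def pad_reflect(img: GrayImage, target: int) -> GrayImage:
    """Pad to a centred ``target``x``target`` square by edge reflection."""
    h, w = img.shape
    if target < h or target < w:
        raise ParameterError(
            f"padding target {target} is smaller than image {h}x{w}"
        )
    return img.with_pixels(_reflect_pad(img.pixels, _pad_amounts((h, w), target)))


def crop_center(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Crop the centred window of the given shape; inverse of pad_reflect."""
    h, w = shape
    (top, _), (left, _) = _pad_amounts((h, w), arr.shape[0])
    return arr[top:top + h, left:left + w]


def augment_pair(pair: TrainPair, rng: np.random.Generator,
                 toggles: dict | None = None) -> TrainPair:
    """Apply one random geometric transform to image and mask jointly.

    Transforms: 90-degree-multiple rotation, horizontal/vertical flip,
    and bounded rescaling (0.9-1.1, nearest-neighbour for the mask).
    Output dimensions equal input dimensions.
    """
    toggles = toggles or {"rotation": True, "flipping": True, "resizing": True}
    img = pair.phase.pixels
    msk = pair.truth.pixels
    if toggles.get("rotation", False):
        k = int(rng.integers(0, 4))
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    if toggles.get("flipping", False):
        if rng.random() < 0.5:
            img, msk = img[:, ::-1], msk[:, ::-1]
        if rng.random() < 0.5:
            img, msk = img[::-1, :], msk[::-1, :]
    if toggles.get("resizing", False):
        scale = float(rng.uniform(0.9, 1.1))
        shape = img.shape
        img = ndimage.zoom(img, scale, order=1)
        msk = ndimage.zoom(msk.astype(np.uint8), scale, order=0).astype(bool)
        img = _fit_to(img, shape, fill=float(np.median(img)))
        msk = _fit_to(msk, shape, fill=False)
    return TrainPair(
        phase=pair.phase.with_pixels(np.ascontiguousarray(img)),
        truth=BinaryMask(np.ascontiguousarray(msk), pixel_size=pair.truth.pixel_size),
    )


def _fit_to(arr: np.ndarray, shape: tuple[int, int], fill) -> np.ndarray:
    """Centre-crop or centre-pad (constant fill) to the given shape."""
    out = np.full(shape, fill, dtype=arr.dtype)
    h, w = arr.shape
    th, tw = shape
    sy, ty = max(0, (h - th) // 2), max(0, (th - h) // 2)
    sx, tx = max(0, (w - tw) // 2), max(0, (tw - w) // 2)
    ch, cw = min(h, th), min(w, tw)
    out[ty:ty + ch, tx:tx + cw] = arr[sy:sy + ch, sx:sx + cw]
    return out


# ---------------------------------------------------------------------------
# training and prediction


def _prepare(pair: TrainPair, target: int) -> tuple[np.ndarray, np.ndarray]:
    phase = normalize_minmax(pair.phase)
    x = pad_reflect(phase, target).pixels[np.newaxis]
    t = _reflect_pad(
        pair.truth.pixels.astype(np.float64),
        _pad_amounts(pair.truth.shape, target),
    )[np.newaxis]
    return x, t


def build_and_train(pairs: list[TrainPair], cfg: NetConfig) -> TrainedModel:
    """Train the encoder-decoder, returning the min-validation-loss snapshot.

    The train/validation split (``cfg.val_fraction`` by image) and all
    augmentation draws derive from ``cfg.seed``, so two runs with the
    same config and pairs produce identical loss curves.
    """
    if len(pairs) < 2:
        raise ParameterError("need at least 2 pairs for a train/validation split")
    for p in pairs:
        if max(p.phase.shape) > cfg.input_size:
            raise ParameterError(
                f"image {p.phase.shape} exceeds input_size {cfg.input_size}"
            )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx[:1], val_idx[1:]

    xs_val, ts_val = zip(*(_prepare(pairs[i], cfg.input_size) for i in val_idx))
    x_val = np.stack(xs_val)
    t_val = np.stack(ts_val)

    params = nn.init_params(cfg.depth, cfg.base_filters, rng)
    opt = nn.Adam(params, lr=cfg.learning_rate)

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_loss, best_epoch = np.inf, -1
    best_params = {k: v.copy() for k, v in params.items()}

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(perm), cfg.batch_size):
            batch = [pairs[train_idx[i]] for i in perm[start:start + cfg.batch_size]]
            batch = [augment_pair(p, rng, cfg.augment) for p in batch]
            xs, ts = zip(*(_prepare(p, cfg.input_size) for p in batch))
            x, t = np.stack(xs), np.stack(ts)
            cache: dict = {}
            logits = nn.forward(params, x, cfg.depth, cache)
            loss, dlogits = nn.bce_loss(logits, t)
            grads = nn.backward(params, cache, dlogits, cfg.depth)
            opt.step(params, grads)
            epoch_losses.append(loss)
        train_hist.append(float(np.mean(epoch_losses)))

        val_losses = []
        for i in range(0, len(x_val), cfg.batch_size):
            logits = nn.forward(params, x_val[i:i + cfg.batch_size], cfg.depth)
            loss, _ = nn.bce_loss(logits, t_val[i:i + cfg.batch_size])
            val_losses.append(loss * len(x_val[i:i + cfg.batch_size]))
        val = float(np.sum(val_losses) / len(x_val))
        val_hist.append(val)

        if val < best_loss:
            best_loss, best_epoch = val, epoch
            best_params = {k: v.copy() for k, v in params.items()}
        elif cfg.patience > 0 and epoch - best_epoch >= cfg.patience:
            break

    return TrainedModel(
        config=cfg,
        params=best_params,
        train_loss=train_hist,
        val_loss=val_hist,
        best_epoch=best_epoch,
    )


def predict(model: TrainedModel, img: GrayImage,
            threshold: float = 0.5) -> BinaryMask:
    """Binarize one image: normalize, pad, forward pass, crop, threshold."""
    cfg = model.config
    if max(img.shape) > cfg.input_size:
        raise ParameterError(
            f"image {img.shape} exceeds the model input size {cfg.input_size}"
        )
    if np.ptp(img.pixels) == 0:
        return BinaryMask(np.zeros(img.shape, dtype=bool),
                          pixel_size=img.pixel_size)
    x = pad_reflect(normalize_minmax(img), cfg.input_size).pixels
    logits = nn.forward(model.params, x[np.newaxis, np.newaxis], cfg.depth)
    prob = nn.sigmoid(logits[0, 0])
    mask = crop_center(prob, img.shape) > threshold
    return BinaryMask(mask, pixel_size=img.pixel_size)
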