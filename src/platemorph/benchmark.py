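"""Phantom closed-loop benchmarks used for validation.

These functions regenerate synthetic datasets from a seed, run a
pipeline stage, and measure recovery of the designed truth.  They back
both the test suite and the acceptance report, so the exact dataset
definitions live here rather than being duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import segmentation as seg
from .phantom import (
    PhantomSpec,
    RenderSpec,
    make_platelet_mask,
    render_empty_field,
    render_image,
)
from .stats import pixel_confusion
from .types import BinaryMask


@dataclass
class SegmentationBenchmark:
    iou: float
    n_train: int
    n_test: int
    best_epoch: int
    val_loss: float


def phantom_render_pairs(
    n: int,
    seed: int,
    canvas: int = 96,
    empty_fraction: float = 0.1,
) -> list[seg.TrainPair]:
    """Seeded phase-contrast renders of varied phantoms with truth masks.

    Noise level, halo strength and background gradient vary per image;
    a small fraction of frames is platelet-free so the segmenter learns
    background noise statistics rather than an absolute grey level.
    """
    rng = np.random.default_rng(seed)
    filo_len = canvas * 0.1
    filo_width = 3.0 if canvas < 64 else 4.0
    a_hi = (canvas - 1) / 2.0 - filo_len - filo_width - 2.0
    b_lo = max(0.45 * a_hi, filo_width + 1.0)
    pairs = []
    for i in range(n):
        render = RenderSpec(
            mode="phase_contrast",
            halo_amplitude=rng.uniform(0.2, 0.4),
            blur_sigma=1.0,
            noise_sd=rng.uniform(0.02, 0.05),
            background_gradient=rng.uniform(-0.002, 0.002),
        )
        render_seed = int(rng.integers(0, 2**31))
        if rng.random() < empty_fraction:
            img = render_empty_field((canvas, canvas), render, seed=render_seed)
            mask = BinaryMask(np.zeros((canvas, canvas), dtype=bool))
        else:
            a = rng.uniform(0.6 * a_hi, a_hi)
            b = rng.uniform(min(b_lo, a - 0.5), a)
            spec = PhantomSpec(
                body_semi_axes=(a, b),
                orientation=rng.uniform(0, np.pi),
                n_filopodia=int(rng.integers(0, 6)),
                filopodium_length=filo_len,
                filopodium_width=filo_width,
                seed=int(rng.integers(0, 2**31)),
            )
            mask, _ = make_platelet_mask(spec, canvas_shape=(canvas, canvas))
            img = render_image(mask, render, seed=render_seed)
        pairs.append(seg.TrainPair(img, mask))
    return pairs


def segmentation_closed_loop(
    seed: int = 0,
    n_images: int = 200,
    canvas: int = 96,
    test_fraction: float = 0.25,
    cfg: seg.NetConfig | None = None,
) -> SegmentationBenchmark:
    """Train on phantom renders and report held-out pixel IoU.

    Images are split train/test up front (the trainer makes its own
    train/validation split inside the training portion); IoU is computed
    over all held-out pixels, TP/(TP+FP+FN).
    """
    pairs = phantom_render_pairs(n_images, seed=seed, canvas=canvas)
    n_test = max(1, int(round(test_fraction * n_images)))
    test_pairs, train_pairs = pairs[:n_test], pairs[n_test:]
    if cfg is None:
        cfg = seg.NetConfig(input_size=canvas, depth=2, base_filters=8,
                            max_epochs=60, learning_rate=2e-3, seed=seed,
                            patience=20)
    model = seg.build_and_train(train_pairs, cfg)
    tp = fp = fn = 0
    for pair in test_pairs:
        pred = seg.predict(model, pair.phase)
        c = pixel_confusion(pred, pair.truth)
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
    return SegmentationBenchmark(
        iou=tp / (tp + fp + fn),
        n_train=len(train_pairs),
        n_test=len(test_pairs),
        best_epoch=model.best_epoch,
        val_loss=model.val_loss[model.best_epoch],
    )
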