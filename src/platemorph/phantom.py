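"""Synthetic platelet phantoms with known ground truth.

Generates platelet-shaped binary masks (ellipse body plus capsule-shaped
filopodia), phase-contrast / fluorescence-like renderings, two-phase
spreading sequences, and migration sequences along designed paths.  Every
generator is a pure function of its spec and seed, and every output is
accompanied by the designed truth so downstream stages can be validated
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .types import BinaryMask, GrayImage, ParameterError, ShapeRecord

CANVAS_MARGIN = 10  # pixels added around the tight bounding geometry


class CanvasError(ParameterError):
    """Geometry does not fit the requested canvas."""


@dataclass
class PhantomSpec:
    """Designed geometry of a single synthetic platelet.

    ``body_semi_axes = (a, b)`` with ``a >= b > 0``; filopodia radiate
    from the ellipse boundary as capsules (rectangle plus rounded tip).
    Angular positions are equally spaced with seeded jitter, guaranteeing
    pairwise separation larger than the angle subtended by one base.
    """

    body_semi_axes: tuple[float, float] = (20.0, 20.0)
    orientation: float = 0.0
    n_filopodia: int = 0
    filopodium_length: float = 15.0
    filopodium_width: float = 4.0
    centroid: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.body_semi_axes
        if not (a >= b > 0):
            raise ParameterError("body semi-axes must satisfy a >= b > 0")
        if self.n_filopodia < 0:
            raise ParameterError("n_filopodia must be non-negative")
        if self.n_filopodia > 0 and not (0 < self.filopodium_width < b):
            raise ParameterError("filopodium_width must lie in (0, b)")
        if self.n_filopodia > 0 and self.filopodium_length <= 0:
            raise ParameterError("filopodium_length must be positive")

    @property
    def aspect_ratio(self) -> float:
        a, b = self.body_semi_axes
        return a / b

    @property
    def reach(self) -> float:
        """Radius of the tight bounding circle around body plus filopodia."""
        a, _ = self.body_semi_axes
        extra = self.filopodium_length + self.filopodium_width if self.n_filopodia else 0.0
        return a + extra

    def filopodia_angles(self) -> np.ndarray:
        """Equally spaced angles with seeded jitter, separation-safe."""
        n = self.n_filopodia
        if n == 0:
            return np.array([])
        rng = np.random.default_rng(self.seed)
        base = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        spacing = 2 * np.pi / n
        # subtended half-angle of one filopodium base at the short axis
        _, b = self.body_semi_axes
        subtend = 2 * math.asin(min(1.0, self.filopodium_width / (2 * b)))
        slack = spacing - subtend
        if slack <= 0:
            raise ParameterError(
                f"{n} filopodia of width {self.filopodium_width} cannot be "
                "separated on this body; reduce count or width"
            )
        jitter = rng.uniform(-0.45 * slack, 0.45 * slack, size=n)
        return base + jitter + rng.uniform(0, 2 * np.pi)


@dataclass
class RenderSpec:
    """Parameters of the image rendering applied to a binary mask."""

    mode: Literal["phase_contrast", "fluorescence"] = "phase_contrast"
    halo_amplitude: float = 0.3
    blur_sigma: float = 1.0
    noise_sd: float = 0.02
    background_gradient: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.blur_sigma < 0:
            raise ParameterError("blur_sigma must be >= 0")


@dataclass
class MotionSpec:
    """Designed centroid motion for a migration sequence."""

    path_kind: Literal[
        "straight", "persistent_random", "isotropic_random", "stationary"
    ] = "straight"
    speed: float = 5.0
    persistence: float = 0.8
    n_frames: int = 10
    frame_interval: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.speed < 0:
            raise ParameterError("speed must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ParameterError("persistence must lie in [0, 1]")


# ---------------------------------------------------------------------------
# mask generation


def _rasterize(spec: PhantomSpec, canvas_shape: tuple[int, int],
               center: tuple[float, float]) -> np.ndarray:
    """Boolean raster of body ellipse plus filopodium capsules."""
    h, w = canvas_shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - cx, yy - cy

    a, b = spec.body_semi_axes
    cos_t, sin_t = math.cos(spec.orientation), math.sin(spec.orientation)
    xr = dx * cos_t + dy * sin_t
    yr = -dx * sin_t + dy * cos_t
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    for ang in spec.filopodia_angles():
        # base point on the ellipse at parametric angle `ang` (body frame)
        bx, by = a * math.cos(ang), b * math.sin(ang)
        norm = math.hypot(bx, by)
        ux, uy = bx / norm, by / norm  # radial outward direction
        # capsule from slightly inside the body to the designed tip
        p0 = np.array([bx - 2.0 * ux, by - 2.0 * uy])
        p1 = np.array([bx + spec.filopodium_length * ux,
                       by + spec.filopodium_length * uy])
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        px, py = xr - p0[0], yr - p0[1]
        t = np.clip((px * seg[0] + py * seg[1]) / seg_len2, 0.0, 1.0)
        dist2 = (px - t * seg[0]) ** 2 + (py - t * seg[1]) ** 2
        mask |= dist2 <= (spec.filopodium_width / 2.0) ** 2
    return mask


def designed_area(spec: PhantomSpec) -> float:
    """Analytic area of the ellipse-plus-capsules geometry, in pixels².

    The capsule contribution beyond the body boundary is length x width
    plus the half-disk tip; the curvature of the base is neglected, which
    is well inside discretization tolerance for widths << semi-axes.
    """
    a, b = spec.body_semi_axes
    area = math.pi * a * b
    if spec.n_filopodia:
        w = spec.filopodium_width
        per_filo = spec.filopodium_length * w + math.pi * (w / 2.0) ** 2 / 2.0
        area += spec.n_filopodia * per_filo
    return area


def make_platelet_mask(
    spec: PhantomSpec,
    canvas_shape: tuple[int, int] | None = None,
    pixel_size: float = 1.0,
) -> tuple[BinaryMask, ShapeRecord]:
    """Rasterize a phantom and return the mask plus its designed truth.

    The truth record carries the *designed* aspect ratio, filopodia count
    and analytic area (converted to µm²).  Raises :class:`CanvasError` if
    the geometry does not fit ``canvas_shape``.
    """
    reach = spec.reach
    required = 2 * math.ceil(reach) + 1 + 2 * CANVAS_MARGIN
    if canvas_shape is None:
        canvas_shape = (required, required)
    if spec.centroid is None:
        center = ((canvas_shape[1] - 1) / 2.0, (canvas_shape[0] - 1) / 2.0)
    else:
        center = spec.centroid
    cx, cy = center
    h, w = canvas_shape
    if (cx - reach < 0 or cy - reach < 0 or cx + reach > w - 1
            or cy + reach > h - 1):
        raise CanvasError(
            f"phantom with reach {reach:.1f} px at ({cx:.1f}, {cy:.1f}) "
            f"needs a canvas of at least {required}x{required}; got {h}x{w}"
        )

    pixels = _rasterize(spec, canvas_shape, center)
    truth = ShapeRecord(
        platelet_id=0,
        frame_index=0,
        centroid=(cx * pixel_size, cy * pixel_size),
        area=designed_area(spec) * pixel_size**2,
        perimeter=float("nan"),
        circularity=float("nan"),
        aspect_ratio=spec.aspect_ratio,
        n_filopodia=spec.n_filopodia,
    )
    return BinaryMask(pixels, pixel_size=pixel_size), truth


# ---------------------------------------------------------------------------
# rendering

_PHASE_BG = 0.7
_PHASE_BODY = 0.3
_FLUOR_BG = 0.05
_FLUOR_BODY = 1.0


def _edge_halo(mask: np.ndarray) -> np.ndarray:
    """Bright rim around the outline: positive part of an edge DoG."""
    edge = mask ^ ndimage.binary_erosion(mask)
    f = edge.astype(np.float64)
    dog = ndimage.gaussian_filter(f, 1.0) - ndimage.gaussian_filter(f, 3.0)
    halo = np.maximum(dog, 0.0)
    peak = halo.max()
    return halo / peak if peak > 0 else halo


def render_image(mask: BinaryMask, render: RenderSpec, seed: int = 0) -> GrayImage:
    """Render a mask as a synthetic microscopy image.

    Phase-contrast mode yields a body darker than background with a
    bright halo around the outline; fluorescence mode a bright body on a
    dark background.  Blur, a linear background gradient, and Gaussian
    noise are applied afterwards.  Deterministic for a fixed seed.
    """
    m = mask.pixels
    if not m.any():
        raise ParameterError("mask is empty; nothing to render")
    if render.mode == "phase_contrast":
        img = np.where(m, _PHASE_BODY, _PHASE_BG)
    else:
        img = np.where(m, _FLUOR_BODY, _FLUOR_BG)
    if render.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, render.blur_sigma)
    if render.mode == "phase_contrast" and render.halo_amplitude != 0:
        img = img + render.halo_amplitude * _edge_halo(m)
    if render.background_gradient != 0:
        xx = np.arange(m.shape[1], dtype=np.float64)
        img = img + render.background_gradient * xx[np.newaxis, :]
    if render.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, render.noise_sd, size=img.shape)
    channel = "fluorescence" if render.mode == "fluorescence" else "phase_contrast"
    return GrayImage(np.clip(img, 0.0, None), pixel_size=mask.pixel_size,
                     channel=channel)


def render_empty_field(shape: tuple[int, int], render: RenderSpec,
                       seed: int = 0, pixel_size: float = 1.0) -> GrayImage:
    """Background-only render (no platelet): level, gradient and noise."""
    level = _FLUOR_BG if render.mode == "fluorescence" else _PHASE_BG
    img = np.full(shape, level, dtype=np.float64)
    if render.background_gradient != 0:
        xx = np.arange(shape[1], dtype=np.float64)
        img = img + render.background_gradient * xx[np.newaxis, :]
    if render.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, render.noise_sd, size=shape)
    channel = "fluorescence" if render.mode == "fluorescence" else "phase_contrast"
    return GrayImage(np.clip(img, 0.0, None), pixel_size=pixel_size,
                     channel=channel)


# ---------------------------------------------------------------------------
# spreading sequences


def _disk_mask(canvas_shape: tuple[int, int], center: tuple[float, float],
               target_area: float) -> np.ndarray:
    """Digitized disk whose pixel count best matches ``target_area``."""
    h, w = canvas_shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dist2 = (xx - cx) ** 2 + (yy - cy) ** 2
    r0 = math.sqrt(target_area / math.pi)
    best, best_err = None, np.inf
    for r in np.linspace(max(r0 - 1.5, 0.5), r0 + 1.5, 61):
        count = int((dist2 <= r * r).sum())
        err = abs(count - target_area)
        if err < best_err:
            best, best_err = r, err
    return dist2 <= best * best


def make_spreading_sequence(
    initial_area: float,
    idle_frames: int,
    fast_rate: float,
    slow_rate: float,
    switch_frame: int,
    n_frames: int,
    pixel_size: float = 1.0,
) -> tuple[list[BinaryMask], list[float]]:
    """Disk sequence with designed two-phase area growth.

    Designed area (pixels²) is constant for ``idle_frames`` frames, then
    grows by ``fast_rate`` per frame until ``switch_frame``, then by
    ``slow_rate``.  Returns the masks and the designed per-frame areas.
    """
    if not (fast_rate > slow_rate >= 0):
        raise ParameterError("require fast_rate > slow_rate >= 0")
    if not (0 <= idle_frames < switch_frame < n_frames):
        raise ParameterError(
            "frame ordering must satisfy 0 <= idle_frames < switch_frame < n_frames"
        )
    areas = [float(initial_area)]
    for t in range(1, n_frames):
        if t < idle_frames:
            rate = 0.0
        elif t <= switch_frame:
            rate = fast_rate
        else:
            rate = slow_rate
        areas.append(areas[-1] + rate)

    max_r = math.sqrt(max(areas) / math.pi)
    side = 2 * math.ceil(max_r) + 1 + 2 * CANVAS_MARGIN
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    masks = [
        BinaryMask(_disk_mask((side, side), center, a), pixel_size=pixel_size)
        for a in areas
    ]
    return masks, areas


# ---------------------------------------------------------------------------
# migration sequences


def design_path(spec: MotionSpec) -> np.ndarray:
    """Designed centroid path (n_frames, 2), starting at the origin."""
    rng = np.random.default_rng(spec.seed)
    n_steps = spec.n_frames - 1
    if spec.path_kind == "stationary" or spec.speed == 0:
        return np.zeros((spec.n_frames, 2))
    if spec.path_kind == "straight":
        heading = np.full(n_steps, rng.uniform(0, 2 * np.pi))
    elif spec.path_kind == "isotropic_random":
        heading = rng.uniform(0, 2 * np.pi, size=n_steps)
    elif spec.path_kind == "persistent_random":
        sigma = (1.0 - spec.persistence) * np.pi
        increments = rng.normal(0.0, sigma, size=n_steps)
        increments[0] = rng.uniform(0, 2 * np.pi)
        heading = np.cumsum(increments)
    else:  # pragma: no cover - guarded by MotionSpec
        raise ParameterError(f"unknown path_kind {spec.path_kind!r}")
    steps = spec.speed * np.column_stack([np.cos(heading), np.sin(heading)])
    path = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return path


def make_migration_sequence(
    spec: MotionSpec,
    shape: PhantomSpec,
    canvas_shape: tuple[int, int] | None = None,
    pixel_size: float = 1.0,
) -> tuple[list[BinaryMask], np.ndarray]:
    """Render a moving phantom; returns masks and the designed centroid path.

    The path is generated from ``spec`` (seeded), shifted into the canvas.
    With an explicit ``canvas_shape`` a path leaving the canvas raises
    :class:`CanvasError`.
    """
    path = design_path(spec)
    reach = shape.reach
    pad = reach + CANVAS_MARGIN
    lo = path.min(axis=0)
    if canvas_shape is None:
        shift = pad - lo
        path = path + shift
        hi = path.max(axis=0)
        canvas_shape = (math.ceil(hi[1] + pad) + 1, math.ceil(hi[0] + pad) + 1)
    else:
        h, w = canvas_shape
        shift = pad - lo
        path = path + shift
        hi = path.max(axis=0)
        if hi[0] + reach > w - 1 or hi[1] + reach > h - 1:
            need_w = math.ceil(hi[0] + pad) + 1
            need_h = math.ceil(hi[1] + pad) + 1
            raise CanvasError(
                f"designed path needs a canvas of at least {need_h}x{need_w}; "
                f"got {h}x{w}"
            )
    masks = []
    for cx, cy in path:
        frame_spec = PhantomSpec(
            body_semi_axes=shape.body_semi_axes,
            orientation=shape.orientation,
            n_filopodia=shape.n_filopodia,
            filopodium_length=shape.filopodium_length,
            filopodium_width=shape.filopodium_width,
            centroid=(float(cx), float(cy)),
            seed=shape.seed,
        )
        mask, _ = make_platelet_mask(frame_spec, canvas_shape=canvas_shape,
                                     pixel_size=pixel_size)
        masks.append(mask)
    return masks, path * pixel_size
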