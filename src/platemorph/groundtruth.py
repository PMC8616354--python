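"""Ground-truth mask generation from membrane-stain fluorescence images.

Three steps: rolling-ball background subtraction, thresholding (fixed or
Otsu), and hole filling.  Manual inspection of the result is out of the
automated path; a per-frame external override mask can be supplied
instead.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters

from .types import BinaryMask, DegenerateInputError, GrayImage, ParameterError

DEFAULT_RADIUS = 50.0  # pixels, appropriate at high magnification


def _ball_structure(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(np.float64)
    d2 = yy**2 + xx**2
    footprint = d2 <= radius**2
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius**2 - d2[footprint]) - radius
    return footprint, heights


def rolling_ball_background(img: GrayImage, radius: float = DEFAULT_RADIUS
                            ) -> np.ndarray:
    """Rolling-ball background: grey-level opening with a ball.

    The ball surface contributes ``sqrt(r^2 - d^2) - r`` at offset
    distance ``d``; outside-image offsets are ignored (equivalent to a
    +/-inf constant pad), matching the direct push-the-ball-up-under-
    the-surface construction.
    """
    if radius < 1:
        raise ParameterError("rolling-ball radius must be >= 1 pixel")
    if radius > max(img.shape):
        raise ParameterError(
            f"rolling-ball radius {radius} exceeds image extent {img.shape}"
        )
    footprint, heights = _ball_structure(radius)
    ero = ndimage.grey_erosion(img.pixels, footprint=footprint,
                               structure=heights, mode="constant",
                               cval=np.inf)
    return ndimage.grey_dilation(ero, footprint=footprint, structure=heights,
                                 mode="constant", cval=-np.inf)


def rolling_ball_subtract(img: GrayImage, radius: float = DEFAULT_RADIUS) -> GrayImage:
    """Subtract the rolling-ball background estimate, clipping at zero.

    Constant regions map to ~0 and adding a constant to the input leaves
    the output unchanged.
    """
    background = rolling_ball_background(img, radius=radius)
    out = np.clip(img.pixels - background, 0.0, None)
    return img.with_pixels(out)


def threshold_and_fill(img: GrayImage, threshold: float | str = "otsu") -> BinaryMask:
    """Binarize strictly above a threshold and fill interior holes.

    ``threshold`` may be a number or ``"otsu"``.  Background regions not
    connected to the image border (4-connected) become foreground.
    """
    pixels = img.pixels
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ParameterError(f"unknown threshold method {threshold!r}")
        if np.ptp(pixels) == 0:
            raise DegenerateInputError(
                "otsu threshold undefined for a constant image"
            )
        threshold = filters.threshold_otsu(pixels)
    fg = pixels > threshold
    filled = ndimage.binary_fill_holes(fg)
    return BinaryMask(filled, pixel_size=img.pixel_size)


def make_ground_truth(
    fluor: GrayImage,
    radius: float = DEFAULT_RADIUS,
    threshold: float | str = "otsu",
    override: BinaryMask | None = None,
) -> BinaryMask:
    """Fluorescence image -> binary ground-truth mask.

    Composition of :func:`rolling_ball_subtract` and
    :func:`threshold_and_fill`.  If ``override`` is given (the stand-in
    for a manually corrected frame) it is returned unchanged.
    """
    if override is not None:
        if override.shape != fluor.shape:
            raise ParameterError("override mask dimensions do not match image")
        return override
    flattened = rolling_ball_subtract(fluor, radius=radius)
    if isinstance(threshold, str) and np.ptp(flattened.pixels) == 0:
        # empty field: nothing above background
        return BinaryMask(np.zeros(fluor.shape, dtype=bool),
                          pixel_size=fluor.pixel_size)
    return threshold_and_fill(flattened, threshold=threshold)
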