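"""Core data carriers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Channel = Literal["phase_contrast", "fluorescence"]


class DegenerateInputError(ValueError):
    """Raised when an input is constant / empty where variation is required."""


class ParameterError(ValueError):
    """Raised when a parameter violates an operation's precondition."""


@dataclass
class GrayImage:
    """2-D scalar intensity field with pixel-size metadata.

    Parameters
    ----------
    pixels
        2-D float array of non-negative intensities.
    pixel_size
        Physical edge length of one pixel in micrometres.
    channel
        Imaging modality the intensities came from.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    channel: Channel = "phase_contrast"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError("image must be 2-D")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass
class BinaryMask:
    """2-D boolean field; ``True`` marks platelet, ``False`` background."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2


@dataclass
class Outline:
    """Ordered closed contour of one platelet.

    ``points`` is an (N, 2) array of (x, y) coordinates in pixel units,
    0-based, pixel-centre convention.  The contour is closed implicitly:
    the last point is adjacent to the first.
    """

    points: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ParameterError("outline points must be an (N, 2) array")
        if len(self.points) < 8:
            raise ParameterError("outline needs at least 8 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class ShapeRecord:
    """Per-platelet, per-frame morphometry row.  Physical units (µm)."""

    platelet_id: int
    frame_index: int
    centroid: tuple[float, float]
    area: float
    perimeter: float
    circularity: float
    aspect_ratio: float
    n_filopodia: int
    curvature_profile: np.ndarray | None = field(default=None, repr=False)

    CSV_COLUMNS = (
        "platelet_id",
        "frame_index",
        "x_um",
        "y_um",
        "area_um2",
        "perimeter_um",
        "circularity",
        "aspect_ratio",
        "n_filopodia",
    )

    def to_row(self) -> dict:
        return {
            "platelet_id": self.platelet_id,
            "frame_index": self.frame_index,
            "x_um": self.centroid[0],
            "y_um": self.centroid[1],
            "area_um2": self.area,
            "perimeter_um": self.perimeter,
            "circularity": self.circularity,
            "aspect_ratio": self.aspect_ratio,
            "n_filopodia": self.n_filopodia,
        }


@dataclass
class Track:
    """Per-platelet centroid time series in physical units."""

    platelet_id: int
    frame_interval: float
    positions: np.ndarray
    complete: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ParameterError("track positions must be an (N, 2) array")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("track positions must be finite")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def steps(self) -> np.ndarray:
        """Per-frame displacement vectors, shape (N-1, 2)."""
        return np.diff(self.positions, axis=0)
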