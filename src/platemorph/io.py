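"""TIFF / CSV / JSON input-output helpers.

Images travel as float64 ``GrayImage`` lists regardless of the on-disk
bit depth; masks are written as 8-bit 0/255 TIFF pages.  Pixel size is
taken from TIFF resolution tags when present, otherwise a configured
value is required.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import BinaryMask, GrayImage, ShapeRecord


class ConfigurationError(ValueError):
    """A required configuration value is missing or invalid."""


class ImageIOError(IOError):
    """A file could not be read as an image stack."""


_SUPPORTED_KINDS = {"u", "i", "f", "b"}


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in µm from X/Y resolution tags, if interpretable."""
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimetre
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    return None


def read_image_stack(
    path: str | Path,
    pixel_size: float | None = None,
    channel: str = "phase_contrast",
) -> list[GrayImage]:
    """Read a single- or multi-page TIFF as a list of float images.

    Page order is frame order.  ``pixel_size`` (µm) overrides any TIFF
    resolution tag; if neither is available a
    :class:`ConfigurationError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            tag_ps = _pixel_size_from_tags(tif)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ImageIOError(f"cannot read {path}: {exc}") from exc
    if arr.dtype.kind not in _SUPPORTED_KINDS:
        raise ImageIOError(f"unsupported bit depth {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ImageIOError(f"{path}: expected 2-D pages, got shape {arr.shape}")
    ps = pixel_size if pixel_size is not None else tag_ps
    if ps is None:
        raise ConfigurationError(
            f"{path} carries no resolution tags; pass pixel_size explicitly"
        )
    return [GrayImage(page.astype(np.float64), pixel_size=ps, channel=channel)
            for page in arr]


def write_image_stack(path: str | Path, images: list[GrayImage]) -> None:
    """Write float images as a multi-page TIFF with resolution tags."""
    arr = np.stack([img.pixels for img in images]).astype(np.float32)
    ps = images[0].pixel_size
    px_per_cm = 1e4 / ps
    tifffile.imwrite(path, arr, photometric="minisblack",
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")


def read_mask_stack(path: str | Path, pixel_size: float | None = None
                    ) -> list[BinaryMask]:
    """Read a TIFF stack as binary masks (nonzero = foreground)."""
    images = read_image_stack(path, pixel_size=pixel_size)
    return [BinaryMask(img.pixels > 0, pixel_size=img.pixel_size)
            for img in images]


def write_mask_stack(path: str | Path, masks: list[BinaryMask]) -> None:
    arr = np.stack([m.pixels for m in masks]).astype(np.uint8) * 255
    ps = masks[0].pixel_size
    px_per_cm = 1e4 / ps
    tifffile.imwrite(path, arr, photometric="minisblack",
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")


def records_to_frame(records: list[ShapeRecord]) -> pd.DataFrame:
    """Stack shape records into the canonical morphometry table."""
    return pd.DataFrame([r.to_row() for r in records],
                        columns=list(ShapeRecord.CSV_COLUMNS))


def write_records_csv(path: str | Path, records: list[ShapeRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
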