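"""Per-platelet shape parameters from binary masks.

Pipeline: label 8-connected components (excluding border-touchers and
sub-threshold specks), trace each boundary with a Moore-neighbour
contour follower, smooth the contour, then compute area, perimeter,
circularity ``c = 4*pi*A/P**2``, moment-ellipse aspect ratio ``e = a/b``,
a signed per-point curvature profile, and a filopodia count based on
length and tip-curvature constraints.

Conventions: 0-based pixel-centre coordinates; 8-connectivity for
platelets, 4-connectivity for background; contours oriented so convex
boundary curvature is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage import measure

from .types import BinaryMask, Outline, ParameterError, ShapeRecord

EIGHT = np.ones((3, 3), dtype=bool)

SMOOTH_SIGMA = 2.0  # px; contour coordinate smoothing before curvature use
PERIMETER_TOLERANCE = 1.0  # px; polygon simplification for arc length
FILO_MIN_LENGTH_UM = 0.5
FILO_MIN_TIP_CURVATURE_UM = 2.0


class DegenerateShapeError(ValueError):
    """Component too thin / collinear for an ellipse fit."""


# ---------------------------------------------------------------------------
# labelling


def label_platelets(mask: BinaryMask, min_area: float = 0.0) -> list[BinaryMask]:
    """Split a mask into per-platelet component masks.

    8-connected components below ``min_area`` (µm²) or touching the
    image border are excluded.  Output order is row-major by centroid.
    """
    labels, n = ndimage.label(mask.pixels, structure=EIGHT)
    if n == 0:
        return []
    border = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) \
        | set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    min_px = min_area / mask.pixel_size**2
    keep = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if lab in border:
            continue
        if comp.sum() < min_px:
            continue
        cy, cx = ndimage.center_of_mass(comp)
        keep.append((cy, cx, comp))
    keep.sort(key=lambda t: (t[0], t[1]))
    return [BinaryMask(comp, pixel_size=mask.pixel_size) for _, _, comp in keep]


# ---------------------------------------------------------------------------
# contour tracing

# clockwise Moore neighbourhood in (row, col) offsets
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_contour(component: BinaryMask) -> Outline:
    """Trace the outer boundary of a single connected component.

    Moore-neighbour tracing with Jacob's stopping criterion: every
    8-connected boundary pixel appears once, in order.  The returned
    outline is oriented so that convex curvature is positive.
    """
    pix = component.pixels
    labels, n = ndimage.label(pix, structure=EIGHT)
    if n != 1:
        raise ParameterError(f"expected a single connected component, got {n}")
    padded = np.pad(pix, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost

    contour = [start]
    # backtrack: the background pixel just before the start in scan order
    prev = (start[0], start[1] - 1)
    cur = start
    entry_dir_at_start = None
    while True:
        # index of the backtrack pixel in the Moore ring around cur
        d0 = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for step in range(1, 9):
            d = (d0 + step) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if padded[cand]:
                nxt = cand
                prev_d = (d0 + step - 1) % 8
                prev = (cur[0] + _MOORE[prev_d][0], cur[1] + _MOORE[prev_d][1])
                break
        if nxt is None:  # isolated pixel
            break
        if nxt == start:
            if entry_dir_at_start == d:
                break
            if entry_dir_at_start is None:
                entry_dir_at_start = d
            else:
                break
        else:
            contour.append(nxt)
        cur = nxt
        if len(contour) > 4 * padded.size:  # pragma: no cover - safety net
            raise RuntimeError("contour tracing failed to terminate")

    pts = np.array([(c - 1, r - 1) for r, c in contour], dtype=np.float64)
    # deduplicate revisited pixels (thin necks) while preserving order
    _, first = np.unique(pts, axis=0, return_index=True)
    pts = pts[np.sort(first)]
    if len(pts) < 8:
        raise ParameterError("component too small to outline (needs >= 8 boundary pixels)")
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    return Outline(pts, pixel_size=component.pixel_size)


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def smooth_outline(outline: Outline, sigma: float = SMOOTH_SIGMA) -> Outline:
    """Gaussian smoothing of the closed contour coordinates (circular)."""
    if sigma <= 0:
        return outline
    xs = gaussian_filter1d(outline.x, sigma, mode="wrap")
    ys = gaussian_filter1d(outline.y, sigma, mode="wrap")
    return Outline(np.column_stack([xs, ys]), pixel_size=outline.pixel_size)


# ---------------------------------------------------------------------------
# shape parameters


def _perimeter_px(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


def subpixel_perimeter(component: BinaryMask,
                       tolerance: float = PERIMETER_TOLERANCE) -> float:
    """Boundary arc length (pixels) of one component, staircase-corrected.

    The 0.5 level-set of the mask (marching squares) is simplified with
    Douglas-Peucker at sub-pixel tolerance; this removes the digitization
    staircase that inflates raw pixel-edge perimeters while preserving
    genuine corners, so a digitized disk measures ~2*pi*r and a square
    measures ~4s.
    """
    padded = np.pad(component.pixels, 2).astype(np.float64)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise DegenerateShapeError("empty component")
    outer = max(contours, key=len)
    poly = measure.approximate_polygon(outer, tolerance=tolerance)
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def _moment_semi_axes(component: np.ndarray) -> tuple[float, float]:
    """Semi-axes of the ellipse with matching normalized second moments."""
    ys, xs = np.nonzero(component)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy**2)
    if (mxx + myy - common) / 2.0 <= 1e-9:
        raise DegenerateShapeError("collinear component; ellipse fit undefined")
    # +1/12: variance of the uniform distribution within one pixel
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy**2)
    l1 = (mxx + myy + common) / 2.0 + 1.0 / 12.0
    l2 = (mxx + myy - common) / 2.0 + 1.0 / 12.0
    return 2.0 * np.sqrt(l1), 2.0 * np.sqrt(l2)


def shape_parameters(
    outline: Outline,
    component: BinaryMask,
    platelet_id: int = 0,
    frame_index: int = 0,
) -> ShapeRecord:
    """Area, perimeter, circularity and aspect ratio of one platelet.

    Area is the pixel count; the perimeter is the arc length of the
    simplified sub-pixel contour (raw pixel-edge perimeters overestimate
    and would bias circularity low).
    """
    ps = component.pixel_size
    area = component.area_um2
    if area <= 0:
        raise DegenerateShapeError("empty component")
    perim = subpixel_perimeter(component) * ps
    circ = 4.0 * np.pi * area / perim**2
    a, b = _moment_semi_axes(component.pixels)
    cy, cx = ndimage.center_of_mass(component.pixels)
    return ShapeRecord(
        platelet_id=platelet_id,
        frame_index=frame_index,
        centroid=(cx * ps, cy * ps),
        area=area,
        perimeter=perim,
        circularity=circ,
        aspect_ratio=a / b,
        n_filopodia=0,
    )


# ---------------------------------------------------------------------------
# curvature and filopodia


def curvature_profile(outline: Outline, smooth_sigma: float = SMOOTH_SIGMA
                      ) -> np.ndarray:
    """Signed curvature per contour point, in 1/µm; convex is positive."""
    if len(outline) < 8:
        raise ParameterError("outline too short for the curvature stencil")
    smoothed = smooth_outline(outline, smooth_sigma)
    x, y = smoothed.x, smoothed.y
    dx = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
    dy = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
    ddx = np.roll(x, -1) - 2 * x + np.roll(x, 1)
    ddy = np.roll(y, -1) - 2 * y + np.roll(y, 1)
    denom = (dx * dx + dy * dy) ** 1.5
    denom = np.where(denom > 1e-12, denom, np.inf)
    kappa_px = (dx * ddy - dy * ddx) / denom
    return kappa_px / outline.pixel_size


@dataclass
class Filopodium:
    apex: tuple[float, float]  # µm
    apex_index: int
    length: float  # µm
    tip_curvature: float  # 1/µm


def _circular_runs(flag: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True in a circular boolean array, as index arrays."""
    n = len(flag)
    if flag.all():
        return [np.arange(n)]
    if not flag.any():
        return []
    # rotate so position 0 is False, then find linear runs
    shift = int(np.argmin(flag))
    rolled = np.roll(flag, -shift)
    edges = np.flatnonzero(np.diff(rolled.astype(np.int8)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1 if len(edges) % 2 == 0 else np.append(edges[1::2] + 1, n)
    return [(np.arange(s, e) + shift) % n for s, e in zip(starts, ends)]


def count_filopodia(
    outline: Outline,
    curvature: np.ndarray,
    min_length: float = FILO_MIN_LENGTH_UM,
    min_tip_curvature: float = FILO_MIN_TIP_CURVATURE_UM,
    neck_curvature: float | None = None,
) -> tuple[int, list[Filopodium]]:
    """Count filopodia on an outline from its curvature profile.

    Candidate tips are maximal arcs with curvature >= ``min_tip_curvature``
    (1/µm).  A candidate is kept only if distinctly concave neck points
    (curvature below ``neck_curvature``, default ``-min_tip_curvature/4``)
    flank the arc on both sides and the apex protrudes at least
    ``min_length`` (µm) from the midpoint of the necks.  Returns
    (count, kept filopodia).
    """
    n = len(outline)
    if len(curvature) != n:
        raise ParameterError("curvature profile length does not match outline")
    if neck_curvature is None:
        neck_curvature = -min_tip_curvature / 4.0
    smoothed = smooth_outline(outline)
    pts_um = smoothed.points * outline.pixel_size
    high = curvature >= min_tip_curvature
    concave = curvature < neck_curvature

    kept: list[Filopodium] = []
    for run in _circular_runs(high):
        apex_local = int(np.argmax(curvature[run]))
        apex_idx = int(run[apex_local])
        neck_a = _nearest_true(concave, run[0], -1)
        neck_b = _nearest_true(concave, run[-1], +1)
        if neck_a is None or neck_b is None:
            continue
        base = (pts_um[neck_a] + pts_um[neck_b]) / 2.0
        length = float(np.hypot(*(pts_um[apex_idx] - base)))
        if length < min_length:
            continue
        kept.append(
            Filopodium(
                apex=(float(pts_um[apex_idx, 0]), float(pts_um[apex_idx, 1])),
                apex_index=apex_idx,
                length=length,
                tip_curvature=float(curvature[apex_idx]),
            )
        )
    return len(kept), kept


def _nearest_true(flag: np.ndarray, start: int, direction: int) -> int | None:
    """Index of the nearest True from ``start`` walking circularly."""
    n = len(flag)
    for step in range(1, n):
        i = (start + direction * step) % n
        if flag[i]:
            return i
    return None


# ---------------------------------------------------------------------------
# full per-mask measurement


def measure_mask(
    mask: BinaryMask,
    frame_index: int = 0,
    min_area: float = 0.0,
    smooth_sigma: float = SMOOTH_SIGMA,
    filo_min_length: float = FILO_MIN_LENGTH_UM,
    filo_min_tip_curvature: float = FILO_MIN_TIP_CURVATURE_UM,
    id_offset: int = 0,
) -> list[ShapeRecord]:
    """Run the full morphometry chain on one mask frame."""
    records = []
    for i, comp in enumerate(label_platelets(mask, min_area=min_area)):
        outline = trace_contour(comp)
        rec = shape_parameters(outline, comp,
                               platelet_id=id_offset + i, frame_index=frame_index)
        kappa = curvature_profile(outline, smooth_sigma=smooth_sigma)
        count, _ = count_filopodia(outline, kappa, min_length=filo_min_length,
                                   min_tip_curvature=filo_min_tip_curvature)
        rec.n_filopodia = count
        rec.curvature_profile = kappa
        records.append(rec)
    return records
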