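"""Centroid tracking and haptotactic-migration statistics.

Centroids of labelled platelets are linked frame-to-frame by mutual
nearest neighbours within a gating distance.  Tracks that do not span
the whole sequence are marked incomplete and excluded from metric
summaries.  Metrics: velocity (accumulated distance / time),
straightness (Euclidean / accumulated distance), and the mean cosine of
the directional change over a time interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BinaryMask, ParameterError, Track

log = logging.getLogger(__name__)

GATE_PX = 20.0  # default max centroid displacement per frame, pixels
EIGHT = np.ones((3, 3), dtype=bool)


def _frame_centroids(mask: BinaryMask) -> np.ndarray:
    """(n, 2) array of component centroids (x, y) in pixels, row-major order."""
    labels, n = ndimage.label(mask.pixels, structure=EIGHT)
    if n == 0:
        return np.empty((0, 2))
    cents = ndimage.center_of_mass(mask.pixels, labels, range(1, n + 1))
    pts = np.array([(cx, cy) for cy, cx in cents])
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]


def _mutual_nearest(prev: np.ndarray, cur: np.ndarray, gate: float
                    ) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs within the gate.

    Equidistant ambiguities resolve to the smaller index (deterministic,
    logged).
    """
    if len(prev) == 0 or len(cur) == 0:
        return []
    d = np.hypot(prev[:, None, 0] - cur[None, :, 0],
                 prev[:, None, 1] - cur[None, :, 1])
    links = []
    for i in range(len(prev)):
        j = int(np.argmin(d[i]))  # argmin takes the smallest index on ties
        if d[i, j] > gate:
            continue
        if int(np.argmin(d[:, j])) == i:
            ties = np.flatnonzero(d[i] == d[i, j])
            if len(ties) > 1:
                log.info("ambiguous link at distance %.3f; taking smaller id %d",
                         d[i, j], j)
            links.append((i, j))
    return links


def link_tracks(
    mask_sequence: list[BinaryMask],
    gate: float = GATE_PX,
    frame_interval: float = 30.0,
) -> list[Track]:
    """Link per-frame centroids into tracks.

    ``gate`` is in pixels per frame.  Returned track positions are in µm.
    Tracks not spanning every frame have ``complete=False``.
    """
    if len(mask_sequence) < 2:
        raise ParameterError("need at least 2 frames to link tracks")
    ps = mask_sequence[0].pixel_size
    frames = [_frame_centroids(m) for m in mask_sequence]

    # active track id -> list of positions; index maps per frame
    tracks: list[list[np.ndarray]] = [[p] for p in frames[0]]
    started: list[int] = [0] * len(frames[0])
    active = {i: i for i in range(len(frames[0]))}  # component idx -> track id

    for f in range(1, len(frames)):
        prev_pts = np.array([tracks[active[i]][-1] for i in sorted(active)]) \
            if active else np.empty((0, 2))
        prev_ids = [active[i] for i in sorted(active)]
        links = _mutual_nearest(prev_pts, frames[f], gate)
        new_active: dict[int, int] = {}
        matched_cur = set()
        for i, j in links:
            tid = prev_ids[i]
            tracks[tid].append(frames[f][j])
            new_active[j] = tid
            matched_cur.add(j)
        for j, p in enumerate(frames[f]):
            if j not in matched_cur:  # new appearance
                tracks.append([p])
                started.append(f)
                new_active[j] = len(tracks) - 1
        active = new_active

    n_frames = len(frames)
    out = []
    for tid, pos in enumerate(tracks):
        if len(pos) < 2:
            continue
        complete = started[tid] == 0 and len(pos) == n_frames
        out.append(Track(platelet_id=tid, frame_interval=frame_interval,
                         positions=np.array(pos) * ps, complete=complete))
    return out


# ---------------------------------------------------------------------------
# metrics


def _step_lengths(track: Track) -> np.ndarray:
    return np.hypot(*track.steps.T)


def accumulated_distance(track: Track) -> float:
    return float(_step_lengths(track).sum())


def migration_velocity(track: Track) -> float:
    """Accumulated distance divided by elapsed time, in µm/min."""
    if len(track) < 2:
        raise ParameterError("velocity needs at least 2 positions")
    minutes = (len(track) - 1) * track.frame_interval / 60.0
    return accumulated_distance(track) / minutes


def straightness(track: Track) -> float:
    """Euclidean distance / accumulated distance, in [0, 1].

    Undefined (ValueError) when the platelet never moved.
    """
    acc = accumulated_distance(track)
    if acc == 0:
        raise ParameterError("straightness undefined for zero accumulated distance")
    net = float(np.hypot(*(track.positions[-1] - track.positions[0])))
    return net / acc


def directional_change(track: Track, interval: float,
                       mode: str = "single_step") -> float:
    """Mean cos(theta) between directions separated by ``interval`` seconds.

    ``single_step`` (default) compares the one-frame displacement at the
    start of the interval with the one at its end; ``net`` compares net
    displacements over consecutive sub-intervals of that length.
    Zero-length displacements at interval boundaries are skipped.
    """
    k = int(round(interval / track.frame_interval))
    if k < 1:
        raise ParameterError("interval must be at least one frame interval")
    steps = track.steps
    if mode == "single_step":
        if len(steps) <= k:
            raise ParameterError("track too short for this interval")
        d0, d1 = steps[:-k], steps[k:]
    elif mode == "net":
        pos = track.positions
        nets = pos[k::k] - pos[:-k:k] if len(pos) > k else np.empty((0, 2))
        if len(nets) < 2:
            raise ParameterError("track too short for this interval")
        d0, d1 = nets[:-1], nets[1:]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    n0 = np.hypot(*d0.T)
    n1 = np.hypot(*d1.T)
    ok = (n0 > 0) & (n1 > 0)
    if not ok.any():
        raise ParameterError("no nonzero displacement pairs in this interval")
    if not ok.all():
        log.info("skipped %d zero-displacement interval(s)", int((~ok).sum()))
    cos = np.sum(d0[ok] * d1[ok], axis=1) / (n0[ok] * n1[ok])
    return float(np.mean(np.clip(cos, -1.0, 1.0)))


def directional_change_curve(track: Track, intervals: np.ndarray | None = None,
                             mode: str = "single_step"
                             ) -> list[tuple[float, float]]:
    """<cos theta> at a grid of intervals (default: up to half the duration)."""
    if intervals is None:
        half = (len(track) - 1) * track.frame_interval / 2.0
        n = max(1, int(half / track.frame_interval))
        intervals = track.frame_interval * np.arange(1, n + 1)
    return [(float(iv), directional_change(track, iv, mode=mode))
            for iv in intervals]


def align_initial_direction(tracks: list[Track]) -> list[Track]:
    """Rotate each track about its start so the first step points along +y.

    Rigid rotation: step lengths, straightness and velocity are
    preserved exactly.  Tracks with a zero initial displacement are
    returned unrotated (flagged in the log).
    """
    out = []
    for tr in tracks:
        first = tr.steps[0]
        norm = float(np.hypot(*first))
        if norm == 0:
            log.warning("track %d has zero initial displacement; not rotated",
                        tr.platelet_id)
            out.append(tr)
            continue
        # rotation taking `first` to (0, +norm)
        c = first[1] / norm
        s = first[0] / norm
        rot = np.array([[c, -s], [s, c]])
        rel = tr.positions - tr.positions[0]
        out.append(Track(platelet_id=tr.platelet_id,
                         frame_interval=tr.frame_interval,
                         positions=tr.positions[0] + rel @ rot.T,
                         complete=tr.complete))
    return out
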