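"""Spreading metrics from per-platelet area time series.

Idle time runs from adhesion (first frame the platelet is present) to
the first frame with >= 15% area increase over the adhesion-frame area;
the initial spreading rate is the least-squares slope of A(t) over the
2 minutes following the end of idle time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .types import ParameterError, ShapeRecord

IDLE_THRESHOLD = 0.15  # relative area increase ending the idle phase
RATE_WINDOW_S = 120.0  # fit window for the initial spreading rate


class AdhesionError(ValueError):
    """The platelet never appears in the trace."""


class TraceStatus(str, Enum):
    OK = "ok"
    CENSORED = "censored"      # area threshold never crossed
    TRUNCATED = "truncated"    # rate window extends past the trace end


@dataclass
class SpreadingTrace:
    """Time-ordered area measurements of one platelet.

    ``records`` may skip frames (platelet temporarily lost); frames must
    be strictly increasing.
    """

    platelet_id: int
    frame_interval: float  # seconds
    records: list[ShapeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        frames = [r.frame_index for r in self.records]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ParameterError("record frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([r.frame_index for r in self.records])

    @property
    def areas(self) -> np.ndarray:
        return np.array([r.area for r in self.records])

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval


@dataclass
class SpreadingMetrics:
    platelet_id: int
    adhesion_frame: int
    idle_time_s: float | None
    rate_um2_per_min: float | None
    status: TraceStatus


def detect_adhesion(trace: SpreadingTrace) -> int:
    """Frame index of first presence; all metrics are measured from it."""
    if not trace.records:
        raise AdhesionError(f"platelet {trace.platelet_id} never present")
    return trace.records[0].frame_index


def idle_time(trace: SpreadingTrace, threshold: float = IDLE_THRESHOLD
              ) -> float | None:
    """Seconds from adhesion to the first frame with A >= (1+threshold)*A0.

    The crossing is inclusive (exactly 15% counts).  Returns ``None``
    when the threshold is never crossed (censored trace).
    """
    adhesion = detect_adhesion(trace)
    areas = trace.areas
    target = (1.0 + threshold) * areas[0]
    crossed = np.flatnonzero(areas >= target)
    if len(crossed) == 0:
        return None
    return float((trace.frames[crossed[0]] - adhesion) * trace.frame_interval)


def initial_spreading_rate(
    trace: SpreadingTrace,
    threshold: float = IDLE_THRESHOLD,
    window_s: float = RATE_WINDOW_S,
) -> tuple[float | None, TraceStatus]:
    """Least-squares slope of A(t) over the post-idle window, in µm²/min.

    The window is closed on both ends: [idle_end, idle_end + window_s].
    Returns (rate, status); censored traces yield (None, CENSORED) and a
    window reaching past the trace end is computed on the available
    frames and flagged TRUNCATED.
    """
    idle = idle_time(trace, threshold=threshold)
    if idle is None:
        return None, TraceStatus.CENSORED
    adhesion_t = detect_adhesion(trace) * trace.frame_interval
    t0 = adhesion_t + idle
    t1 = t0 + window_s
    times = trace.times
    sel = (times >= t0) & (times <= t1)
    if sel.sum() < 2:
        return None, TraceStatus.TRUNCATED
    status = TraceStatus.OK
    if times[-1] < t1:
        status = TraceStatus.TRUNCATED
    t = times[sel] / 60.0  # minutes
    a = trace.areas[sel]
    slope = float(np.polyfit(t, a, 1)[0])
    return slope, status


def normalized_area_trace(trace: SpreadingTrace, t_ref: int) -> np.ndarray:
    """Per-frame A / A(t_ref); equals 1 at the reference frame."""
    frames = trace.frames
    match = np.flatnonzero(frames == t_ref)
    if len(match) == 0:
        raise ParameterError(f"reference frame {t_ref} not in trace")
    a0 = trace.areas[match[0]]
    if a0 <= 0:
        raise ParameterError("reference-frame area must be positive")
    return trace.areas / a0


def spreading_metrics(trace: SpreadingTrace,
                      threshold: float = IDLE_THRESHOLD,
                      window_s: float = RATE_WINDOW_S) -> SpreadingMetrics:
    """Bundle adhesion frame, idle time and initial rate with a status."""
    adhesion = detect_adhesion(trace)
    idle = idle_time(trace, threshold=threshold)
    if idle is None:
        return SpreadingMetrics(trace.platelet_id, adhesion, None, None,
                                TraceStatus.CENSORED)
    rate, status = initial_spreading_rate(trace, threshold=threshold,
                                          window_s=window_s)
    return SpreadingMetrics(trace.platelet_id, adhesion, idle, rate, status)
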