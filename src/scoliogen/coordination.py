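"""Bilateral calcium-signal coordination and swim-trajectory kinematics.

Left and right hindbrain/spinal GCaMP fluorescence traces are normalized
to F_t / F_min per channel (so each normalized channel has minimum exactly
1), calcium events are detected as upward threshold crossings with a
refractory period, and left-right coordination is summarized as the
log-ratio log(f_left / f_right) of event frequencies: 0 means symmetric
activation, positive means left-dominant.

Swim trajectories (centroid tracks) are summarized by total distance,
mean velocity, and turning statistics; the signed turning angle per step
is the heading change between consecutive displacement vectors wrapped to
(-180, 180] degrees with leftward (counter-clockwise) turns positive. The
*relative* turning angle is the running sum of signed turns, so a
direction-unbiased swimmer scores near 0 while a fish that favours one
side accumulates a large positive (left) or negative (right) total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BilateralTrace:
    """Uniformly sampled left/right fluorescence intensity series."""

    time: np.ndarray  # seconds
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if not (self.time.size == self.left.size == self.right.size):
            raise ValueError("time/left/right lengths differ")
        if self.time.size < 2:
            raise ValueError("trace needs at least two frames")

    @property
    def fps(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "left": self.left, "right": self.right})


@dataclass
class EventSeries:
    """Detected (or ground-truth) calcium event times per channel."""

    left_times: np.ndarray  # seconds
    right_times: np.ndarray
    duration: float  # seconds

    def __post_init__(self) -> None:
        self.left_times = np.asarray(self.left_times, dtype=float)
        self.right_times = np.asarray(self.right_times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def f_left(self) -> float:
        return self.left_times.size / self.duration

    @property
    def f_right(self) -> float:
        return self.right_times.size / self.duration


class LogRatioResult(NamedTuple):
    """log(f_left / f_right); ``value`` is None when a side has no events."""

    value: Optional[float]
    reason: Optional[str] = None


def normalize_trace(trace: BilateralTrace) -> BilateralTrace:
    """Divide each channel by its own minimum (F_t / F_min).

    Idempotent; each normalized channel has minimum exactly 1 and the
    result is invariant to rescaling a raw channel by any c > 0.
    """
    if trace.left.min() <= 0 or trace.right.min() <= 0:
        raise ValueError("fluorescence intensities must be positive")
    return BilateralTrace(
        trace.time.copy(),
        trace.left / trace.left.min(),
        trace.right / trace.right.min(),
    )


def _crossings(signal: np.ndarray, time: np.ndarray, threshold: float,
               refractory: float) -> np.ndarray:
    above = signal > threshold
    up = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:  # already above threshold at the first frame
        up = np.concatenate([[0], up])
    times = []
    last = -math.inf
    for i in up:
        t = time[i]
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


def detect_events(
    trace: BilateralTrace,
    threshold: float = 1.5,
    refractory: float = 0.5,
) -> EventSeries:
    """Threshold-crossing event detector on a normalized trace.

    An event is an upward crossing of ``threshold`` (fold-change over the
    per-channel minimum); crossings within ``refractory`` seconds of the
    previous accepted event are ignored. Event frequency = count/duration.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1 (fold-change over baseline)")
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    norm = normalize_trace(trace)
    return EventSeries(
        _crossings(norm.left, norm.time, threshold, refractory),
        _crossings(norm.right, norm.time, threshold, refractory),
        norm.duration,
    )


def lr_frequency_ratio(events: EventSeries, base: float = math.e) -> LogRatioResult:
    """Log-transformed left/right event-frequency ratio.

    0 iff the two sides fire at the same rate; swapping channels negates
    the value; the value does not depend on the time unit. A side with no
    events makes the ratio undefined and is flagged rather than computed.
    """
    if base <= 0 or base == 1.0:
        raise ValueError("log base must be positive and != 1")
    if events.f_left == 0 or events.f_right == 0:
        side = "left" if events.f_left == 0 else "right"
        return LogRatioResult(None, f"no events on {side} channel: ratio undefined")
    return LogRatioResult(math.log(events.f_left / events.f_right, base))


@dataclass
class TrajectorySummary:
    """Kinematic summary of one centroid track."""

    total_distance_mm: float
    mean_velocity_mm_s: float
    relative_angle_deg: float  # signed sum of turns, left positive
    mean_abs_angle_deg: float
    mean_abs_angular_velocity_deg_s: float
    n_turns: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def turning_statistics(traj: pd.DataFrame) -> TrajectorySummary:
    """Distance, velocity and turning-angle statistics of a 2-D track.

    ``traj`` must have columns time, x, y with strictly increasing time.
    Headings come from consecutive displacement vectors; zero-length steps
    carry no direction and are skipped (logged). The signed turn per step
    is wrapped to (-180, 180] with leftward turns positive; the relative
    angle is the sum of signed turns; angular velocity averages
    |turn| / dt over the turns.
    """
    t = np.asarray(traj["time"], dtype=float)
    x = np.asarray(traj["x"], dtype=float)
    y = np.asarray(traj["y"], dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples for turning statistics")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy)
    total_distance = float(steps.sum())
    duration = float(t[-1] - t[0])
    moving = steps > 0
    if not np.all(moving):
        logger.info("skipping %d zero-length steps", int((~moving).sum()))
    headings = np.arctan2(dy[moving], dx[moving])
    step_end_times = t[1:][moving]
    if headings.size < 2:
        return TrajectorySummary(total_distance, total_distance / duration,
                                 0.0, 0.0, 0.0, 0)
    dtheta = np.diff(headings)
    # wrap to (-pi, pi]; counter-clockwise (leftward) positive
    dtheta = np.where(dtheta > np.pi, dtheta - 2 * np.pi, dtheta)
    dtheta = np.where(dtheta <= -np.pi, dtheta + 2 * np.pi, dtheta)
    dt = np.diff(step_end_times)
    deg = np.degrees(dtheta)
    return TrajectorySummary(
        total_distance_mm=total_distance,
        mean_velocity_mm_s=total_distance / duration,
        relative_angle_deg=float(deg.sum()),
        mean_abs_angle_deg=float(np.abs(deg).mean()),
        mean_abs_angular_velocity_deg_s=float((np.abs(deg) / dt).mean()),
        n_turns=int(deg.size),
    )
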