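"""Allocentric neck movement speed from pose tracks.

The animal's neck point, tracked per video frame in arena (world)
coordinates, is differenced frame-to-frame to obtain movement speed in
cm/s.  Speed is floored before taking log2 so that stationary frames map
to a finite value, and frames below 3 cm/s are flagged as stationary.
Sessions dominated by stationary behaviour (stationary fraction strictly
greater than 2/3) can be selected for the stationary-activity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Frames with neck speed below this value (cm/s) count as stationary.
STATIONARY_THRESHOLD_CM_S = 3.0

#: Default floor (cm/s) applied before log2; roughly one pixel of tracking
#: jitter per frame at 30 Hz.
DEFAULT_LOG_FLOOR = 0.25

#: Pose-estimation likelihood below which a frame is treated as a dropout.
DEFAULT_LIKELIHOOD_THRESHOLD = 0.9


@dataclass
class PoseTrack:
    """Neck position per video frame, in calibrated cm."""

    time_s: np.ndarray
    neck_x: np.ndarray
    neck_y: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.neck_x = np.asarray(self.neck_x, dtype=float)
        self.neck_y = np.asarray(self.neck_y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.time_s)
        if not (len(self.neck_x) == len(self.neck_y) == len(self.likelihood) == n):
            raise ValueError("PoseTrack fields must have equal length")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class SpeedSeries:
    """Per-frame speed, log2-speed and stationary mask."""

    speed: np.ndarray
    logspeed: np.ndarray
    stationary_mask: np.ndarray
    epsilon: float = DEFAULT_LOG_FLOOR
    threshold: float = STATIONARY_THRESHOLD_CM_S

    def __len__(self) -> int:
        return len(self.speed)

    @property
    def stationary_fraction(self) -> float:
        return float(np.mean(self.stationary_mask))


def interpolate_low_likelihood(
    pose: PoseTrack, likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD
) -> PoseTrack:
    """Replace low-likelihood frames by linear interpolation between valid neighbours.

    Leading/trailing runs of bad frames are held at the nearest valid value.
    Raises if no frame reaches the threshold.
    """
    good = pose.likelihood >= likelihood_threshold
    n_good = int(np.count_nonzero(good))
    if n_good == 0:
        raise ValueError("all frames below likelihood threshold; nothing to interpolate from")
    if n_good == len(pose):
        return pose
    idx = np.arange(len(pose), dtype=float)
    x = np.interp(idx, idx[good], pose.neck_x[good])
    y = np.interp(idx, idx[good], pose.neck_y[good])
    return PoseTrack(pose.time_s, x, y, pose.likelihood.copy())


def log2_with_floor(speed: np.ndarray, epsilon: float = DEFAULT_LOG_FLOOR) -> np.ndarray:
    """log2(max(speed, epsilon)); strictly monotone above the floor."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return np.log2(np.maximum(np.asarray(speed, dtype=float), epsilon))


def neck_speed(
    pose: PoseTrack,
    frame_rate: float,
    epsilon: float = DEFAULT_LOG_FLOOR,
    threshold: float = STATIONARY_THRESHOLD_CM_S,
    median_filter: bool = False,
) -> SpeedSeries:
    """Frame-to-frame neck speed in cm/s.

    speed[i] = ||r[i] - r[i-1]|| * frame_rate, with speed[0] = speed[1].
    Optionally applies a 3-frame median filter to the positions first
    (off by default).
    """
    x, y = pose.neck_x, pose.neck_y
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite coordinates in pose track")
    if median_filter:
        from scipy.ndimage import median_filter as _mf

        x = _mf(x, size=3, mode="nearest")
        y = _mf(y, size=3, mode="nearest")
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy) * frame_rate
    speed = np.empty(len(pose), dtype=float)
    if len(pose) == 1:
        speed[:] = 0.0
    else:
        speed[1:] = step
        speed[0] = step[0]
    return SpeedSeries(
        speed=speed,
        logspeed=log2_with_floor(speed, epsilon),
        stationary_mask=speed < threshold,
        epsilon=epsilon,
        threshold=threshold,
    )


def stationary_session_filter(sessions, fraction_threshold: float = 2.0 / 3.0):
    """Sessions whose stationary-frame fraction strictly exceeds the threshold.

    ``sessions`` is any iterable of objects exposing a ``stationary_fraction``
    attribute (e.g. :class:`SpeedSeries` or aligned sessions).
    """
    return [s for s in sessions if s.stationary_fraction > fraction_threshold]


def calibrate_pixels_to_cm(
    pixel_extent: float, arena_width_cm: float
) -> float:
    """Linear pixel-to-cm scale from the observed wall-to-wall extent."""
    if pixel_extent <= 0 or arena_width_cm <= 0:
        raise ValueError("extents must be positive")
    return arena_width_cm / pixel_extent
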