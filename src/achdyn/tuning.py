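"""Speed-tuning curves of cholinergic activity.

Builds tuning curves of z-scored dF/F against speed or log2-speed and
fits the two descriptive models used for open-field cholinergic data:
a saturating exponential in raw speed, and an ordinary linear fit in
log2-speed (the latter is the better description: activity is linear in
the logarithm of speed across the whole range, including stationary
neck movements).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class AlignedSession:
    """Frame-aligned z-dF/F, speed and behaviour labels for one session."""

    animal_id: str
    session_id: str
    lighting: str  # "light" or "dark"
    frame_time: np.ndarray
    zdff: np.ndarray
    speed: np.ndarray
    logspeed: np.ndarray
    community: np.ndarray  # integer label per frame

    def __post_init__(self) -> None:
        n = len(self.frame_time)
        for name in ("zdff", "speed", "logspeed", "community"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from frame_time")
        if self.lighting not in ("light", "dark"):
            raise ValueError("lighting must be 'light' or 'dark'")

    def __len__(self) -> int:
        return len(self.frame_time)

    @property
    def stationary_fraction(self) -> float:
        from achdyn.kinematics import STATIONARY_THRESHOLD_CM_S

        return float(np.mean(self.speed < STATIONARY_THRESHOLD_CM_S))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "session_id": self.session_id,
                "lighting": self.lighting,
                "frame_time": self.frame_time,
                "zdff": self.zdff,
                "speed": self.speed,
                "logspeed": self.logspeed,
                "community": self.community,
            }
        )


@dataclass
class TuningCurve:
    """Binned mean +/- SEM of z-dF/F vs. (log-)speed."""

    bin_edges: np.ndarray
    bin_mean: np.ndarray
    bin_sem: np.ndarray
    bin_n: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def sample_interval(
    x: np.ndarray, z: np.ndarray, frame_time: np.ndarray, interval: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample (x, z) at the frame nearest each multiple of ``interval``.

    Sampling the scatter at 1-s intervals decorrelates consecutive points
    relative to the 30 Hz frame clock.
    """
    t = np.asarray(frame_time, dtype=float)
    t0 = t[0]
    dt_frame = np.median(np.diff(t)) if len(t) > 1 else interval
    if interval < dt_frame - 1e-12:
        raise ValueError("interval must be at least one frame")
    targets = np.arange(t0, t[-1] + 1e-9, interval)
    idx = np.searchsorted(t, targets)
    idx = np.clip(idx, 0, len(t) - 1)
    left = np.clip(idx - 1, 0, len(t) - 1)
    use_left = np.abs(t[left] - targets) <= np.abs(t[idx] - targets)
    idx = np.where(use_left, left, idx)
    idx = np.unique(idx)
    return np.asarray(x)[idx], np.asarray(z)[idx]


def bin_tuning_curve(
    x: np.ndarray, z: np.ndarray, bin_width: float, min_count: int = 5
) -> TuningCurve:
    """Half-open bins [k*w, (k+1)*w); bins with fewer than min_count points
    are reported empty (NaN mean/SEM)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    k_lo = int(np.floor(x.min() / bin_width))
    k_hi = int(np.floor(x.max() / bin_width)) + 1
    edges = np.arange(k_lo, k_hi + 1) * bin_width
    which = np.floor(x / bin_width).astype(int) - k_lo
    n_bins = len(edges) - 1
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=z, minlength=n_bins)
    sq = np.bincount(which, weights=z * z, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    ok = counts >= max(min_count, 1)
    mean[ok] = sums[ok] / counts[ok]
    var = np.zeros(n_bins)
    multi = ok & (counts > 1)
    var[multi] = (sq[multi] - counts[multi] * mean[multi] ** 2) / (counts[multi] - 1)
    var = np.maximum(var, 0.0)
    sem[ok] = np.sqrt(var[ok] / counts[ok])
    return TuningCurve(bin_edges=edges, bin_mean=mean, bin_sem=sem, bin_n=counts)


def fit_linear_log(x: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of z on log-speed x; returns (slope, intercept, r).

    Pearson's r of a zero-variance response is defined as 0 (with a warning).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    var_x = float(np.var(x))
    if var_x == 0.0:
        raise ValueError("zero variance in x")
    slope = float(np.cov(x, z, bias=True)[0, 1] / var_x)
    intercept = float(np.mean(z) - slope * np.mean(x))
    var_z = float(np.var(z))
    if var_z == 0.0:
        warnings.warn("zero-variance response; Pearson r reported as 0")
        r = 0.0
    else:
        r = float(np.corrcoef(x, z)[0, 1])
    return slope, intercept, r


def _sat_exp(speed, y_inf, amplitude, tau):
    return y_inf - amplitude * np.exp(-speed / tau)


def fit_saturating_exponential(
    speed: np.ndarray,
    z: np.ndarray,
    tau_starts: tuple[float, ...] = (1.0, 5.0, 20.0),
) -> tuple[float, float, float, bool]:
    """Nonlinear least squares of z = y_inf - A*exp(-speed/tau).

    Multi-start over ``tau_starts`` (cm/s); the best-SSE converged start
    wins.  Returns (y_inf, amplitude, tau, converged).
    """
    speed = np.asarray(speed, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(speed) < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(speed) <= 0:
        raise ValueError("speed range must be positive")
    best = None
    for tau0 in tau_starts:
        p0 = (float(np.max(z)), float(np.ptp(z)) or 1.0, tau0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_sat_exp, speed, z, p0=p0, maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((z - _sat_exp(speed, *popt)) ** 2))
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt)
    if best is None:
        raise RuntimeError("saturating-exponential fit failed from all starts")
    y_inf, amplitude, tau = best[1]
    return float(y_inf), float(amplitude), float(tau), True


def aggregate_curves(
    curves_by_condition: dict[str, list[TuningCurve]],
) -> dict[str, TuningCurve]:
    """Across-session mean +/- SEM of session-level bin means per condition.

    All curves within a condition must share bin width; curves are aligned
    on their absolute bin edges.
    """
    out: dict[str, TuningCurve] = {}
    for cond, curves in curves_by_condition.items():
        if not curves:
            raise ValueError(f"no sessions for condition {cond!r}")
        width = curves[0].bin_edges[1] - curves[0].bin_edges[0]
        k_lo = min(int(round(c.bin_edges[0] / width)) for c in curves)
        k_hi = max(int(round(c.bin_edges[-1] / width)) for c in curves)
        edges = np.arange(k_lo, k_hi + 1) * width
        n_bins = len(edges) - 1
        stacked = np.full((len(curves), n_bins), np.nan)
        for i, c in enumerate(curves):
            off = int(round(c.bin_edges[0] / width)) - k_lo
            stacked[i, off : off + len(c.bin_mean)] = c.bin_mean
        n_sess = np.sum(np.isfinite(stacked), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean = np.nanmean(stacked, axis=0)
            sd = np.nanstd(stacked, axis=0, ddof=1)
        sem = np.where(n_sess > 1, sd / np.sqrt(np.maximum(n_sess, 1)), 0.0)
        mean[n_sess == 0] = np.nan
        sem[n_sess == 0] = np.nan
        out[cond] = TuningCurve(bin_edges=edges, bin_mean=mean, bin_sem=sem, bin_n=n_sess)
    return out
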