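"""Two-channel fiber-photometry preprocessing.

Converts a raw 500 Hz recording with a calcium-dependent channel (473 nm
excitation, ``f470``) and an isosbestic control channel (405 nm, ``f405``)
into a frame-aligned, z-scored dF/F trace:

1. both channels are resampled to the video frame clock given by the TTL
   frame timestamps (within-window mean);
2. the control is adjusted for the differential bleaching of the two
   channels: a 2nd-degree polynomial is fitted to (signal - control) over
   time and added back to the control;
3. a scale/offset pair (alpha, beta) is fitted by least squares so that
   alpha*c + beta best matches the signal;
4. dF/F = (s - (c*alpha + beta)) / (c*alpha + beta);
5. the dF/F trace is z-scored within the session so that sessions with
   different expression levels and laser power can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Relative tolerance for the dF/F denominator guard.
DENOMINATOR_GUARD = 1e-6


@dataclass
class RawPhotometry:
    """One session of raw two-channel photometry plus video TTL times."""

    time_s: np.ndarray
    f470: np.ndarray
    f405: np.ndarray
    ttl_frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f470 = np.asarray(self.f470, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        self.ttl_frame_times = np.asarray(self.ttl_frame_times, dtype=float)
        if not (len(self.time_s) == len(self.f470) == len(self.f405)):
            raise ValueError("channel lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if len(self.ttl_frame_times) < 2:
            raise ValueError("need at least 2 TTL frame times")

    @property
    def n_frames(self) -> int:
        return len(self.ttl_frame_times)


@dataclass
class DffTrace:
    """Frame-aligned dF/F with the fit parameters that produced it."""

    frame_time: np.ndarray
    dff: np.ndarray
    zdff: np.ndarray
    alpha: float
    beta: float
    poly_coeffs: np.ndarray  # power-basis coefficients, ascending


def resample_to_frames(raw: RawPhotometry) -> tuple[np.ndarray, np.ndarray]:
    """Average each channel within consecutive TTL frame windows.

    Frame ``i`` covers samples with time in ``[t_i, t_{i+1})``; the last
    frame's window extends by the median inter-frame interval.  Returns
    per-frame ``(f470, f405)`` arrays, one value per TTL frame.
    """
    t = raw.time_s
    ft = raw.ttl_frame_times
    median_dt = float(np.median(np.diff(ft)))
    edges = np.concatenate([ft, [ft[-1] + median_dt]])
    idx = np.searchsorted(t, edges, side="left")
    counts = np.diff(idx)
    if np.any(counts == 0):
        bad = np.nonzero(counts == 0)[0]
        raise ValueError(f"no photometry samples in frame window(s) {bad.tolist()[:10]}")
    c470 = np.concatenate([[0.0], np.cumsum(raw.f470)])
    c405 = np.concatenate([[0.0], np.cumsum(raw.f405)])
    sums470 = c470[idx[1:]] - c470[idx[:-1]]
    sums405 = c405[idx[1:]] - c405[idx[:-1]]
    return sums470 / counts, sums405 / counts


def adjust_control(
    s: np.ndarray, c_raw: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bleaching adjustment of the isosbestic control.

    Fits a 2nd-degree polynomial to ``d = s - c_raw`` as a function of time
    (centred/scaled internally for conditioning) and returns
    ``(c_adj, poly_coeffs)`` with ``c_adj = c_raw + p(t)``.  ``poly_coeffs``
    are ascending power-basis coefficients in unscaled time.
    """
    s = np.asarray(s, dtype=float)
    c_raw = np.asarray(c_raw, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 frames to fit a 2nd-degree polynomial")
    d = s - c_raw
    poly = np.polynomial.Polynomial.fit(t, d, deg=2)
    c_adj = c_raw + poly(t)
    return c_adj, poly.convert().coef


def fit_scale_offset(s: np.ndarray, c_adj: np.ndarray) -> tuple[float, float]:
    """Least-squares (alpha, beta) minimising sum((s - (c*alpha + beta))^2).

    Closed form: alpha = cov(c, s)/var(c), beta = mean(s) - alpha*mean(c).
    """
    s = np.asarray(s, dtype=float)
    c = np.asarray(c_adj, dtype=float)
    var_c = float(np.var(c))
    if var_c == 0.0:
        raise ValueError("degenerate control: var(c_adj) = 0")
    alpha = float(np.cov(c, s, bias=True)[0, 1] / var_c)
    beta = float(np.mean(s) - alpha * np.mean(c))
    return alpha, beta


def compute_dff(
    s: np.ndarray, c_adj: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """dF/F = (s - (c*alpha + beta)) / (c*alpha + beta), with a zero guard."""
    s = np.asarray(s, dtype=float)
    den = np.asarray(c_adj, dtype=float) * alpha + beta
    tol = DENOMINATOR_GUARD * float(np.median(np.abs(den)))
    bad = np.abs(den) <= tol
    if np.any(bad):
        frames = np.nonzero(bad)[0]
        raise ValueError(
            f"dF/F denominator within tolerance of zero at frame(s) {frames.tolist()[:10]}"
        )
    return (s - den) / den


def zscore_session(dff: np.ndarray) -> np.ndarray:
    """Within-session z-score with sample (n-1) standard deviation."""
    x = np.asarray(dff, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant trace")
    return (x - np.mean(x)) / sd


def process_session(raw: RawPhotometry) -> DffTrace:
    """Full preprocessing chain: resample, adjust, fit, dF/F, z-score."""
    s, c_raw = resample_to_frames(raw)
    t = raw.ttl_frame_times
    c_adj, coeffs = adjust_control(s, c_raw, t)
    alpha, beta = fit_scale_offset(s, c_adj)
    dff = compute_dff(s, c_adj, alpha, beta)
    return DffTrace(
        frame_time=t,
        dff=dff,
        zdff=zscore_session(dff),
        alpha=alpha,
        beta=beta,
        poly_coeffs=coeffs,
    )


def uncorrected_dff(raw: RawPhotometry) -> np.ndarray:
    """dF/F with the correction skipped (raw control, alpha=1, beta=0).

    Reference for quantifying how much artifact/bleach variance the
    isosbestic correction removes.
    """
    s, c_raw = resample_to_frames(raw)
    return compute_dff(s, c_raw, 1.0, 0.0)
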