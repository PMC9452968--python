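"""Integration-window statistics of cholinergic activity.

How fast does the cholinergic signal track movement speed?  The activity
trace is smoothed with centred boxcar windows of increasing width and the
Pearson correlation with log2(speed) is recorded per width; the width that
maximises the correlation is the session's optimal integration window.
Cohort-level summaries and light/dark comparisons (two-sample t-test on
the correlation at a reference window, Kolmogorov-Smirnov test on the
optimal-window distributions) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Reference window (s) for the light/dark t-test: the cohort-level optimum.
REFERENCE_WINDOW_S = 1.3


def default_window_grid(frame_rate: float, max_window_s: float = 10.0) -> np.ndarray:
    """1 frame to ``max_window_s`` in 1-frame steps, in seconds."""
    n = int(round(max_window_s * frame_rate))
    return np.arange(1, n + 1) / frame_rate


@dataclass
class WindowScan:
    """Correlation-vs-window curve and the per-session optimum."""

    window_grid: np.ndarray  # s
    r_per_window: np.ndarray
    optimal_window: float  # s
    session_id: str = ""


def moving_average(z: np.ndarray, window_s: float, frame_rate: float) -> np.ndarray:
    """Centred boxcar mean of width round(window_s * frame_rate), forced odd.

    Edges use truncated (shrinking) windows so the output length matches
    the input.
    """
    z = np.asarray(z, dtype=float)
    w = int(round(window_s * frame_rate))
    if w < 1:
        raise ValueError("window must be at least one frame")
    if w % 2 == 0:
        w += 1
    if w > len(z):
        raise ValueError("window longer than the session")
    if w == 1:
        return z.copy()
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(z)])
    n = len(z)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def window_scan(
    z: np.ndarray,
    logspeed: np.ndarray,
    grid: np.ndarray,
    frame_rate: float,
    session_id: str = "",
) -> WindowScan:
    """Pearson r between boxcar-smoothed activity and log-speed per window.

    Only the activity is smoothed.  The optimal window is the argmax of r;
    ties break toward the smallest window.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(logspeed, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and sorted")
    if np.std(z) == 0 or np.std(x) == 0:
        raise ValueError("zero-variance series")
    r = np.empty(len(grid))
    for i, w_s in enumerate(grid):
        sm = moving_average(z, w_s, frame_rate)
        sd = np.std(sm)
        if sd == 0:
            r[i] = 0.0
        else:
            r[i] = np.corrcoef(sm, x)[0, 1]
    best = int(np.argmax(r))  # argmax takes the first (smallest-w) maximum
    return WindowScan(
        window_grid=grid,
        r_per_window=r,
        optimal_window=float(grid[best]),
        session_id=session_id,
    )


def cohort_window_summary(
    scans: list[WindowScan], hist_bin_width: float = 0.2
) -> dict:
    """Across-session mean +/- SEM of r(w) and a histogram of per-session optima."""
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    grid = scans[0].window_grid
    for s in scans[1:]:
        if len(s.window_grid) != len(grid) or not np.allclose(s.window_grid, grid):
            raise ValueError("scans must share a common window grid")
    r = np.vstack([s.r_per_window for s in scans])
    optima = np.array([s.optimal_window for s in scans])
    n_bins = int(np.ceil((optima.max() + 1e-9) / hist_bin_width)) or 1
    edges = np.arange(n_bins + 1) * hist_bin_width
    hist, _ = np.histogram(optima, bins=edges)
    return {
        "window_grid": grid,
        "mean_r": r.mean(axis=0),
        "sem_r": r.std(axis=0, ddof=1) / np.sqrt(len(scans)),
        "optima": optima,
        "hist_edges": edges,
        "hist_counts": hist,
    }


def compare_light_dark(
    scans_light: list[WindowScan],
    scans_dark: list[WindowScan],
    reference_window: float = REFERENCE_WINDOW_S,
) -> dict:
    """Light-vs-dark comparison of temporal dynamics.

    Pooled-variance two-sample t-test (df = n1 + n2 - 2) on r at the
    reference window, and a two-sample Kolmogorov-Smirnov test on the
    distributions of per-session optimal windows.
    """
    if len(scans_light) < 2 or len(scans_dark) < 2:
        raise ValueError("need at least 2 sessions per group")

    def r_at(scans):
        out = []
        for s in scans:
            i = int(np.argmin(np.abs(s.window_grid - reference_window)))
            out.append(s.r_per_window[i])
        return np.array(out)

    r_l, r_d = r_at(scans_light), r_at(scans_dark)
    t_res = stats.ttest_ind(r_l, r_d, equal_var=True)
    opt_l = np.array([s.optimal_window for s in scans_light])
    opt_d = np.array([s.optimal_window for s in scans_dark])
    ks_res = stats.ks_2samp(opt_l, opt_d)
    return {
        "t": float(t_res.statistic),
        "df": len(r_l) + len(r_d) - 2,
        "p": float(t_res.pvalue),
        "ks_stat": float(ks_res.statistic),
        "ks_p": float(ks_res.pvalue),
        "reference_window": reference_window,
        "mean_r_light": float(r_l.mean()),
        "mean_r_dark": float(r_d.mean()),
    }
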