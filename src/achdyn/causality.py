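"""Multi-trial bivariate Granger causality between log-speed and z-dF/F.

A series x Granger-causes y if x's past improves the prediction of y
beyond y's own past.  The magnitude is the log residual-variance ratio of
the reduced (own lags only) and full bivariate VAR models,

    F_{x->y} = ln( SSR_reduced / SSR_full ),

fitted by OLS on a lagged design stacked across trials (sessions of one
animal are treated as trials; lags never leak across trial boundaries).
Significance uses the large-sample likelihood-ratio form
n_eff * F ~ chi2(p) under the null.  Analysis is restricted to the first
5 minutes of each session so sessions are statistically comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Default maximum model order for AIC selection (~1 s at 30 Hz).
DEFAULT_P_MAX = 30

#: Channel order in every trial array: column 0 = log-speed, column 1 = z-dF/F.
SPEED, ACH = 0, 1


@dataclass
class VARFit:
    """Bivariate VAR(p) fitted by stacked multi-trial OLS."""

    order: int
    coef: np.ndarray  # (p, 2, 2); coef[k, i, j] = effect of channel j at lag k+1 on channel i
    sigma: np.ndarray  # residual covariance, denominator n_eff - 2p - 1
    n_eff: int
    ssr: np.ndarray  # per-equation residual sum of squares
    se_coef: np.ndarray  # (p, 2, 2) OLS standard errors

    @property
    def resid_var(self) -> np.ndarray:
        return np.diag(self.sigma)


def truncate_first_minutes(
    logspeed: np.ndarray,
    zdff: np.ndarray,
    frame_rate: float,
    minutes: float = 5.0,
) -> np.ndarray:
    """First ``minutes`` of a session as a (n, 2) trial array, mean-removed.

    Shorter sessions are used whole (with a warning).  Column order is
    (log-speed, z-dF/F).
    """
    n_keep = int(round(minutes * 60.0 * frame_rate))
    n = len(logspeed)
    if n < n_keep:
        warnings.warn(
            f"session shorter than {minutes} min ({n} frames); using the whole session"
        )
        n_keep = n
    trial = np.column_stack([logspeed[:n_keep], zdff[:n_keep]]).astype(float)
    return trial - trial.mean(axis=0)


def _stack_lagged(trials, p: int, start: int | None = None):
    """Stacked (Y, X) design: X rows are [lag1 ch0, lag1 ch1, lag2 ch0, ...].

    ``start`` sets the first usable index within each trial (defaults to p);
    passing p_max gives a common effective sample across orders.
    """
    if start is None:
        start = p
    ys, xs = [], []
    for tr in trials:
        tr = np.asarray(tr, dtype=float)
        n = len(tr)
        if n <= start + 10:
            raise ValueError(f"trial length {n} too short for order {p}")
        ys.append(tr[start:])
        cols = [tr[start - k : n - k] for k in range(1, p + 1)]
        xs.append(np.concatenate(cols, axis=1))
    return np.concatenate(ys), np.concatenate(xs)


def fit_var_multitrial(trials, p: int) -> VARFit:
    """OLS fit of a bivariate VAR(p) on trials stacked without lag leakage."""
    if p < 1:
        raise ValueError("order must be >= 1")
    Y, X = _stack_lagged(trials, p)
    n_eff = len(Y)
    B, res, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular lagged design")
    resid = Y - X @ B
    ssr = np.sum(resid**2, axis=0)
    dof = n_eff - 2 * p - 1
    sigma = resid.T @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(xtx_inv), np.diag(sigma)))
    # B is (2p, 2): rows ordered lag-major, channel-minor; reshape to (p, 2, 2)
    coef = B.reshape(p, 2, 2).transpose(0, 2, 1)
    se_coef = se.reshape(p, 2, 2).transpose(0, 2, 1)
    return VARFit(
        order=p, coef=coef, sigma=sigma, n_eff=n_eff, ssr=ssr, se_coef=se_coef
    )


def select_order(trials, p_max: int, criterion: str = "aic") -> int:
    """Order minimising AIC (or BIC) over 1..p_max on a common sample."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    best_p, best_val = 1, np.inf
    for p in range(1, p_max + 1):
        val = information_criterion(trials, p, p_max, criterion)
        if val < best_val:
            best_p, best_val = p, val
    return best_p


def information_criterion(
    trials, p: int, start: int, criterion: str = "aic"
) -> float:
    """Gaussian AIC/BIC of a VAR(p) on the common sample starting at ``start``."""
    Y, X = _stack_lagged(trials, p, start=start)
    n = len(Y)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    sigma_ml = resid.T @ resid / n
    sign, logdet = np.linalg.slogdet(sigma_ml)
    if sign <= 0:
        return np.inf
    k = 4 * p  # free VAR coefficients (2x2 per lag)
    if criterion == "aic":
        return n * logdet + 2 * k
    if criterion == "bic":
        return n * logdet + k * np.log(n)
    raise ValueError(f"unknown criterion {criterion!r}")


def _reduced_ssr(trials, p: int, target: int) -> tuple[float, int]:
    """SSR of the target channel on its own p lags, on the full-model sample."""
    Y, X = _stack_lagged(trials, p)
    own_cols = [2 * k + target for k in range(p)]
    Xr = X[:, own_cols]
    y = Y[:, target]
    b, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    resid = y - Xr @ b
    return float(np.sum(resid**2)), len(y)


def gc_magnitude(trials, p: int, direction: str = "speed->ach") -> float:
    """Granger-causality magnitude in nats for one direction.

    ``direction`` is ``"speed->ach"`` or ``"ach->speed"``; the target
    channel's reduced (own-lags) and full residual sums of squares are
    computed on the identical stacked sample.
    """
    full = fit_var_multitrial(trials, p)
    return _gc_from_full(trials, full, direction)


def _gc_from_full(trials, full: VARFit, direction: str) -> float:
    target = ACH if direction == "speed->ach" else SPEED
    if direction not in ("speed->ach", "ach->speed"):
        raise ValueError(f"unknown direction {direction!r}")
    ssr_red, _ = _reduced_ssr(trials, full.order, target)
    ssr_full = full.ssr[target]
    if ssr_full <= 0 or ssr_red <= 0:
        raise FloatingPointError("non-positive residual sum of squares")
    f = np.log(ssr_red / ssr_full)
    if f < -1e-12:
        raise FloatingPointError("reduced model fit better than full model")
    return float(max(f, 0.0))


def gc_significance(magnitude: float, n_eff: int, p: int) -> float:
    """Upper-tail p-value of n_eff * F under the null chi2(p) distribution."""
    if n_eff <= p:
        raise ValueError("n_eff must exceed the model order")
    return float(stats.chi2.sf(n_eff * magnitude, df=p))


@dataclass
class GCResult:
    """Both-direction Granger causality for one unit (animal or session)."""

    gc_speed_to_ach: float
    gc_ach_to_speed: float
    p_speed_to_ach: float
    p_ach_to_speed: float
    order: int
    n_trials: int
    n_eff: int


def gc_pair(trials, p: int) -> GCResult:
    """Granger causality in both directions with chi2 p-values."""
    full = fit_var_multitrial(trials, p)
    f_sa = _gc_from_full(trials, full, "speed->ach")
    f_as = _gc_from_full(trials, full, "ach->speed")
    return GCResult(
        gc_speed_to_ach=f_sa,
        gc_ach_to_speed=f_as,
        p_speed_to_ach=gc_significance(f_sa, full.n_eff, p),
        p_ach_to_speed=gc_significance(f_as, full.n_eff, p),
        order=p,
        n_trials=len(trials),
        n_eff=full.n_eff,
    )


def per_mouse_gc(
    sessions,
    frame_rate: float,
    p_max: int = DEFAULT_P_MAX,
    minutes: float = 5.0,
):
    """Per-animal multi-trial GC plus a per-session GC table.

    ``sessions`` is an iterable of aligned sessions (``animal_id``,
    ``session_id``, ``lighting``, ``logspeed``, ``zdff``).  Sessions of one
    animal are treated as trials; the AIC-selected per-animal order is also
    used for the single-session fits that feed the direction mixed model.

    Returns ``(per_animal_df, per_session_df)``.
    """
    import pandas as pd

    by_animal: dict[str, list] = {}
    meta: dict[str, list] = {}
    for s in sessions:
        trial = truncate_first_minutes(s.logspeed, s.zdff, frame_rate, minutes)
        by_animal.setdefault(s.animal_id, []).append(trial)
        meta.setdefault(s.animal_id, []).append((s.session_id, s.lighting))
    animal_rows, session_rows = [], []
    for animal_id in sorted(by_animal):
        trials = by_animal[animal_id]
        p = select_order(trials, p_max)
        res = gc_pair(trials, p)
        animal_rows.append(
            {
                "animal_id": animal_id,
                "order": p,
                "n_sessions": len(trials),
                "gc_speed_to_ach": res.gc_speed_to_ach,
                "gc_ach_to_speed": res.gc_ach_to_speed,
                "p_speed_to_ach": res.p_speed_to_ach,
                "p_ach_to_speed": res.p_ach_to_speed,
            }
        )
        for trial, (session_id, lighting) in zip(trials, meta[animal_id]):
            r = gc_pair([trial], p)
            for direction, gc, pv in (
                ("speed_to_ach", r.gc_speed_to_ach, r.p_speed_to_ach),
                ("ach_to_speed", r.gc_ach_to_speed, r.p_ach_to_speed),
            ):
                session_rows.append(
                    {
                        "animal_id": animal_id,
                        "session_id": session_id,
                        "lighting": lighting,
                        "direction": direction,
                        "gc_nats": gc,
                        "p_value": pv,
                        "order": p,
                    }
                )
    return pd.DataFrame(animal_rows), pd.DataFrame(session_rows)


def simulate_var(coef: np.ndarray, n: int, seed, sigma: float = 1.0) -> np.ndarray:
    """Simulate a bivariate VAR with coefficient array (p, 2, 2); for oracles."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coef = np.asarray(coef, dtype=float)
    p = coef.shape[0]
    burn = 200
    x = np.zeros((n + burn, 2))
    eps = sigma * rng.standard_normal((n + burn, 2))
    for t in range(p, n + burn):
        acc = eps[t].copy()
        for k in range(p):
            acc += coef[k] @ x[t - k - 1]
        x[t] = acc
    return x[burn:]
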