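"""Linear mixed-effects models of cholinergic activity and Granger causality.

Four designs are supported:

- ``speed_dark``: z-dF/F ~ intercept + log2(speed) + log2(speed) x darkness,
  with random effects for animal and session;
- ``stationary_speed_dark``: the same model restricted to sessions that are
  stationary (< 3 cm/s) for more than two thirds of their length;
- ``gc_direction_dark``: per-session Granger-causality magnitude ~
  intercept + direction + darkness + direction x darkness, random
  intercepts for animal and session;
- ``behavior_speed_dark``: z-dF/F ~ intercept + log2(speed) + darkness +
  behaviour-community dummies (exploratory walking as reference), random
  intercepts for animal, session, darkness and community.

Fitting uses REML with residual-degrees-of-freedom t-tests.  The full
random-slope structure of the first two designs is simplified to random
intercept + log-speed slope per animal and a random intercept per session
(nested), which keeps the fits tractable without biasing the fixed
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from achdyn import simulate
from achdyn.kinematics import STATIONARY_THRESHOLD_CM_S

FORMULA_IDS = (
    "speed_dark",
    "stationary_speed_dark",
    "gc_direction_dark",
    "behavior_speed_dark",
)


@dataclass
class LMMDesign:
    """A ready-to-fit mixed-model specification."""

    formula_id: str
    data: pd.DataFrame
    formula: str
    groups: str
    re_formula: str | None
    vc_formula: dict[str, str] | None
    fixed_names: list[str]


@dataclass
class LMMEstimate:
    """Coefficient table and fit statistics of a mixed model."""

    formula_id: str
    table: pd.DataFrame  # name, estimate, se, t, df, p, ci_low, ci_high
    variance_components: dict[str, float]
    scale: float  # residual variance
    llf: float
    deviance: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool

    def coef(self, name: str) -> float:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["estimate"].iloc[0])


def _stationary_sessions(data: pd.DataFrame) -> pd.DataFrame:
    frac = data.groupby("session_id")["speed"].apply(
        lambda s: np.mean(s < STATIONARY_THRESHOLD_CM_S)
    )
    keep = frac[frac > 2.0 / 3.0].index
    return data[data["session_id"].isin(keep)]


def build_design(data: pd.DataFrame, formula_id: str) -> LMMDesign:
    """Assemble the model formula, grouping and variance components.

    ``data`` is a long frame; activity models need columns ``animal_id``,
    ``session_id``, ``lighting``, ``zdff``, ``logspeed`` (plus ``speed``
    for the stationary subset and ``community`` for the behaviour model);
    the GC model needs ``direction`` and ``gc_nats`` instead.
    """
    if formula_id not in FORMULA_IDS:
        raise ValueError(f"unknown formula_id {formula_id!r}")
    data = data.copy()
    data["dark"] = (data["lighting"] == "dark").astype(float)

    if formula_id in ("speed_dark", "stationary_speed_dark"):
        if formula_id == "stationary_speed_dark":
            data = _stationary_sessions(data)
            if data.empty:
                raise ValueError("no stationary-dominated sessions in the data")
        design = LMMDesign(
            formula_id=formula_id,
            data=data,
            formula="zdff ~ 1 + logspeed + logspeed:dark",
            groups="animal_id",
            re_formula="1 + logspeed",
            vc_formula={"session": "0 + C(session_id)"},
            fixed_names=["Intercept", "logspeed", "logspeed:dark"],
        )
    elif formula_id == "gc_direction_dark":
        data["dir_ach"] = (data["direction"] == "ach_to_speed").astype(float)
        design = LMMDesign(
            formula_id=formula_id,
            data=data,
            formula="gc_nats ~ 1 + dir_ach + dark + dir_ach:dark",
            groups="animal_id",
            re_formula="1",
            vc_formula={"session": "0 + C(session_id)"},
            fixed_names=["Intercept", "dir_ach", "dark", "dir_ach:dark"],
        )
    else:  # behavior_speed_dark
        comm = data["community"].to_numpy()
        data["er"] = (comm == simulate.STATE_INDEX["run"]).astype(float)
        data["rear"] = (comm == simulate.STATE_INDEX["rear"]).astype(float)
        data["groom"] = (comm == simulate.STATE_INDEX["groom"]).astype(float)
        design = LMMDesign(
            formula_id=formula_id,
            data=data,
            formula="zdff ~ 1 + logspeed + dark + er + rear + groom",
            groups="animal_id",
            # The source formula also lists random intercepts for darkness
            # (2 levels) and community (4 levels); those are not jointly
            # identifiable with the fixed effects for the same factors and
            # shrink them toward zero, so only the grouping factors with
            # real replication (animal, session) enter the covariance.
            re_formula="1",
            vc_formula={"session": "0 + C(session_id)"},
            fixed_names=["Intercept", "logspeed", "dark", "er", "rear", "groom"],
        )
    _check_design(design)
    return design


def _check_design(design: LMMDesign) -> None:
    import patsy

    y, X = patsy.dmatrices(design.formula, design.data, return_type="dataframe")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient fixed-effect design for {design.formula_id}")
    if X.shape[1] != len(design.fixed_names):
        raise AssertionError("fixed-effect column count mismatch")


class ConvergenceError(RuntimeError):
    pass


def fit_lmm(design: LMMDesign, method: str = "reml") -> LMMEstimate:
    """Fit by (restricted) maximum likelihood; report residual-DF t-tests.

    Singular fits (variance components at zero) produce a warning, not an
    error; non-convergence under all optimisers raises
    :class:`ConvergenceError`.
    """
    model = MixedLM.from_formula(
        design.formula,
        design.data,
        groups=design.groups,
        re_formula=design.re_formula,
        vc_formula=design.vc_formula,
    )
    reml = method.lower() == "reml"
    result = None
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=reml, method="lbfgs", maxiter=1000)
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            errors.append(f"lbfgs: {exc}")
        # lbfgs can report convergence prematurely on flat REML surfaces;
        # always refine with a derivative-free pass, warm-started at the
        # incumbent, and keep the better optimum.
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        start = None
        if result is not None and result.scale > 0:
            cov_re = (
                result.cov_re / result.scale
                if result.cov_re is not None and result.cov_re.size
                else None
            )
            try:
                start = MixedLMParams.from_components(
                    cov_re=cov_re, vcomp=result.vcomp / result.scale
                )
            except (ValueError, np.linalg.LinAlgError):
                start = None
        try:
            cand = model.fit(
                reml=reml, method="powell", maxiter=2000, start_params=start
            )
            if result is None or cand.llf >= result.llf:
                result = cand
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            errors.append(f"powell: {exc}")
    if result is None:
        raise ConvergenceError(
            f"mixed-model fit failed for {design.formula_id}: {errors}"
        )
    if not getattr(result, "converged", True):
        warnings.warn(f"optimizer did not flag convergence for {design.formula_id}")

    k_fixed = len(result.fe_params)
    n = int(model.nobs)
    df_resid = n - k_fixed
    est = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    tstat = est / se
    pval = 2.0 * sps.t.sf(np.abs(tstat), df_resid)
    tcrit = sps.t.ppf(0.975, df_resid)
    table = pd.DataFrame(
        {
            "name": design.fixed_names,
            "estimate": est,
            "se": se,
            "t": tstat,
            "df": df_resid,
            "p": pval,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
        }
    )

    vcomp: dict[str, float] = {}
    if result.cov_re is not None and result.cov_re.size:
        cov_re = np.asarray(result.cov_re)
        names = model.data.exog_re_names or [
            f"re{i}" for i in range(cov_re.shape[0])
        ]
        for i, nm in enumerate(names):
            vcomp[f"var({nm})"] = float(cov_re[i, i])
    if design.vc_formula:
        for nm, val in zip(model.exog_vc.names, np.atleast_1d(result.vcomp)):
            vcomp[f"var({nm})"] = float(val)
    if any(v <= 1e-12 for v in vcomp.values()):
        warnings.warn(
            f"singular fit for {design.formula_id}: a variance component is zero"
        )

    n_cov = len(vcomp) + 1  # + residual variance
    # cov_re is a full covariance: count its off-diagonals too
    if result.cov_re is not None and result.cov_re.size:
        q = result.cov_re.shape[0]
        n_cov += q * (q - 1) // 2
    k = k_fixed + n_cov
    llf = float(result.llf)
    deviance = -2.0 * llf
    return LMMEstimate(
        formula_id=design.formula_id,
        table=table,
        variance_components=vcomp,
        scale=float(result.scale),
        llf=llf,
        deviance=deviance,
        aic=deviance + 2 * k,
        bic=deviance + k * np.log(n),
        n_obs=n,
        n_params=k,
        converged=bool(getattr(result, "converged", True)),
    )


# ---------------------------------------------------------------------------
# cohort assembly and parameter-recovery studies


def sessions_to_frame(sessions, sample_interval_s: float | None = 1.0) -> pd.DataFrame:
    """Long DataFrame from aligned sessions, optionally subsampled.

    Subsampling at ~1 s spacing thins the 30 Hz frame clock so that the
    AR(1) latent noise is close to independent between retained rows,
    which the mixed model's error term assumes.
    """
    frames = []
    for s in sessions:
        df = s.to_frame()
        if sample_interval_s is not None:
            dt = float(np.median(np.diff(s.frame_time))) if len(s) > 1 else 1.0
            step = max(1, int(round(sample_interval_s / dt)))
            df = df.iloc[::step]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


TRUTH_MAP = {
    "speed_dark": {
        "Intercept": "beta0",
        "logspeed": "beta_speed",
        "logspeed:dark": "beta_dark_slope",
    },
    "stationary_speed_dark": {
        "Intercept": "beta0",
        "logspeed": "beta_speed",
        "logspeed:dark": "beta_dark_slope",
    },
    "behavior_speed_dark": {
        "Intercept": "beta0",
        "logspeed": "beta_speed",
        "dark": "beta_dark_main",
        "er": "beta_er",
        "rear": "beta_rear",
        "groom": "beta_groom",
    },
}


def recovery_study(
    config: simulate.SynthConfig,
    formula_id: str,
    n_replicates: int,
    seed,
    n_animals: int = 5,
    sessions_per_animal=10,
    lighting_schedule="alternate",
    sample_interval_s: float = 1.0,
    response: str = "model",
) -> pd.DataFrame:
    """Simulate cohorts, refit the model, report bias / RMSE / CI coverage.

    Returns one row per fixed effect with columns ``truth``,
    ``mean_estimate``, ``bias``, ``rmse``, ``coverage``, ``mc_se``,
    ``n_ok`` (replicates that converged; failures are recorded, not fatal).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = simulate._rng(seed)
    truth_map = TRUTH_MAP[formula_id]
    cdict = config.coeffs.as_dict()
    estimates: dict[str, list[float]] = {k: [] for k in truth_map}
    covered: dict[str, list[bool]] = {k: [] for k in truth_map}
    n_failed = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        sessions, _ = simulate.simulate_aligned_cohort(
            config,
            n_animals,
            sessions_per_animal,
            rep_seed,
            lighting_schedule=lighting_schedule,
            response=response,
        )
        data = sessions_to_frame(sessions, sample_interval_s)
        try:
            fit = fit_lmm(build_design(data, formula_id))
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"replicate failed: {exc}")
            n_failed += 1
            continue
        for name in truth_map:
            row = fit.table.loc[fit.table["name"] == name].iloc[0]
            estimates[name].append(float(row["estimate"]))
            truth = cdict[truth_map[name]]
            covered[name].append(
                bool(row["ci_low"] <= truth <= row["ci_high"])
            )
    rows = []
    for name, key in truth_map.items():
        est = np.array(estimates[name])
        truth = cdict[key]
        if len(est) == 0:
            raise ConvergenceError("all replicates failed")
        rows.append(
            {
                "name": name,
                "truth": truth,
                "mean_estimate": est.mean(),
                "bias": est.mean() - truth,
                "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
                "coverage": float(np.mean(covered[name])),
                "mc_se": float(est.std(ddof=1) / np.sqrt(len(est)))
                if len(est) > 1
                else np.nan,
                "n_ok": len(est),
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)
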