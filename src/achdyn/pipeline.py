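"""End-to-end orchestration: configuration, validation, and the staged
pipeline from raw session files to cohort-level result tables."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from achdyn import causality, dynamics, io, kinematics, mixed_models, photometry, tuning

log = logging.getLogger("achdyn")


@dataclass
class StageToggles:
    preprocess: bool = True
    tuning: bool = True
    dynamics: bool = True
    granger: bool = True
    lmm: bool = True


@dataclass
class PipelineConfig:
    """Every tunable of the file-level pipeline, round-trippable via YAML."""

    manifest: str = "manifest.csv"
    outdir: str = "results"
    seed: int = 0
    frame_rate: float = 30.0
    stages: StageToggles = field(default_factory=StageToggles)
    # kinematics
    speed_floor: float = 0.25  # cm/s, epsilon for log2
    likelihood_threshold: float = 0.9
    stationary_threshold: float = 3.0  # cm/s
    median_filter: bool = False
    # tuning
    speed_bin_width: float = 1.0  # cm/s
    logspeed_bin_width: float = 0.1
    min_bin_count: int = 5
    sample_interval_s: float = 1.0
    # dynamics
    window_max_s: float = 10.0
    reference_window_s: float = 1.3
    # causality
    gc_p_max: int = 30
    gc_minutes: float = 5.0
    # mixed models
    lmm_method: str = "reml"
    lmm_sample_interval_s: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        stages = raw.pop("stages", {})
        if isinstance(stages, dict):
            bad = set(stages) - {f.name for f in dataclasses.fields(StageToggles)}
            if bad:
                raise ValueError(f"unknown stage toggles: {sorted(bad)}")
            stages = StageToggles(**stages)
        return cls(stages=stages, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        """Hash of the analytic parameters (file locations excluded)."""
        d = self.to_dict()
        d.pop("manifest", None)
        d.pop("outdir", None)
        return io.config_hash(d)


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(f"- {v}" for v in self.violations)


def validate_inputs(manifest_path, frame_rate: float = 30.0) -> ValidationReport:
    """Check file formats, TTL counts vs. pose frames, monotone timestamps."""
    violations: list[str] = []
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    try:
        manifest = pd.read_csv(manifest_path)
    except Exception as exc:  # noqa: BLE001
        return ValidationReport([f"cannot read manifest: {exc}"])
    required = {
        "animal_id",
        "session_id",
        "lighting",
        "photometry_path",
        "pose_path",
        "labels_path",
    }
    missing = required - set(manifest.columns)
    if missing:
        violations.append(f"manifest missing columns {sorted(missing)}")
        return ValidationReport(violations)
    for _, row in manifest.iterrows():
        sid = row["session_id"]
        paths = {
            "photometry": base / row["photometry_path"],
            "pose": base / row["pose_path"],
            "labels": base / row["labels_path"],
        }
        for kind, p in paths.items():
            if not p.exists():
                violations.append(f"{sid}: missing {kind} file {p}")
        if any(not p.exists() for p in paths.values()):
            continue
        try:
            raw = io.read_photometry_csv(paths["photometry"])
        except ValueError as exc:
            t = pd.read_csv(paths["photometry"])["time_s"].to_numpy()
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if len(bad):
                violations.append(
                    f"{sid}: non-monotone timestamps at rows {bad.tolist()[:5]}"
                )
            else:
                violations.append(f"{sid}: bad photometry file ({exc})")
            continue
        pose = io.read_pose_csv(paths["pose"], frame_rate)
        labels = io.read_labels_csv(paths["labels"])
        if len(pose) != raw.n_frames:
            violations.append(
                f"{sid}: pose frames ({len(pose)}) != TTL frames ({raw.n_frames})"
            )
        if len(labels) != len(pose):
            violations.append(
                f"{sid}: label rows ({len(labels)}) != pose frames ({len(pose)})"
            )
        if np.any((pose.likelihood < 0) | (pose.likelihood > 1)):
            violations.append(f"{sid}: pose likelihood outside [0, 1]")
    return ValidationReport(violations)


def load_session(row, base: Path, config: PipelineConfig) -> tuning.AlignedSession:
    """Raw files -> frame-aligned session via the full preprocessing chain."""
    raw = io.read_photometry_csv(base / row["photometry_path"])
    trace = photometry.process_session(raw)
    pose = io.read_pose_csv(base / row["pose_path"], config.frame_rate)
    pose = kinematics.interpolate_low_likelihood(pose, config.likelihood_threshold)
    speeds = kinematics.neck_speed(
        pose,
        config.frame_rate,
        epsilon=config.speed_floor,
        threshold=config.stationary_threshold,
        median_filter=config.median_filter,
    )
    labels = io.read_labels_csv(base / row["labels_path"])
    n = min(len(trace.zdff), len(speeds.speed), len(labels))
    return tuning.AlignedSession(
        animal_id=str(row["animal_id"]),
        session_id=str(row["session_id"]),
        lighting=str(row["lighting"]),
        frame_time=trace.frame_time[:n],
        zdff=trace.zdff[:n],
        speed=speeds.speed[:n],
        logspeed=speeds.logspeed[:n],
        community=np.asarray(labels[:n]),
    )


def run_pipeline(config: PipelineConfig, manifest_path=None) -> dict:
    """Run all enabled stages; per-session failures are isolated.

    Writes results under ``<outdir>/<stage>/`` and returns a report dict
    with ``n_failed`` > 0 if any session or stage failed.
    """
    manifest_path = Path(manifest_path or config.manifest)
    base = manifest_path.parent
    outdir = Path(config.outdir)
    prov = {"config_hash": config.hash, "seed": config.seed}
    manifest = pd.read_csv(manifest_path)
    report: dict = {"outputs": [], "failures": [], "n_failed": 0}

    sessions: list[tuning.AlignedSession] = []
    if config.stages.preprocess:
        stage_dir = outdir / "preprocess"
        stage_dir.mkdir(parents=True, exist_ok=True)
        for _, row in manifest.iterrows():
            sid = row["session_id"]
            try:
                sess = load_session(row, base, config)
            except Exception as exc:  # noqa: BLE001
                log.error("session %s failed: %s", sid, exc)
                report["failures"].append(f"preprocess/{sid}: {exc}")
                continue
            sessions.append(sess)
            out = stage_dir / f"{sid}.csv"
            io.write_result_csv(out, sess.to_frame(), prov)
            report["outputs"].append(str(out))
    else:
        raise ValueError("the preprocess stage is required to build sessions")

    if not sessions:
        report["n_failed"] = len(report["failures"])
        return report

    if config.stages.tuning:
        stage_dir = outdir / "tuning"
        stage_dir.mkdir(parents=True, exist_ok=True)
        curves: dict[str, list[tuning.TuningCurve]] = {}
        fit_rows = []
        for s in sessions:
            xs, zs = tuning.sample_interval(
                s.logspeed, s.zdff, s.frame_time, config.sample_interval_s
            )
            curve = tuning.bin_tuning_curve(
                xs, zs, config.logspeed_bin_width, config.min_bin_count
            )
            curves.setdefault(s.lighting, []).append(curve)
            slope, intercept, r = tuning.fit_linear_log(xs, zs)
            fit_rows.append(
                {
                    "session_id": s.session_id,
                    "lighting": s.lighting,
                    "slope": slope,
                    "intercept": intercept,
                    "pearson_r": r,
                }
            )
        agg = tuning.aggregate_curves(curves)
        rows = []
        for cond, c in agg.items():
            for i in range(len(c.bin_mean)):
                rows.append(
                    {
                        "condition": cond,
                        "bin_left": c.bin_edges[i],
                        "bin_mean": c.bin_mean[i],
                        "bin_sem": c.bin_sem[i],
                        "bin_n": c.bin_n[i],
                    }
                )
        io.write_result_csv(stage_dir / "logspeed_curves.csv", pd.DataFrame(rows), prov)
        io.write_result_csv(stage_dir / "session_fits.csv", pd.DataFrame(fit_rows), prov)
        report["outputs"] += [
            str(stage_dir / "logspeed_curves.csv"),
            str(stage_dir / "session_fits.csv"),
        ]

    scans: list[dynamics.WindowScan] = []
    if config.stages.dynamics:
        stage_dir = outdir / "dynamics"
        stage_dir.mkdir(parents=True, exist_ok=True)
        grid = dynamics.default_window_grid(config.frame_rate, config.window_max_s)
        rows = []
        for s in sessions:
            scan = dynamics.window_scan(
                s.zdff, s.logspeed, grid, config.frame_rate, s.session_id
            )
            scans.append(scan)
            rows += [
                {"session_id": s.session_id, "window_s": w, "r": r}
                for w, r in zip(scan.window_grid, scan.r_per_window)
            ]
        io.write_result_csv(stage_dir / "window_scans.csv", pd.DataFrame(rows), prov)
        payload: dict = {
            "optimal_window_per_session": {
                sc.session_id: sc.optimal_window for sc in scans
            }
        }
        light = [sc for sc, s in zip(scans, sessions) if s.lighting == "light"]
        dark = [sc for sc, s in zip(scans, sessions) if s.lighting == "dark"]
        if len(light) >= 2 and len(dark) >= 2:
            payload["light_dark"] = dynamics.compare_light_dark(
                light, dark, config.reference_window_s
            )
        io.write_result_json(stage_dir / "summary.json", payload, prov)
        report["outputs"] += [
            str(stage_dir / "window_scans.csv"),
            str(stage_dir / "summary.json"),
        ]

    gc_sessions = None
    if config.stages.granger:
        stage_dir = outdir / "granger"
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            per_animal, gc_sessions = causality.per_mouse_gc(
                sessions, config.frame_rate, config.gc_p_max, config.gc_minutes
            )
            io.write_result_csv(stage_dir / "per_animal.csv", per_animal, prov)
            io.write_result_csv(stage_dir / "per_session.csv", gc_sessions, prov)
            report["outputs"] += [
                str(stage_dir / "per_animal.csv"),
                str(stage_dir / "per_session.csv"),
            ]
        except Exception as exc:  # noqa: BLE001
            log.error("granger stage failed: %s", exc)
            report["failures"].append(f"granger: {exc}")

    if config.stages.lmm:
        stage_dir = outdir / "lmm"
        stage_dir.mkdir(parents=True, exist_ok=True)
        data = mixed_models.sessions_to_frame(sessions, config.lmm_sample_interval_s)
        models = [("speed_dark", data)]
        n_station = len(
            kinematics.stationary_session_filter(sessions)
        )
        if n_station >= 2:
            models.append(("stationary_speed_dark", data))
        models.append(("behavior_speed_dark", data))
        if gc_sessions is not None and len(gc_sessions):
            models.append(("gc_direction_dark", gc_sessions))
        stats = {}
        for formula_id, d in models:
            try:
                fit = mixed_models.fit_lmm(
                    mixed_models.build_design(d, formula_id), config.lmm_method
                )
            except Exception as exc:  # noqa: BLE001
                log.error("lmm %s failed: %s", formula_id, exc)
                report["failures"].append(f"lmm/{formula_id}: {exc}")
                continue
            out = stage_dir / f"{formula_id}_coefficients.csv"
            io.write_result_csv(out, fit.table, prov)
            report["outputs"].append(str(out))
            stats[formula_id] = {
                "aic": fit.aic,
                "bic": fit.bic,
                "llf": fit.llf,
                "deviance": fit.deviance,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "variance_components": fit.variance_components,
                "scale": fit.scale,
            }
        io.write_result_json(stage_dir / "model_stats.json", stats, prov)
        report["outputs"].append(str(stage_dir / "model_stats.json"))

    report["n_failed"] = len(report["failures"])
    return report
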