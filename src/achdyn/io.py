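"""File formats: photometry CSV, pose CSVs (DeepLabCut and simple
dialects), behaviour-label CSV, ground-truth CSV, and provenance-stamped
result files.

All formats are plain text.  Photometry files carry the 500 Hz channels
plus a TTL column with a rising edge (value 1) at the sample that starts
each video frame; pose files come either in the DeepLabCut three-header
dialect (scorer / bodyparts / coords) or as a simple
``frame,time_s,neck_x,neck_y,likelihood`` table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from achdyn.kinematics import PoseTrack
from achdyn.photometry import RawPhotometry

DLC_BODYPARTS = ("neck", "nose", "left_ear", "right_ear", "tail_base", "tail_tip")
#: Offsets (cm) of the non-tracked bodyparts relative to the neck; only the
#: neck is simulated, the rest make the file shape realistic.
_PART_OFFSETS = {
    "neck": (0.0, 0.0),
    "nose": (2.0, 0.0),
    "left_ear": (1.0, 0.8),
    "right_ear": (1.0, -0.8),
    "tail_base": (-3.0, 0.0),
    "tail_tip": (-7.0, 0.0),
}


# ---------------------------------------------------------------------------
# photometry


def write_photometry_csv(path, raw: RawPhotometry) -> None:
    ttl = np.zeros(len(raw.time_s), dtype=int)
    idx = np.searchsorted(raw.time_s, raw.ttl_frame_times, side="left")
    idx = np.clip(idx, 0, len(ttl) - 1)
    ttl[idx] = 1
    pd.DataFrame(
        {"time_s": raw.time_s, "f470": raw.f470, "f405": raw.f405, "ttl": ttl}
    ).to_csv(path, index=False, float_format="%.6f")


def read_photometry_csv(path) -> RawPhotometry:
    df = pd.read_csv(path)
    for col in ("time_s", "f470", "f405", "ttl"):
        if col not in df.columns:
            raise ValueError(f"photometry file {path} lacks column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    frame_times = t[df["ttl"].to_numpy() == 1]
    return RawPhotometry(
        time_s=t,
        f470=df["f470"].to_numpy(dtype=float),
        f405=df["f405"].to_numpy(dtype=float),
        ttl_frame_times=frame_times,
    )


# ---------------------------------------------------------------------------
# pose


def write_dlc_pose_csv(path, pose: PoseTrack, scorer: str = "synthetic") -> None:
    """DeepLabCut dialect: three header rows (scorer/bodyparts/coords)."""
    cols: dict[str, np.ndarray] = {}
    for part in DLC_BODYPARTS:
        ox, oy = _PART_OFFSETS[part]
        cols[f"{part}_x"] = pose.neck_x + ox
        cols[f"{part}_y"] = pose.neck_y + oy
        cols[f"{part}_likelihood"] = pose.likelihood
    n = len(pose)
    with open(path, "w") as fh:
        fh.write("scorer," + ",".join([scorer] * (3 * len(DLC_BODYPARTS))) + "\n")
        fh.write(
            "bodyparts,"
            + ",".join(p for p in DLC_BODYPARTS for _ in range(3))
            + "\n"
        )
        fh.write("coords," + ",".join(["x", "y", "likelihood"] * len(DLC_BODYPARTS)) + "\n")
        body = np.column_stack(
            [np.arange(n)]
            + [
                cols[f"{p}_{c}"]
                for p in DLC_BODYPARTS
                for c in ("x", "y", "likelihood")
            ]
        )
        np.savetxt(fh, body, delimiter=",", fmt=["%d"] + ["%.5f"] * (3 * len(DLC_BODYPARTS)))


def write_simple_pose_csv(path, pose: PoseTrack) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(pose)),
            "time_s": pose.time_s,
            "neck_x": pose.neck_x,
            "neck_y": pose.neck_y,
            "likelihood": pose.likelihood,
        }
    ).to_csv(path, index=False, float_format="%.5f")


def read_pose_csv(path, frame_rate: float = 30.0) -> PoseTrack:
    """Read either pose dialect; DLC files are detected by their header."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("scorer"):
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        scorer = df.columns[0][0]
        neck_x = df[(scorer, "neck", "x")].to_numpy(dtype=float)
        neck_y = df[(scorer, "neck", "y")].to_numpy(dtype=float)
        lik = df[(scorer, "neck", "likelihood")].to_numpy(dtype=float)
        time_s = np.arange(len(neck_x)) / frame_rate
        return PoseTrack(time_s=time_s, neck_x=neck_x, neck_y=neck_y, likelihood=lik)
    df = pd.read_csv(path)
    return PoseTrack(
        time_s=df["time_s"].to_numpy(dtype=float),
        neck_x=df["neck_x"].to_numpy(dtype=float),
        neck_y=df["neck_y"].to_numpy(dtype=float),
        likelihood=df["likelihood"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# labels and ground truth


def write_labels_csv(path, states: np.ndarray) -> None:
    pd.DataFrame({"frame": np.arange(len(states)), "community": states}).to_csv(
        path, index=False
    )


def read_labels_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["community"].to_numpy(dtype=int)


def write_truth_csv(path, truth) -> None:
    """Per-frame ground truth of a simulated session (:class:`SessionTruth`)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(len(truth.latent)),
            "state": truth.labels.states,
            "true_speed": truth.true_speed,
            "latent": truth.latent,
        }
    )
    if truth.render is not None:
        df["true_dff"] = truth.render.true_dff
    df.to_csv(path, index=False, float_format="%.6f")


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# provenance-stamped outputs


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_result_csv(path, df: pd.DataFrame, provenance: dict) -> None:
    """CSV with a leading ``#`` comment line declaring config hash and seed."""
    with open(path, "w") as fh:
        fh.write(
            "# " + " ".join(f"{k}={v}" for k, v in sorted(provenance.items())) + "\n"
        )
        df.to_csv(fh, index=False)


def read_result_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_result_json(path, payload: dict, provenance: dict) -> None:
    out = {"provenance": provenance, **payload}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)


def _json_default(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serialisable: {type(x)}")
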