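"""File formats: trajectory logs as CSV, trial configs as JSON, manifests.

Logs are long-format CSV with one row per (sample, agent): columns
``t, agent_id, role, x, y, heading_deg, vx, vy, influenced, contained,
targeted_ta``.  Angles are serialized in degrees and positions in metres.
Write/read round-trips canonical logs losslessly (full float precision).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import Arena
from .herder_model import ModelParams
from .policies import policy_from_name
from .simulator import TrajectoryLog, TrialConfig
from .target_dynamics import TAParams

__all__ = [
    "write_log", "read_log", "log_to_frame", "frame_to_log",
    "write_config", "read_config", "config_to_dict", "config_from_dict",
    "RunManifest", "LogFormatError",
]

LOG_COLUMNS = ["t", "agent_id", "role", "x", "y", "heading_deg",
               "vx", "vy", "influenced", "contained", "targeted_ta"]


class LogFormatError(ValueError):
    """Malformed trajectory-log file."""


def log_to_frame(log: TrajectoryLog) -> pd.DataFrame:
    """Long-format DataFrame view of a log (one row per sample and agent)."""
    k = log.n_tas
    frames = [pd.DataFrame({
        "t": log.t, "agent_id": "HA", "role": "HA",
        "x": log.ha[:, 0], "y": log.ha[:, 1],
        "heading_deg": log.ha_heading_deg,
        "vx": np.nan, "vy": np.nan,          # herder speed is the model's v0
        "influenced": False, "contained": False,
        "targeted_ta": log.targeted,
    })]
    for j in range(k):
        frames.append(pd.DataFrame({
            "t": log.t, "agent_id": f"TA{j}", "role": "TA",
            "x": log.ta[:, j, 0], "y": log.ta[:, j, 1],
            "heading_deg": np.nan,
            "vx": log.ta_vel[:, j, 0], "vy": log.ta_vel[:, j, 1],
            "influenced": log.influenced[:, j],
            "contained": log.contained[:, j],
            "targeted_ta": log.targeted,
        }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["t", "agent_id"], kind="stable").reset_index(drop=True)


def frame_to_log(df: pd.DataFrame, dt: float | None = None) -> TrajectoryLog:
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"missing columns: {missing}")
    if len(df) == 0:
        raise LogFormatError("empty log")
    if df[["t", "x", "y"]].isna().any().any():
        bad = df.index[df[["t", "x", "y"]].isna().any(axis=1)].tolist()[:5]
        raise LogFormatError(f"NaN coordinates at rows {bad}")
    ha = df[df["role"] == "HA"].sort_values("t", kind="stable")
    if len(ha) == 0:
        raise LogFormatError("no herder rows")
    t = ha["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise LogFormatError(f"non-monotone time at sample {i + 1}")
    ta_ids = sorted(df.loc[df["role"] == "TA", "agent_id"].unique())
    k = len(ta_ids)
    n = len(t)
    ta = np.empty((n, k, 2))
    vel = np.empty((n, k, 2))
    infl = np.empty((n, k), dtype=bool)
    cont = np.empty((n, k), dtype=bool)
    for j, aid in enumerate(ta_ids):
        rows = df[df["agent_id"] == aid].sort_values("t", kind="stable")
        if len(rows) != n:
            raise LogFormatError(
                f"agent {aid} has {len(rows)} samples, herder has {n}")
        ta[:, j, 0] = rows["x"].to_numpy(float)
        ta[:, j, 1] = rows["y"].to_numpy(float)
        vel[:, j, 0] = rows["vx"].to_numpy(float)
        vel[:, j, 1] = rows["vy"].to_numpy(float)
        infl[:, j] = rows["influenced"].to_numpy(bool)
        cont[:, j] = rows["contained"].to_numpy(bool)
    if dt is None:
        dt = float(np.median(np.diff(t))) if n > 1 else 0.02
    return TrajectoryLog(
        t=t,
        ha=ha[["x", "y"]].to_numpy(float),
        ha_heading_deg=ha["heading_deg"].to_numpy(float),
        ta=ta, ta_vel=vel, influenced=infl, contained=cont,
        targeted=ha["targeted_ta"].to_numpy(int),
        dt=dt,
    )


def write_log(log: TrajectoryLog, path: str | Path) -> Path:
    path = Path(path)
    log_to_frame(log).to_csv(path, index=False, float_format="%.17g")
    return path


def read_log(path: str | Path) -> TrajectoryLog:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise LogFormatError(f"{path}: empty file") from None
    return frame_to_log(df)


# ------------------------------------------------------------- configs ----

def config_to_dict(config: TrialConfig) -> dict:
    d = {
        "ha_position": list(config.ha_position),
        "ha_heading_deg": config.ha_heading_deg,
        "ta_positions": [list(p) for p in config.ta_positions],
        "arena": config.arena.to_dict(),
        "model": config.model.to_dict(),
        "ta_params": config.ta_params.to_dict(),
        "dt": config.dt,
        "max_duration": config.max_duration,
        "policy_period": config.policy_period,
        "latch_mode": config.latch_mode,
        "policy_mode": config.policy_mode,
    }
    if config.policy is not None:
        d["policy"] = {
            "name": config.policy.name,
            "collinear_threshold": config.policy.collinear_threshold,
        }
    return d


def config_from_dict(d: dict) -> TrialConfig:
    policy = None
    if "policy" in d and d["policy"] is not None:
        p = d["policy"]
        policy = policy_from_name(p["name"])
        if "collinear_threshold" in p:
            policy = policy.with_threshold(p["collinear_threshold"])
    return TrialConfig(
        ha_position=tuple(d["ha_position"]),
        ha_heading_deg=d["ha_heading_deg"],
        ta_positions=tuple(tuple(p) for p in d["ta_positions"]),
        arena=Arena.from_dict(d.get("arena", {})),
        model=ModelParams.from_dict(d.get("model", {})),
        ta_params=TAParams.from_dict(d.get("ta_params", {})),
        policy=policy,
        dt=d.get("dt", 0.02),
        max_duration=d.get("max_duration", 120.0),
        policy_period=d.get("policy_period", 0.25),
        latch_mode=d.get("latch_mode", "entry"),
        policy_mode=d.get("policy_mode", "locked"),
    )


def write_config(config: TrialConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config_to_dict(config), indent=2))
    return path


def read_config(path: str | Path) -> TrialConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------ manifest ----

@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None = None
    config_hash: str | None = None
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = self.timestamp or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def hash_config(config: TrialConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
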