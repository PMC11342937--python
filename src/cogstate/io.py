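"""CSV/JSON interchange for every artifact the pipeline produces.

CSV with explicit headers is the interchange dialect (there is no
domain-standard container for marked-point-process trial data); JSON holds
parameter sets and run reports.  Readers validate headers and fail naming
the missing column; JSON writers refuse NaN so reports stay portable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import ImpulseTrain, SCRecording
from .mpp import MPPArousalParams
from .pb import PBParams
from .performance import TRIAL_COLUMNS, PerfParams
from .trajectory import StateTrajectory

_PARAM_CLASSES = {cls.__name__: cls
                  for cls in (MPPArousalParams, PerfParams, PBParams)}


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")


def write_scr_csv(path, scr: SCRecording) -> None:
    pd.DataFrame({"time_s": scr.times, "scr_uS": scr.samples}).to_csv(
        path, index=False)


def read_scr_csv(path) -> SCRecording:
    frame = pd.read_csv(path)
    _require_columns(frame, ["time_s", "scr_uS"], path)
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling grid")
    return SCRecording(frame["scr_uS"].to_numpy(dtype=float),
                       fs=1.0 / dt[0], t_start=float(t[0]))


def write_impulses_csv(path, impulses: ImpulseTrain) -> None:
    pd.DataFrame({"time_s": impulses.times,
                  "amplitude": impulses.amplitudes}).to_csv(path, index=False)


def read_impulses_csv(path) -> ImpulseTrain:
    frame = pd.read_csv(path)
    _require_columns(frame, ["time_s", "amplitude"], path)
    return ImpulseTrain(frame["time_s"].to_numpy(dtype=float),
                        frame["amplitude"].to_numpy(dtype=float))


def write_trials_csv(path, trials: pd.DataFrame) -> None:
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, TRIAL_COLUMNS, path)
    return frame


def write_trajectory_csv(path, traj: StateTrajectory,
                         index_name: str = "bin") -> None:
    k = len(traj)
    frame = pd.DataFrame({
        index_name: np.arange(k),
        "x_filt": traj.x_filt, "var_filt": traj.var_filt,
        "x_smooth": traj.x_smooth, "var_smooth": traj.var_smooth,
        "prob": traj.prob,
    })
    frame.to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("x_filt", "var_filt", "x_smooth", "var_smooth", "prob"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return frame


def write_params_json(path, params) -> None:
    payload = {"class": type(params).__name__,
               "fields": dataclasses.asdict(params)}
    text = json.dumps(payload, indent=2, allow_nan=False)
    Path(path).write_text(text + "\n")


def read_params_json(path):
    payload = json.loads(Path(path).read_text())
    cls = _PARAM_CLASSES.get(payload.get("class"))
    if cls is None:
        raise ValueError(f"{path}: unknown parameter class "
                         f"'{payload.get('class')}'")
    return cls(**payload["fields"])


def write_report_json(path, report: dict) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return [_clean(v) for v in obj.tolist()]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    text = json.dumps(_clean(report), indent=2, allow_nan=False)
    Path(path).write_text(text + "\n")
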