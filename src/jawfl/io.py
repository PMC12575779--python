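"""Plain-text serialization of trials, calibrations, preps and curves.

A trial is written as one CSV per channel (columns ``time_s,value``) plus a
JSON sidecar holding units, rates, metadata and — for synthetic data — the
ground-truth block.  A session manifest JSON lists trial directories.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conditioning import CalibrationModel
from .core import FoodItem, MusclePrep, Trace, Trial, TrialMeta
from .flcurves import FLCurve

__all__ = [
    "write_trial",
    "read_trial",
    "write_manifest",
    "read_manifest",
    "write_session",
    "read_session",
    "calibration_to_json",
    "calibration_from_json",
    "prep_to_json",
    "prep_from_json",
    "curve_to_json",
    "curve_from_json",
    "features_to_frame",
    "features_to_csv",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trial(trial: Trial, path) -> Path:
    """Write a trial as per-channel CSVs plus a JSON sidecar; returns the dir."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {"channels": {}, "meta": {}, "truth": _jsonable(trial.truth)}
    for name, ch in trial.channels.items():
        fname = f"{name}.csv"
        pd.DataFrame({"time_s": ch.times(), "value": ch.values}).to_csv(
            path / fname, index=False
        )
        sidecar["channels"][name] = {
            "file": fname,
            "rate_hz": ch.rate,
            "t0_s": ch.t0,
            "units": ch.units,
        }
    meta = dataclasses.asdict(trial.meta)
    if trial.meta.food is not None:
        meta["food"] = {"name": trial.meta.food.name, "E": trial.meta.food.E}
    sidecar["meta"] = _jsonable(meta)
    with open(path / "trial.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return path


def read_trial(path) -> Trial:
    path = Path(path)
    with open(path / "trial.json") as fh:
        sidecar = json.load(fh)
    channels = {}
    for name, info in sidecar["channels"].items():
        df = pd.read_csv(path / info["file"])
        channels[name] = Trace(
            df["value"].to_numpy(), info["rate_hz"], info["t0_s"], info["units"]
        )
    meta_d = sidecar.get("meta", {})
    food = meta_d.get("food")
    meta = TrialMeta(
        subject=meta_d.get("subject", ""),
        protocol=meta_d.get("protocol", "in_vivo"),
        food=FoodItem(**food) if food else None,
        cycle_number=meta_d.get("cycle_number"),
        set_length=meta_d.get("set_length"),
        stim_on=meta_d.get("stim_on"),
        stim_off=meta_d.get("stim_off"),
        response_end=meta_d.get("response_end"),
    )
    return Trial(channels=channels, meta=meta, truth=sidecar.get("truth"))


def write_manifest(session_dir, trial_dirs: Sequence, extra: dict = None) -> Path:
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "trials": [str(Path(d).relative_to(session_dir)) for d in trial_dirs],
    }
    if extra:
        manifest.update(_jsonable(extra))
    out = session_dir / "manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def read_manifest(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return [base / d for d in manifest["trials"]]


def write_session(trials: Sequence[Trial], session_dir, extra: dict = None) -> Path:
    """Write a list of trials under ``session_dir`` with a manifest."""
    session_dir = Path(session_dir)
    dirs = []
    for i, tr in enumerate(trials):
        dirs.append(write_trial(tr, session_dir / f"trial_{i:03d}"))
    return write_manifest(session_dir, dirs, extra)


def read_session(manifest_path) -> list:
    return [read_trial(d) for d in read_manifest(manifest_path)]


def calibration_to_json(model: CalibrationModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(dataclasses.asdict(model)), fh, indent=2, sort_keys=True)


def calibration_from_json(path) -> CalibrationModel:
    with open(path) as fh:
        return CalibrationModel(**json.load(fh))


def prep_to_json(prep: MusclePrep, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(dataclasses.asdict(prep)), fh, indent=2, sort_keys=True)


def prep_from_json(path) -> MusclePrep:
    with open(path) as fh:
        return MusclePrep(**json.load(fh))


def curve_to_json(curve: FLCurve, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(dataclasses.asdict(curve)), fh, indent=2, sort_keys=True)


def curve_from_json(path) -> FLCurve:
    with open(path) as fh:
        d = json.load(fh)
    for key in (
        "lengths_active",
        "stress_active",
        "lengths_passive",
        "stress_passive",
        "cubic_coeffs_active",
        "cubic_coeffs_passive",
    ):
        d[key] = np.asarray(d[key], dtype=float)
    d["fit_range"] = tuple(d["fit_range"])
    return FLCurve(**d)


def features_to_frame(features: Sequence) -> pd.DataFrame:
    """Bite features -> one CSV-ready row per bite."""
    rows = []
    for f in features:
        d = dataclasses.asdict(f)
        d["flags"] = ";".join(d.get("flags", []))
        rows.append(d)
    return pd.DataFrame(rows)


def features_to_csv(features: Sequence, path) -> None:
    features_to_frame(features).to_csv(path, index=False)
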