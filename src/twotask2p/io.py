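"""Readers and writers for the pipeline's on-disk formats.

Trial tables travel as CSV (comma-separated, UTF-8, header row). Arrays
(traces, pixel patches, retinotopy maps) travel as a flat ``.npz`` container
with a JSON sidecar recording shapes, labels, units, and the generating
configuration including its seed, so every artifact is self-describing and
round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "save_arrays",
    "load_arrays",
    "save_trials",
    "load_trials",
    "save_session",
    "load_session_arrays",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_arrays(
    path: str | Path,
    arrays: dict[str, np.ndarray],
    meta: dict | None = None,
    units: dict[str, str] | None = None,
) -> Path:
    """Write named arrays to ``<path>.npz`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "arrays": {
            k: {"shape": list(v.shape), "dtype": str(np.asarray(v).dtype),
                "units": (units or {}).get(k)}
            for k, v in arrays.items()
        },
        "meta": _jsonable(meta or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_arrays(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Load an array container and its sidecar metadata."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as f:
        arrays = {k: f[k] for k in f.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    for k, info in sidecar["arrays"].items():
        if list(arrays[k].shape) != info["shape"]:
            raise ValueError(f"sidecar shape mismatch for array {k!r}")
    return arrays, sidecar["meta"]


def save_trials(path: str | Path, trials: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def load_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("rewarded", "repeat_flag"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def save_session(session, out_dir: str | Path) -> Path:
    """Write a generated session: one CSV per trial table, one array
    container for the traces and movement signals, config in the sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for task, table in session.trials.items():
        save_trials(out / f"trials_{task}.csv", table)
    arrays = {f"traces_{c}": session.traces[c] for c in session.condition_labels}
    units = {k: "deconvolved a.u." for k in arrays}
    for c, run in session.running.items():
        arrays[f"running_{c}"] = run
        units[f"running_{c}"] = "cm/s"
    for c, w in session.wheel.items():
        arrays[f"wheel_{c}"] = w
        units[f"wheel_{c}"] = "deg/s"
    meta = {
        "config": session.config,
        "seed": session.seed,
        "condition_labels": list(session.condition_labels),
        "classes": session.classes.tolist(),
        "frame_rate": session.config.frame_rate,
    }
    save_arrays(out / "session", arrays, meta=meta, units=units)
    return out


def load_session_arrays(out_dir: str | Path) -> tuple[dict, dict, dict[str, pd.DataFrame]]:
    """Read back what ``save_session`` wrote: (arrays, meta, trial tables)."""
    out = Path(out_dir)
    arrays, meta = load_arrays(out / "session")
    trials = {
        p.stem.removeprefix("trials_"): load_trials(p)
        for p in sorted(out.glob("trials_*.csv"))
    }
    return arrays, meta, trials
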