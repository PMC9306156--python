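"""Session-bundle container I/O and run configuration.

A session bundle is a directory with a ``session.json`` sidecar (sampling
rate, layout, task labels, seed, config echo, MVC table) and one
``signals_<task_id>.f32`` file per recording: little-endian 32-bit floats,
channel-major (all samples of channel 0, then channel 1, ...).  Signals
round-trip bit-exactly at float32 precision.  A CSV escape hatch (one column
per channel) is provided for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import EmgRecording, TaskLabel
from .layout import GridLayout
from .synth import Session, SimulationConfig, default_gesture_model

__all__ = ["write_session", "read_session", "export_csv", "import_csv",
           "write_model", "read_model", "RunConfig"]

_SIDECAR = "session.json"


def _rec_entry(rec: EmgRecording, kind: str) -> dict:
    return {
        "task_id": rec.task_id,
        "kind": kind,
        "gesture": rec.label.gesture,
        "wrist": rec.label.wrist,
        "level": rec.label.level,
        "mvc": rec.mvc,
        "n_channels": rec.signal.shape[0],
        "n_samples": rec.signal.shape[1],
        "file": f"signals_{rec.task_id}.f32",
    }


def _write_signal(path: Path, signal: np.ndarray) -> None:
    np.asarray(signal, dtype="<f4").tofile(path)


def _read_signal(path: Path, n_channels: int, n_samples: int, task_id: str) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing signal file for task {task_id!r}: {path}")
    flat = np.fromfile(path, dtype="<f4")
    if flat.size != n_channels * n_samples:
        raise ValueError(
            f"signal file for task {task_id!r} has {flat.size} values, expected "
            f"{n_channels} x {n_samples}"
        )
    return flat.reshape(n_channels, n_samples)


def write_session(session: Session, path) -> Path:
    """Write a session bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tasks = []
    for rec in session.recordings:
        tasks.append(_rec_entry(rec, "task"))
        _write_signal(path / tasks[-1]["file"], rec.signal)
    for rec in session.mvc_recordings.values():
        tasks.append(_rec_entry(rec, "mvc"))
        _write_signal(path / tasks[-1]["file"], rec.signal)
    sidecar = {
        "fs": session.config.fs,
        "layout": session.layout.to_dict(),
        "seed": session.seed,
        "config": session.config.to_dict(),
        "mvc_table": {f"{g}|{w}": v for (g, w), v in session.mvc_table.items()},
        "tasks": tasks,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path) -> Session:
    """Read a session bundle written by :func:`write_session`."""
    path = Path(path)
    sidecar = json.loads((path / _SIDECAR).read_text())
    layout = GridLayout.from_dict(sidecar["layout"])
    config = SimulationConfig.from_dict(sidecar["config"])
    model = default_gesture_model(layout, config.jitter_mm, sidecar["seed"])
    mvc_table = {tuple(k.split("|")): v for k, v in sidecar["mvc_table"].items()}
    recordings, mvc_recordings = [], {}
    for t in sidecar["tasks"]:
        sig = _read_signal(path / t["file"], t["n_channels"], t["n_samples"],
                           t["task_id"])
        rec = EmgRecording(sig, sidecar["fs"],
                           TaskLabel(t["gesture"], t["wrist"], t["level"]),
                           layout, mvc=t["mvc"], task_id=t["task_id"])
        if t["kind"] == "mvc":
            mvc_recordings[(t["gesture"], t["wrist"])] = rec
        else:
            recordings.append(rec)
    return Session(layout, config, model, recordings, mvc_recordings,
                   mvc_table, sidecar["seed"])


def export_csv(rec: EmgRecording, path) -> Path:
    """One column per channel (header ch<i>), one row per sample."""
    path = Path(path)
    df = pd.DataFrame(rec.signal.T,
                      columns=[f"ch{i}" for i in range(rec.signal.shape[0])])
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def import_csv(path, fs: float, label: TaskLabel, layout: GridLayout,
               mvc: Optional[float] = None,
               task_id: Optional[str] = None) -> EmgRecording:
    df = pd.read_csv(path)
    return EmgRecording(df.to_numpy(dtype=np.float32).T, fs, label, layout,
                        mvc=mvc, task_id=task_id)


def write_model(model, path, name: str = "lda_model") -> Path:
    """Serialize a fitted LDA model next to the session data: a JSON header
    (classes, priors, shrinkage, array shapes) plus one float32 block."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {"means": model.means, "covariance": model.covariance,
              "coef": model.coef, "intercept": model.intercept}
    header = {
        "classes": [str(c) for c in model.classes],
        "priors": [float(p) for p in model.priors],
        "shrinkage": model.shrinkage,
        "arrays": {k: list(v.shape) for k, v in arrays.items()},
    }
    (path / f"{name}.json").write_text(json.dumps(header, indent=1))
    with open(path / f"{name}.f32", "wb") as f:
        for k in ("means", "covariance", "coef", "intercept"):
            np.asarray(arrays[k], dtype="<f4").tofile(f)
    return path


def read_model(path, name: str = "lda_model"):
    """Load a model written by :func:`write_model` (float32 precision)."""
    from .classify import LdaModel

    path = Path(path)
    header = json.loads((path / f"{name}.json").read_text())
    flat = np.fromfile(path / f"{name}.f32", dtype="<f4").astype(np.float64)
    arrays, offset = {}, 0
    for k in ("means", "covariance", "coef", "intercept"):
        shape = header["arrays"][k]
        size = int(np.prod(shape))
        arrays[k] = flat[offset:offset + size].reshape(shape)
        offset += size
    if offset != flat.size:
        raise ValueError(f"model block for {name!r} has {flat.size} values, "
                         f"expected {offset}")
    return LdaModel(np.array(header["classes"]), arrays["means"],
                    arrays["covariance"], np.array(header["priors"]),
                    header["shrinkage"], arrays["coef"], arrays["intercept"])


@dataclass
class RunConfig:
    """Configuration of a pipeline run, loadable from YAML.

    Groups the simulator parameters with the analysis knobs (feature deadband,
    SFS fold count, LDA shrinkage, online subject policy) and the master seed.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    feature_eps: Optional[float] = None  # None -> RMS-fraction deadband
    train_frac: float = 0.70
    cv_folds: int = 10
    lda_shrinkage: float = 1e-4
    sfs_channels: int = 8
    reaction_delay_s: float = 0.5
    activation_sigma: float = 0.08
    off_target_prob: float = 0.05
    seed: int = 42

    _KNOWN = ("simulation", "feature_eps", "train_frac", "cv_folds",
              "lda_shrinkage", "sfs_channels", "reaction_delay_s",
              "activation_sigma", "off_target_prob", "seed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls._KNOWN)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}) or {})
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self._KNOWN if k != "simulation"}
        d["simulation"] = self.simulation.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
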