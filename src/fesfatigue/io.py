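"""Measurement-set containers and the on-disk measurement-directory layout.

A measurement session is a directory with a ``manifest.json`` describing the
session (type, mode, subject constants, sampling rate) and one plain CSV per
contraction (columns ``t_ms`` and the channel, ``torque_Nm`` or
``theta_deg``).  Time series are sampled uniformly (300 Hz by default,
mirroring the acquisition rate of the experiments the synthetic sessions
emulate).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .protocol import PulseTrain

__all__ = ["Trace", "MeasurementSet", "write_measurement_dir",
           "read_measurement_dir", "provenance", "MeasurementError"]


class MeasurementError(ValueError):
    pass


@dataclass
class Trace:
    """One per-contraction time series (times local to train onset, ms)."""

    index: int
    role: str
    channel: str  # "torque_Nm" | "theta_deg"
    mode: str
    onset_ms: float
    fs_hz: float
    t_ms: np.ndarray
    values: np.ndarray
    train_spec: dict | None
    rest_after_ms: float = 0.0
    angle_deg: float | None = None
    block: int | None = None

    def train(self) -> PulseTrain | None:
        return PulseTrain.from_spec(self.train_spec) if self.train_spec else None


@dataclass
class MeasurementSet:
    session_type: str
    mode: str
    traces: list[Trace]
    meta: dict = field(default_factory=dict)

    def by_role(self, role: str) -> list[Trace]:
        return [t for t in self.traces if t.role == role]


def write_measurement_dir(ms: MeasurementSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in ms.traces:
        fname = f"trace_{tr.index:04d}.csv"
        with open(path / fname, "w") as fh:
            fh.write(f"t_ms,{tr.channel}\n")
            for t, v in zip(tr.t_ms, tr.values):
                fh.write(f"{t:.9f},{v:.9g}\n")
        entries.append({
            "file": fname, "index": tr.index, "role": tr.role,
            "channel": tr.channel, "mode": tr.mode, "onset_ms": tr.onset_ms,
            "fs_hz": tr.fs_hz, "train_spec": tr.train_spec,
            "rest_after_ms": tr.rest_after_ms, "angle_deg": tr.angle_deg,
            "block": tr.block,
        })
    manifest = {"session_type": ms.session_type, "mode": ms.mode,
                "meta": ms.meta, "traces": entries}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_measurement_dir(path: str | Path) -> MeasurementSet:
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise MeasurementError(f"missing manifest: {mpath}")
    manifest = json.loads(mpath.read_text())
    traces = []
    for row in manifest["traces"]:
        fpath = path / row["file"]
        if not fpath.exists():
            raise MeasurementError(f"missing trace file: {fpath}")
        data = np.genfromtxt(fpath, delimiter=",", names=True)
        t = np.atleast_1d(data["t_ms"])
        channel = row["channel"]
        v = np.atleast_1d(data[channel])
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise MeasurementError(f"non-finite values in {fpath}")
        if t.size >= 3:
            steps = np.diff(t)
            if np.max(np.abs(steps - steps[0])) > 1e-4:  # sub-0.1 μs jitter ok
                raise MeasurementError(f"non-uniform sampling in {fpath}")
        traces.append(Trace(
            index=int(row["index"]), role=row["role"], channel=channel,
            mode=row["mode"], onset_ms=float(row["onset_ms"]),
            fs_hz=float(row["fs_hz"]), t_ms=t, values=v,
            train_spec=row.get("train_spec"),
            rest_after_ms=float(row.get("rest_after_ms") or 0.0),
            angle_deg=row.get("angle_deg"), block=row.get("block")))
    return MeasurementSet(manifest["session_type"], manifest["mode"],
                          traces, manifest.get("meta", {}))


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Provenance block written into every CLI output: package version, seed
    and a hash of the effective configuration."""
    from . import __version__

    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {"package": "fesfatigue", "version": __version__, "seed": seed,
            "config_sha256": hashlib.sha256(blob).hexdigest()[:16]}
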