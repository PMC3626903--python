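"""Stimulation pulse trains and whole-session protocols.

A :class:`PulseTrain` is an ordered set of pulse times within one train:
either a constant-frequency train (CFT, equally spaced singlets) or a
variable-frequency train (VFT, an initial doublet 5 ms apart followed by
equally spaced singlets).  Pulse duration (μs) and amplitude are session
metadata only — the force model has no explicit term for either.

A :class:`StimulationProtocol` sequences trains with rest intervals.  The
fatiguing protocol used throughout is 15 blocks of
[50 Hz CFT, 12.5 Hz VFT, 13 × 33 Hz CFT] — 30 testing plus 195 fatiguing
trains, 225 in total — with 10 s rests after each train of the first testing
pair and a short constant rest (1 s isometric, 1.2 s free-swing) elsewhere.

Pulse placement convention: a train of frequency f and duration D carries
pulses at t = k·(1000/f) for every integer k ≥ 0 with t < D (half-open
interval).  VFT singlets are spaced one inter-pulse interval after the second
pulse of the doublet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "PulseTrain",
    "ProtocolEntry",
    "StimulationProtocol",
    "make_cft",
    "make_vft",
    "make_fatigue_protocol",
    "make_potentiation_protocol",
    "ROLE_POTENTIATION",
    "ROLE_TESTING_50CFT",
    "ROLE_TESTING_VFT",
    "ROLE_FATIGUING",
    "MODES",
]

ROLE_POTENTIATION = "potentiation"
ROLE_TESTING_50CFT = "testing_50CFT"
ROLE_TESTING_VFT = "testing_12.5VFT"
ROLE_FATIGUING = "fatiguing_33CFT"

MODES = ("isometric", "isovelocity", "free_swing")

_TIME_EPS = 1e-9


@dataclass(frozen=True)
class PulseTrain:
    """One stimulation train: pulse times (ms from train onset) plus metadata."""

    pulse_times: tuple[float, ...]
    train_duration: float  # ms
    kind: str  # "CFT" | "VFT"
    nominal_frequency: float  # Hz of the singlet spacing
    pulse_duration_label: float = 600.0  # μs, metadata only
    doublet_gap: float | None = None  # ms, VFT only

    def __post_init__(self) -> None:
        pt = np.asarray(self.pulse_times, dtype=float)
        if pt.size == 0:
            raise ValueError("a train must contain at least one pulse")
        if pt[0] != 0.0:
            raise ValueError("first pulse must be at t = 0")
        if np.any(np.diff(pt) <= 0):
            raise ValueError("pulse_times must be strictly increasing")
        if pt[-1] >= self.train_duration:
            raise ValueError("all pulse times must be < train_duration")
        if self.kind not in ("CFT", "VFT"):
            raise ValueError(f"unknown train kind {self.kind!r}")
        if self.kind == "VFT" and len(pt) >= 2:
            gap = self.doublet_gap if self.doublet_gap is not None else 5.0
            if abs(pt[1] - pt[0] - gap) > 1e-6:
                raise ValueError("a VFT must start with its doublet")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)

    def pulse_array(self) -> np.ndarray:
        return np.asarray(self.pulse_times, dtype=float)

    def spec(self) -> dict:
        """Constructor spec sufficient to rebuild the train bit-identically."""
        d = {
            "kind": self.kind,
            "frequency_hz": float(self.nominal_frequency),
            "train_duration_ms": float(self.train_duration),
            "pulse_duration_us": float(self.pulse_duration_label),
        }
        if self.kind == "VFT":
            d["doublet_gap_ms"] = float(self.doublet_gap if self.doublet_gap is not None else 5.0)
        return d

    @staticmethod
    def from_spec(d: dict) -> "PulseTrain":
        if d["kind"] == "CFT":
            return make_cft(d["frequency_hz"], d["train_duration_ms"], d["pulse_duration_us"])
        return make_vft(d["frequency_hz"], d["train_duration_ms"],
                        d.get("doublet_gap_ms", 5.0), d["pulse_duration_us"])


def make_cft(frequency: float, train_duration: float,
             pulse_duration_label: float = 600.0) -> PulseTrain:
    """Constant-frequency train: singlets at 0, IPI, 2·IPI, … while t < duration.

    >>> make_cft(50, 1000).n_pulses
    50
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if train_duration <= 0:
        raise ValueError("train_duration must be > 0")
    ipi = 1000.0 / frequency
    n = int(np.ceil(train_duration / ipi - _TIME_EPS))
    n = max(n, 1)
    times = tuple(k * ipi for k in range(n))
    return PulseTrain(times, float(train_duration), "CFT", float(frequency),
                      float(pulse_duration_label))


def make_vft(base_frequency: float, train_duration: float, doublet_gap: float = 5.0,
             pulse_duration_label: float = 600.0) -> PulseTrain:
    """Variable-frequency train: doublet at (0, gap), then singlets every IPI.

    Singlets are spaced one inter-pulse interval after the doublet's second
    pulse.  Pulses at or beyond ``train_duration`` are truncated.

    >>> make_vft(12.5, 1000).pulse_times[:3]
    (0.0, 5.0, 85.0)
    """
    if base_frequency <= 0:
        raise ValueError("base_frequency must be > 0")
    if train_duration <= 0:
        raise ValueError("train_duration must be > 0")
    ipi = 1000.0 / base_frequency
    if doublet_gap >= ipi:
        raise ValueError("doublet_gap must be smaller than the inter-pulse interval")
    times = [0.0]
    if doublet_gap < train_duration - _TIME_EPS:
        times.append(float(doublet_gap))
        t = doublet_gap + ipi
        while t < train_duration - _TIME_EPS:
            times.append(float(t))
            t += ipi
    return PulseTrain(tuple(times), float(train_duration), "VFT", float(base_frequency),
                      float(pulse_duration_label), doublet_gap=float(doublet_gap))


@dataclass(frozen=True)
class ProtocolEntry:
    train: PulseTrain
    onset: float  # ms, absolute
    rest_after: float  # ms
    role: str


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered trains with onsets, rests and roles, plus the contraction mode."""

    entries: tuple[ProtocolEntry, ...]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for k in range(1, len(self.entries)):
            p = self.entries[k - 1]
            if self.entries[k].onset <= p.onset:
                raise ValueError("train onsets must be strictly increasing")
            expected = p.onset + p.train.train_duration + p.rest_after
            if abs(self.entries[k].onset - expected) > 1e-6:
                raise ValueError("onset(k+1) must equal onset(k) + duration(k) + rest(k)")

    @property
    def n_trains(self) -> int:
        return len(self.entries)

    def count_role(self, role: str) -> int:
        return sum(1 for e in self.entries if e.role == role)

    @property
    def n_testing_pairs(self) -> int:
        n = 0
        for k in range(len(self.entries) - 1):
            if (self.entries[k].role == ROLE_TESTING_50CFT
                    and self.entries[k + 1].role == ROLE_TESTING_VFT):
                n += 1
        return n

    @property
    def total_duration(self) -> float:
        e = self.entries[-1]
        return e.onset + e.train.train_duration + e.rest_after

    def absolute_pulse_times(self) -> np.ndarray:
        """Flat (train_index, time_ms) array of every pulse in the protocol."""
        rows = []
        for i, e in enumerate(self.entries):
            for t in e.train.pulse_times:
                rows.append((i, e.onset + t))
        return np.asarray(rows, dtype=float)

    def regroup_pulses(self, flat: np.ndarray) -> list[np.ndarray]:
        """Group a flat (train_index, abs_time) export back into per-train
        onset-relative pulse times."""
        out = []
        for i, e in enumerate(self.entries):
            sel = flat[flat[:, 0] == i, 1] - e.onset
            out.append(np.sort(sel))
        return out

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "trains": [
                {**e.train.spec(), "rest_after_ms": float(e.rest_after), "role": e.role}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        entries = []
        onset = 0.0
        for row in d["trains"]:
            spec = {k: row[k] for k in row if k not in ("rest_after_ms", "role")}
            train = PulseTrain.from_spec(spec)
            entries.append(ProtocolEntry(train, onset, float(row["rest_after_ms"]),
                                         str(row["role"])))
            onset += train.train_duration + float(row["rest_after_ms"])
        return cls(tuple(entries), str(d["mode"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "StimulationProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def export_pulses(self, path: str | Path) -> None:
        """Two-column text export: train_index, absolute time in ms."""
        flat = self.absolute_pulse_times()
        with open(path, "w") as fh:
            fh.write("train_index\ttime_ms\n")
            for i, t in flat:
                fh.write(f"{int(i)}\t{t:.6f}\n")


def _sequence(trains_rests_roles: Iterable[tuple[PulseTrain, float, str]],
              mode: str) -> StimulationProtocol:
    entries = []
    onset = 0.0
    for train, rest, role in trains_rests_roles:
        entries.append(ProtocolEntry(train, onset, float(rest), role))
        onset += train.train_duration + rest
    return StimulationProtocol(tuple(entries), mode)


def make_fatigue_protocol(mode: str, train_duration: float,
                          pulse_duration_label: float = 600.0,
                          first_pair_rest: float = 10_000.0,
                          inter_train_rest: float = 1000.0) -> StimulationProtocol:
    """The 225-train fatiguing protocol.

    15 blocks of [50CFT, 12.5VFT, 13 × 33CFT]; the two trains of the first
    testing pair are each followed by ``first_pair_rest`` (10 s), every other
    train by ``inter_train_rest`` (1 s isometric, 1.2 s free-swing).
    """
    if first_pair_rest <= 0 or inter_train_rest <= 0:
        raise ValueError("rest times must be > 0")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    cft50 = make_cft(50.0, train_duration, pulse_duration_label)
    vft = make_vft(12.5, train_duration, 5.0, pulse_duration_label)
    cft33 = make_cft(33.0, train_duration, pulse_duration_label)
    seq: list[tuple[PulseTrain, float, str]] = []
    for block in range(15):
        pair_rest = first_pair_rest if block == 0 else inter_train_rest
        seq.append((cft50, pair_rest, ROLE_TESTING_50CFT))
        seq.append((vft, pair_rest, ROLE_TESTING_VFT))
        for _ in range(13):
            seq.append((cft33, inter_train_rest, ROLE_FATIGUING))
    return _sequence(seq, mode)


def make_potentiation_protocol(mode: str = "isometric") -> StimulationProtocol:
    """Twelve 14 Hz CFTs of 0.8 s with 5 s rests, used to potentiate the muscle."""
    train = make_cft(14.0, 800.0, 600.0)
    return _sequence([(train, 5000.0, ROLE_POTENTIATION) for _ in range(12)], mode)
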