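"""Canonical trial/calibration file formats and recording validation.

A trial is one performance of the suturing task: three 6-DOF pose streams
(Maryland dissector, needle driver, endoscope) sampled at approximately
20 Hz by a magnetic tracker, plus two grip-sensor voltage streams from
handle-mounted flex sensors.  Everything downstream (calibration,
kinematics, feature extraction, modeling) consumes the types defined here.

Units: positions in cm, orientations as unit quaternions (w, x, y, z),
time in seconds relative to the trial start, voltages in volts.

On-disk dialect: a UTF-8 CSV with header ``t,channel,x,y,z,qw,qx,qy,qz,
voltage``; pose rows leave ``voltage`` empty and grip rows leave the pose
fields empty.  A JSON sidecar (``<trial>.meta.json``) carries the subject
id, trial index, nominal rate, and optional ground-truth rating.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "POSE_CHANNELS",
    "GRIP_CHANNELS",
    "OSATS_DOMAINS",
    "FormatError",
    "ValidationError",
    "SensorSample",
    "PoseStream",
    "GripStream",
    "TrialMeta",
    "TrialRecording",
    "OSATSRating",
    "Issue",
    "read_trial",
    "write_trial",
    "validate_trial",
]

POSE_CHANNELS = ("maryland_pose", "needle_pose", "scope_pose")
GRIP_CHANNELS = ("maryland_grip", "needle_grip")
TOOLS = ("maryland", "needle")

#: Fixed OSATS domain order used throughout.
OSATS_DOMAINS = (
    "respect_for_tissue",
    "time_and_motion",
    "instrument_handling",
    "flow_of_operation",
    "knowledge_of_procedure",
)

#: Hard cap on trial duration, seconds (data acquisition stops at 10 min).
MAX_TRIAL_SECONDS = 600.0

_QUAT_TOL = 1e-6


class FormatError(ValueError):
    """A file does not conform to the trial CSV dialect."""


class ValidationError(ValueError):
    """A recording violates a structural invariant."""


@dataclass(frozen=True)
class SensorSample:
    """One timestamped 6-DOF pose measurement.

    ``pos`` is the sensor position in cm in the world frame; ``quat`` is
    the sensor-to-world rotation as a unit quaternion ``(w, x, y, z)``.
    """

    t: float
    pos: np.ndarray
    quat: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        object.__setattr__(self, "quat", np.asarray(self.quat, dtype=float))
        if not math.isfinite(self.t) or self.t < 0:
            raise ValidationError(f"sample time must be finite and >= 0, got {self.t}")
        if self.pos.shape != (3,):
            raise ValidationError("pos must be a 3-vector")
        if self.quat.shape != (4,):
            raise ValidationError("quat must be a 4-vector (w, x, y, z)")
        n = float(np.linalg.norm(self.quat))
        if abs(n - 1.0) > _QUAT_TOL:
            raise ValidationError(f"quaternion norm {n:.6f} not within {_QUAT_TOL} of 1")


class PoseStream:
    """Time-ordered pose samples for one channel, stored as arrays."""

    def __init__(self, t: np.ndarray, pos: np.ndarray, quat: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.pos = np.asarray(pos, dtype=float)
        self.quat = np.asarray(quat, dtype=float)
        if self.t.ndim != 1:
            raise ValidationError("t must be 1-D")
        n = self.t.size
        if self.pos.shape != (n, 3) or self.quat.shape != (n, 4):
            raise ValidationError("pos must be (N,3) and quat (N,4) matching t")

    def __len__(self) -> int:
        return self.t.size

    def __iter__(self) -> Iterable[SensorSample]:
        for i in range(len(self)):
            yield SensorSample(self.t[i], self.pos[i], self.quat[i])

    @classmethod
    def from_samples(cls, samples: Iterable[SensorSample]) -> "PoseStream":
        samples = list(samples)
        return cls(
            np.array([s.t for s in samples]),
            np.array([s.pos for s in samples]),
            np.array([s.quat for s in samples]),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PoseStream)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.quat, other.quat)
        )


class GripStream:
    """Time-ordered (t, voltage) samples for one grip sensor."""

    def __init__(self, t: np.ndarray, voltage: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.voltage = np.asarray(voltage, dtype=float)
        if self.t.shape != self.voltage.shape or self.t.ndim != 1:
            raise ValidationError("t and voltage must be matching 1-D arrays")

    def __len__(self) -> int:
        return self.t.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GripStream)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.voltage, other.voltage)
        )


@dataclass
class TrialMeta:
    subject_id: str = "unknown"
    trial_index: int = 1
    nominal_rate_hz: float = 20.0
    completed: bool = True
    seed: int | None = None
    rating: "OSATSRating | None" = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trial_index"] = int(self.trial_index)
        d["nominal_rate_hz"] = float(self.nominal_rate_hz)
        d["completed"] = bool(self.completed)
        if self.seed is not None:
            d["seed"] = int(self.seed)
        if self.rating is not None:
            d["rating"] = {"domains": [int(x) for x in self.rating.domains]}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeta":
        d = dict(d)
        r = d.get("rating")
        if r is not None:
            d["rating"] = OSATSRating(tuple(r["domains"]))
        return cls(**d)


@dataclass
class TrialRecording:
    """Raw sensor streams plus metadata for one task performance."""

    streams: dict[str, PoseStream]
    grip: dict[str, GripStream]
    meta: TrialMeta = field(default_factory=TrialMeta)

    def duration(self) -> float:
        """Span from the earliest to the latest timestamp, seconds."""
        t0 = min(s.t[0] for s in self._all_streams() if len(s))
        t1 = max(s.t[-1] for s in self._all_streams() if len(s))
        return float(t1 - t0)

    def _all_streams(self):
        return list(self.streams.values()) + list(self.grip.values())

    def check(self) -> None:
        """Raise :class:`ValidationError` on any structural violation."""
        for ch in POSE_CHANNELS:
            if ch not in self.streams:
                raise ValidationError(f"missing pose stream {ch!r}")
        for tool in TOOLS:
            if tool not in self.grip:
                raise ValidationError(f"missing grip stream {tool!r}")
        for name, s in list(self.streams.items()) + list(self.grip.items()):
            if len(s) == 0:
                raise ValidationError(f"empty channel {name!r}")
            if np.any(np.diff(s.t) <= 0):
                raise ValidationError(f"non-monotone timestamps in {name!r}")
            if not np.all(np.isfinite(s.t)) or s.t[0] < 0:
                raise ValidationError(f"invalid timestamps in {name!r}")
        for name, s in self.streams.items():
            norms = np.linalg.norm(s.quat, axis=1)
            if np.any(np.abs(norms - 1.0) > _QUAT_TOL):
                raise ValidationError(f"non-unit quaternion in {name!r}")
            if not np.all(np.isfinite(s.pos)):
                raise ValidationError(f"non-finite position in {name!r}")
        if self.duration() > MAX_TRIAL_SECONDS:
            raise ValidationError(
                f"duration {self.duration():.1f} s exceeds {MAX_TRIAL_SECONDS:.0f} s cap"
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TrialRecording)
            and self.streams == other.streams
            and self.grip == other.grip
            and self.meta == other.meta
        )


@dataclass(frozen=True)
class OSATSRating:
    """Five OSATS domain scores (each 1-5) for one trial.

    ``summed`` ranges 5-25; ``rounded_avg`` is round(summed / 5).
    """

    domains: tuple[int, int, int, int, int]

    def __post_init__(self):
        if len(self.domains) != 5:
            raise ValidationError("exactly five domain scores required")
        for d in self.domains:
            if not (isinstance(d, (int, np.integer)) and 1 <= d <= 5):
                raise ValidationError(f"domain score {d!r} outside 1..5")
        object.__setattr__(self, "domains", tuple(int(d) for d in self.domains))

    @property
    def summed(self) -> int:
        return int(sum(self.domains))

    @property
    def rounded_avg(self) -> int:
        # summed/5 is never exactly half-way for integer sums not divisible
        # by 5/2, but use round-half-away to match ordinary rounding.
        return int(math.floor(self.summed / 5 + 0.5))


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    location: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.location}: {self.message}"


# ---------------------------------------------------------------------------
# CSV dialect I/O

_COLUMNS = ["t", "channel", "x", "y", "z", "qw", "qx", "qy", "qz", "voltage"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_trial(rec: TrialRecording, path: str | Path) -> None:
    """Write a recording in the trial CSV dialect plus its JSON sidecar.

    The recording is validated first; nothing is written on failure.
    Numeric fields are stored with 17 significant digits so a read-back
    round-trips to within 1e-9 (in fact exactly for doubles).
    """
    rec.check()
    path = Path(path)
    frames = []
    for ch in POSE_CHANNELS:
        s = rec.streams[ch]
        frames.append(pd.DataFrame({
            "t": s.t, "channel": ch,
            "x": s.pos[:, 0], "y": s.pos[:, 1], "z": s.pos[:, 2],
            "qw": s.quat[:, 0], "qx": s.quat[:, 1],
            "qy": s.quat[:, 2], "qz": s.quat[:, 3],
            "voltage": np.nan,
        }))
    for tool in TOOLS:
        g = rec.grip[tool]
        frames.append(pd.DataFrame({
            "t": g.t, "channel": f"{tool}_grip",
            "x": np.nan, "y": np.nan, "z": np.nan,
            "qw": np.nan, "qx": np.nan, "qy": np.nan, "qz": np.nan,
            "voltage": g.voltage,
        }))
    df = pd.concat(frames, ignore_index=True)[_COLUMNS]
    df.to_csv(path, index=False, float_format="%.17g")
    _meta_path(path).write_text(json.dumps(rec.meta.to_dict(), indent=1))


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial CSV (and sidecar metadata, if present) into memory."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path.name}")

    streams: dict[str, PoseStream] = {}
    grip: dict[str, GripStream] = {}
    for ch, sub in df.groupby("channel", sort=False):
        if ch in POSE_CHANNELS:
            streams[ch] = PoseStream(
                sub["t"].to_numpy(),
                sub[["x", "y", "z"]].to_numpy(),
                sub[["qw", "qx", "qy", "qz"]].to_numpy(),
            )
        elif ch in GRIP_CHANNELS:
            grip[ch.removesuffix("_grip")] = GripStream(
                sub["t"].to_numpy(), sub["voltage"].to_numpy()
            )
        else:
            raise FormatError(f"unknown channel {ch!r} in {path.name}")
    for ch in POSE_CHANNELS:
        if ch not in streams:
            raise FormatError(f"missing channel {ch!r} in {path.name}")
    for tool in TOOLS:
        if tool not in grip:
            raise FormatError(f"missing channel '{tool}_grip' in {path.name}")

    meta = TrialMeta()
    mp = _meta_path(path)
    if mp.exists():
        meta = TrialMeta.from_dict(json.loads(mp.read_text()))
    rec = TrialRecording(streams=streams, grip=grip, meta=meta)
    rec.check()
    return rec


def validate_trial(rec: TrialRecording) -> list[Issue]:
    """Report structural and plausibility issues; never raises.

    An empty list means the recording satisfies every invariant and each
    stream's median sampling interval lies in [0.033, 0.1] s (10-30 Hz,
    bracketing the nominal ~20 Hz acquisition rate).
    """
    issues: list[Issue] = []
    for ch in POSE_CHANNELS:
        if ch not in rec.streams:
            issues.append(Issue("error", ch, "missing pose stream"))
    for tool in TOOLS:
        if tool not in rec.grip:
            issues.append(Issue("error", f"{tool}_grip", "missing grip stream"))

    named = [(ch, s) for ch, s in rec.streams.items()]
    named += [(f"{tool}_grip", g) for tool, g in rec.grip.items()]
    for name, s in named:
        if len(s) == 0:
            issues.append(Issue("error", name, "empty channel"))
            continue
        if np.any(np.diff(s.t) <= 0):
            issues.append(Issue("error", name, "timestamps not strictly increasing"))
        if len(s) > 1:
            dt = float(np.median(np.diff(s.t)))
            if not (0.033 <= dt <= 0.1):
                issues.append(Issue(
                    "error", name,
                    f"median sampling interval {dt:.4f} s outside [0.033, 0.1] s",
                ))
    for name, s in rec.streams.items():
        if len(s) and np.any(np.abs(np.linalg.norm(s.quat, axis=1) - 1.0) > _QUAT_TOL):
            issues.append(Issue("error", name, "non-unit quaternion"))
    try:
        dur = rec.duration()
    except ValueError:
        dur = 0.0
    if dur > MAX_TRIAL_SECONDS:
        issues.append(Issue(
            "error", "trial",
            f"duration {dur:.1f} s exceeds {MAX_TRIAL_SECONDS:.0f} s cap",
        ))
    return issues
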