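"""Trial file formats.

One channel per CSV file, plain text so every artifact is inspectable:

    # axis=VT
    # quantity=acceleration
    # units=m/s^2
    # nominal_rate=128
    time_s,value
    0.000000000,0.012345

A trial is a set of channel files sharing a stem plus a JSON sidecar
``<stem>_meta.json`` holding the trial id, task, device role, the full
simulation config for synthetic trials, and the true event times when
known. Kinematic triplets are written as a single four-column CSV
(``time_s,disp_m,vel_mps,acc_mps2``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ParseError
from .features import Task
from .signal import Axis, KinematicTriplet, Quantity, SampledSignal, UNITS

__all__ = ["DeviceRole", "TrialRecording", "read_channel", "write_channel",
           "read_trial", "write_trial", "read_kinematics", "write_kinematics"]


class DeviceRole(str, Enum):
    """Which device a channel set emulates; fixes quantity and nominal rate."""

    HEADSET_POSITION = "headset_position"   # fused displacement, ~30 Hz
    HEAD_IMU = "head_imu"                   # gravity-corrected acceleration, 128 Hz
    LUMBAR_IMU = "lumbar_imu"

    @property
    def quantity(self) -> Quantity:
        return (Quantity.DISPLACEMENT if self is DeviceRole.HEADSET_POSITION
                else Quantity.ACCELERATION)

    @property
    def nominal_rate(self) -> float:
        return 30.0 if self is DeviceRole.HEADSET_POSITION else 128.0


@dataclass
class TrialRecording:
    """One device's channels for one trial, plus free-form metadata."""

    trial_id: str
    task: Task
    device_role: DeviceRole
    channels: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.device_role = DeviceRole(self.device_role)
        self.channels = {Axis(k): v for k, v in self.channels.items()}
        if Axis.VT not in self.channels:
            raise ParseError(f"trial {self.trial_id!r}: missing required VT channel")
        for axis, sig in self.channels.items():
            if sig.quantity is not self.device_role.quantity:
                raise ParseError(
                    f"trial {self.trial_id!r}: {axis.value} channel is "
                    f"{sig.quantity.value}, but role {self.device_role.value} "
                    f"expects {self.device_role.quantity.value}")

    @property
    def vt(self) -> SampledSignal:
        return self.channels[Axis.VT]


def write_channel(path: str | Path, signal: SampledSignal) -> Path:
    """Write one channel CSV with metadata comment lines."""
    path = Path(path)
    rate = "" if signal.nominal_rate is None else f"{signal.nominal_rate:g}"
    lines = [
        f"# axis={signal.axis.value}",
        f"# quantity={signal.quantity.value}",
        f"# units={signal.units}",
        f"# nominal_rate={rate}",
        "time_s,value",
    ]
    lines += [f"{t:.9f},{v:.9g}" for t, v in zip(signal.timestamps, signal.values)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_channel(path: str | Path) -> SampledSignal:
    """Read one channel CSV; validates monotone time, finiteness, units."""
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    values: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "time_s,value":
                    raise ParseError(f"{path}:{lineno}: expected header 'time_s,value', got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if not (np.isfinite(t) and np.isfinite(v)):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            if times and t <= times[-1]:
                raise ParseError(
                    f"{path}:{lineno}: timestamp {t} not after previous {times[-1]}")
            times.append(t)
            values.append(v)
    if not header_seen or not times:
        raise ParseError(f"{path}: no data rows found")
    for key in ("axis", "quantity"):
        if key not in meta:
            raise ParseError(f"{path}: missing '# {key}=' metadata line")
    quantity = Quantity(meta["quantity"])
    if "units" in meta and meta["units"] != UNITS[quantity]:
        raise ParseError(
            f"{path}: units {meta['units']!r} do not match quantity "
            f"{quantity.value} ({UNITS[quantity]})")
    rate = float(meta["nominal_rate"]) if meta.get("nominal_rate") else None
    return SampledSignal(np.asarray(times), np.asarray(values),
                         axis=Axis(meta["axis"]), quantity=quantity, nominal_rate=rate)


def _role_suffix(role: DeviceRole) -> str:
    return {"headset_position": "pos", "head_imu": "imu", "lumbar_imu": "imu_lb"}[role.value]


def write_trial(directory: str | Path, recording: TrialRecording) -> list[Path]:
    """Write all channels plus the meta sidecar; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = _role_suffix(recording.device_role)
    written: list[Path] = []
    for axis, sig in sorted(recording.channels.items(), key=lambda kv: kv[0].value):
        tag = "" if axis is Axis.VT else f"_{axis.value.lower()}"
        written.append(write_channel(directory / f"{recording.trial_id}_{suffix}{tag}.csv", sig))
    meta = dict(recording.meta)
    meta.update(trial_id=recording.trial_id, task=recording.task.value,
                device_role=recording.device_role.value)
    meta_path = directory / f"{recording.trial_id}_{suffix}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written


def read_trial(directory: str | Path, trial_id: str, role: DeviceRole) -> TrialRecording:
    """Read back a trial written by :func:`write_trial`."""
    directory = Path(directory)
    suffix = _role_suffix(DeviceRole(role))
    meta_path = directory / f"{trial_id}_{suffix}_meta.json"
    if not meta_path.exists():
        raise ParseError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    channels: dict[Axis, SampledSignal] = {}
    for axis in Axis:
        tag = "" if axis is Axis.VT else f"_{axis.value.lower()}"
        path = directory / f"{trial_id}_{suffix}{tag}.csv"
        if path.exists():
            channels[axis] = read_channel(path)
    return TrialRecording(trial_id=trial_id, task=Task(meta["task"]),
                          device_role=DeviceRole(meta["device_role"]),
                          channels=channels, meta=meta)


def write_kinematics(path: str | Path, kin: KinematicTriplet) -> Path:
    """Write a kinematic triplet as time_s,disp_m,vel_mps,acc_mps2."""
    path = Path(path)
    rows = ["time_s,disp_m,vel_mps,acc_mps2"]
    rows += [
        f"{t:.9f},{d:.9g},{v:.9g},{a:.9g}"
        for t, d, v, a in zip(kin.timestamps, kin.displacement.values,
                              kin.velocity.values, kin.acceleration.values)
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


def read_kinematics(path: str | Path, axis: Axis = Axis.VT) -> KinematicTriplet:
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.size < 2:
        raise ParseError(f"{path}: kinematics file needs at least 2 rows")
    t = data["time_s"]
    rate = 1.0 / float(np.median(np.diff(t)))
    return KinematicTriplet(
        SampledSignal(t, data["disp_m"], axis=axis, quantity=Quantity.DISPLACEMENT,
                      nominal_rate=rate),
        SampledSignal(t, data["vel_mps"], axis=axis, quantity=Quantity.VELOCITY,
                      nominal_rate=rate),
        SampledSignal(t, data["acc_mps2"], axis=axis, quantity=Quantity.ACCELERATION,
                      nominal_rate=rate),
    )
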