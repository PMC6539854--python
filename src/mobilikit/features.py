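"""Phase segmentation and clinical mobility features.

From a drift-corrected vertical kinematic triplet this module locates the
rise (sit-to-stand) and descent (stand-to-sit) movement phases and derives
the performance outcomes reported for the two clinical tests:

* five-time sit-to-stand (STS): total duration (first rise initiation to
  last descent completion), mean stand-phase and sit-phase durations, and
  the maximum vertical acceleration and upward velocity;
* timed up and go (TUG): total duration (rise initiation to descent
  completion) and the same maxima.

Phase boundaries come from a sustained velocity-threshold rule refined to
the nearest preceding/following zero crossing, with a displacement-
excursion guard so that gait-related vertical bounce during the walking
part of a TUG trial is never mistaken for a chair transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import AmbiguousPhaseError, DataIntegrityError, NoMovementError
from .signal import KinematicTriplet

__all__ = ["Task", "PhaseEvents", "FeatureSet", "detect_phases",
           "sts_features", "tug_features", "extract_features"]


class Task(str, Enum):
    STS = "STS"
    TUG = "TUG"


@dataclass(frozen=True)
class PhaseEvents:
    """Rise/descent phase boundaries, paired in temporal order."""

    rise_onsets: np.ndarray
    rise_offsets: np.ndarray
    descent_onsets: np.ndarray
    descent_offsets: np.ndarray

    def __post_init__(self) -> None:
        for name in ("rise_onsets", "rise_offsets", "descent_onsets", "descent_offsets"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise DataIntegrityError(f"{name} must be 1-D")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise DataIntegrityError(f"{name} must be strictly increasing")
        n = self.n_cycles
        if not (self.rise_offsets.size == n and self.descent_onsets.size == n
                and self.descent_offsets.size == n):
            raise DataIntegrityError("unpaired rise/descent events")
        for r_on, r_off, d_on, d_off in zip(self.rise_onsets, self.rise_offsets,
                                            self.descent_onsets, self.descent_offsets):
            if not (r_on < r_off <= d_on < d_off):
                raise DataIntegrityError(
                    "events must interleave rise_onset < rise_offset <= "
                    "descent_onset < descent_offset within each cycle")

    @property
    def n_cycles(self) -> int:
        return self.rise_onsets.size


@dataclass(frozen=True)
class FeatureSet:
    """Performance outcomes of one trial. STS-only fields are None for TUG."""

    task: Task
    total_time: float
    max_acceleration: float
    max_velocity: float
    mean_stand_time: float | None = None
    mean_sit_time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        if self.total_time <= 0:
            raise DataIntegrityError("total_time must be positive")

    def as_dict(self) -> dict:
        return {
            "task": self.task.value,
            "total_time_s": self.total_time,
            "mean_stand_time_s": self.mean_stand_time,
            "mean_sit_time_s": self.mean_sit_time,
            "max_acceleration_mps2": self.max_acceleration,
            "max_velocity_mps": self.max_velocity,
        }


def _zero_cross_back(v: np.ndarray, i: int, sign: int) -> int:
    """Walk back from index i while velocity keeps the phase's sign."""
    while i > 0 and sign * v[i - 1] > 0:
        i -= 1
    return i


def _zero_cross_fwd(v: np.ndarray, i: int, sign: int) -> int:
    while i < v.size - 1 and sign * v[i + 1] > 0:
        i += 1
    return i


def _sustained_runs(above: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    return [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_len]


def detect_phases(kin: KinematicTriplet,
                  threshold_frac: float = 0.1,
                  min_phase: float = 0.1,
                  min_excursion_frac: float = 0.5) -> PhaseEvents:
    """Segment rise and descent phases from the vertical velocity.

    A candidate rise is a stretch where velocity exceeds
    ``threshold_frac`` of the peak speed for at least ``min_phase``
    seconds; its onset/offset are refined backward/forward to the nearest
    zero crossing, where the movement actually starts and stops. Descents
    are detected symmetrically on negative velocity. A candidate is kept
    only if the displacement change across it reaches
    ``min_excursion_frac`` of the trial's displacement range — this
    rejects walking bounce and noise wiggles that cross the velocity
    threshold without going anywhere.

    Raises :class:`NoMovementError` when no suprathreshold excursion
    exists (e.g. constant displacement).
    """
    t = kin.timestamps
    v = kin.velocity.values
    d = kin.displacement.values
    v_peak = float(np.max(np.abs(v)))
    d_range = float(d.max() - d.min())
    if v_peak <= 0 or d_range < 1e-9:
        raise NoMovementError("no movement found in the trial")
    threshold = threshold_frac * v_peak
    fs = (t.size - 1) / (t[-1] - t[0])
    min_len = max(1, int(np.ceil(min_phase * fs)))

    def candidates(sign: int) -> list[tuple[int, int]]:
        runs = _sustained_runs(sign * v > threshold, min_len)
        seen: set[tuple[int, int]] = set()
        out = []
        for s, e in runs:
            on = _zero_cross_back(v, s, sign)
            off = _zero_cross_fwd(v, e, sign)
            excursion = sign * (d[off] - d[on])
            if excursion < min_excursion_frac * d_range:
                continue
            if (on, off) in seen:
                continue
            seen.add((on, off))
            out.append((on, off))
        return out

    rises = candidates(+1)
    descents = candidates(-1)
    if not rises or not descents:
        raise NoMovementError("no complete rise/descent cycle found")
    if len(rises) != len(descents):
        raise AmbiguousPhaseError(
            f"unpaired phases: {len(rises)} rises vs {len(descents)} descents")
    return PhaseEvents(
        rise_onsets=t[[r[0] for r in rises]],
        rise_offsets=t[[r[1] for r in rises]],
        descent_onsets=t[[c[0] for c in descents]],
        descent_offsets=t[[c[1] for c in descents]],
    )


def _window_maxima(kin: KinematicTriplet, t_start: float, t_end: float) -> tuple[float, float]:
    t = kin.timestamps
    w = (t >= t_start) & (t <= t_end)
    max_acc = float(np.max(np.abs(kin.acceleration.values[w])))
    max_vel = float(np.max(kin.velocity.values[w]))  # maximum upward velocity
    return max_acc, max_vel


def sts_features(kin: KinematicTriplet, phases: PhaseEvents) -> FeatureSet:
    """Five-time sit-to-stand outcomes.

    Total time runs from the first rise initiation to the last descent
    completion. The stand phase is the rising movement (onset to offset)
    and the sit phase the descending movement; maxima are taken over the
    whole active window. Maximum velocity is the peak *upward* velocity —
    the clinically reported quantity.
    """
    if phases.n_cycles < 1:
        raise AmbiguousPhaseError("need at least one complete cycle")
    t0 = float(phases.rise_onsets[0])
    t1 = float(phases.descent_offsets[-1])
    max_acc, max_vel = _window_maxima(kin, t0, t1)
    return FeatureSet(
        task=Task.STS,
        total_time=t1 - t0,
        mean_stand_time=float(np.mean(phases.rise_offsets - phases.rise_onsets)),
        mean_sit_time=float(np.mean(phases.descent_offsets - phases.descent_onsets)),
        max_acceleration=max_acc,
        max_velocity=max_vel,
    )


def tug_features(kin: KinematicTriplet, phases: PhaseEvents) -> FeatureSet:
    """Timed-up-and-go outcomes: one rise, one descent, total time and maxima."""
    if phases.n_cycles != 1:
        raise AmbiguousPhaseError(
            f"timed-up-and-go expects exactly one rise/descent cycle, found "
            f"{phases.n_cycles} (rises at {phases.rise_onsets.round(2).tolist()})")
    t0 = float(phases.rise_onsets[0])
    t1 = float(phases.descent_offsets[-1])
    max_acc, max_vel = _window_maxima(kin, t0, t1)
    return FeatureSet(task=Task.TUG, total_time=t1 - t0,
                      max_acceleration=max_acc, max_velocity=max_vel)


def extract_features(kin: KinematicTriplet, task: Task | str,
                     threshold_frac: float = 0.1, min_phase: float = 0.1) -> FeatureSet:
    """Detect phases and compute the task's feature set in one call."""
    task = Task(task)
    phases = detect_phases(kin, threshold_frac=threshold_frac, min_phase=min_phase)
    if task is Task.STS:
        return sts_features(kin, phases)
    return tug_features(kin, phases)
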