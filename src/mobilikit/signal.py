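"""Foundational time-series types and operators.

The universal currency of the pipeline is :class:`SampledSignal`: one
time-stamped scalar channel with body-axis and physical-quantity metadata.
On top of it this module provides the four primitives every later stage is
built from: uniform resampling, Butterworth filtering (zero-phase by
default), trapezoid cumulative integration and central-difference
differentiation.

All operators are linear and preserve the signal's axis; integration and
differentiation move the quantity down/up the displacement–velocity–
acceleration ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .errors import DataIntegrityError, NonUniformSamplingError, QuantityError, ConfigError

__all__ = [
    "Axis",
    "Quantity",
    "SampledSignal",
    "KinematicTriplet",
    "FilterSpec",
    "LOWPASS_SMOOTHING",
    "HIGHPASS_DRIFT",
    "resample_uniform",
    "butterworth",
    "cumulative_integrate",
    "differentiate",
]


class Axis(str, Enum):
    """Body-frame axis: vertical, anterior-posterior, medio-lateral."""

    VT = "VT"
    AP = "AP"
    ML = "ML"


class Quantity(str, Enum):
    DISPLACEMENT = "displacement"
    VELOCITY = "velocity"
    ACCELERATION = "acceleration"


#: SI units per quantity, used for serialization and validation.
UNITS = {
    Quantity.DISPLACEMENT: "m",
    Quantity.VELOCITY: "m/s",
    Quantity.ACCELERATION: "m/s^2",
}

_DEMOTE = {
    Quantity.ACCELERATION: Quantity.VELOCITY,
    Quantity.VELOCITY: Quantity.DISPLACEMENT,
}
_PROMOTE = {v: k for k, v in _DEMOTE.items()}


@dataclass(frozen=True)
class SampledSignal:
    """One time-stamped scalar channel.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing.
    values
        Scalar samples; units follow ``quantity`` (m, m/s or m/s^2).
    axis
        Body axis the channel measures along.
    quantity
        Physical quantity of the samples.
    nominal_rate
        The advertised sampling rate in Hz (e.g. 30 for the headset
        position stream, 128 for the reference IMU). Informational; the
        actual rate is derived from the timestamps.
    """

    timestamps: np.ndarray
    values: np.ndarray
    axis: Axis = Axis.VT
    quantity: Quantity = Quantity.DISPLACEMENT
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        x = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", x)
        object.__setattr__(self, "axis", Axis(self.axis))
        object.__setattr__(self, "quantity", Quantity(self.quantity))
        if t.ndim != 1 or x.ndim != 1:
            raise DataIntegrityError("timestamps and values must be 1-D arrays")
        if t.shape != x.shape:
            raise DataIntegrityError(
                f"length mismatch: {t.size} timestamps vs {x.size} values"
            )
        if t.size < 1:
            raise DataIntegrityError("signal must contain at least one sample")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise DataIntegrityError("timestamps/values contain NaN or inf")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataIntegrityError("timestamps must be strictly increasing")

    # -- derived properties -------------------------------------------------

    @property
    def n(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def units(self) -> str:
        return UNITS[self.quantity]

    @property
    def rate(self) -> float:
        """Effective sampling rate estimated from the median sample spacing."""
        if self.n < 2:
            raise DataIntegrityError("rate undefined for a single sample")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def is_uniform(self, rel_tol: float = 1e-6) -> bool:
        """True when sample spacing is constant to within ``rel_tol``."""
        if self.n < 2:
            return True
        dt = np.diff(self.timestamps)
        return bool(np.max(np.abs(dt - dt.mean())) <= rel_tol * dt.mean())

    def with_values(self, values: np.ndarray, quantity: Quantity | None = None) -> "SampledSignal":
        """Copy of this signal with new values (and optionally new quantity)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       quantity=self.quantity if quantity is None else quantity)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification.

    The pipeline uses two instances of this: a 4th-order 5 Hz low-pass for
    smoothing both channels and a 4th-order 0.1 Hz high-pass for
    integration-drift removal.
    """

    cutoff: float
    order: int = 4
    kind: str = "lowpass"  # "lowpass" | "highpass"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ConfigError(f"order must be >= 1, got {self.order}")
        if self.kind not in ("lowpass", "highpass"):
            raise ConfigError(f"kind must be lowpass or highpass, got {self.kind!r}")


#: 4th-order 5 Hz low-pass applied to every channel after resampling.
LOWPASS_SMOOTHING = FilterSpec(cutoff=5.0, order=4, kind="lowpass")
#: 4th-order 0.1 Hz high-pass used as one of the two drift corrections.
HIGHPASS_DRIFT = FilterSpec(cutoff=0.1, order=4, kind="highpass")


@dataclass(frozen=True)
class KinematicTriplet:
    """Displacement, velocity and acceleration on one shared uniform time base."""

    displacement: SampledSignal
    velocity: SampledSignal
    acceleration: SampledSignal

    def __post_init__(self) -> None:
        d, v, a = self.displacement, self.velocity, self.acceleration
        if not (d.n == v.n == a.n):
            raise DataIntegrityError("triplet members differ in length")
        if not (np.array_equal(d.timestamps, v.timestamps)
                and np.array_equal(d.timestamps, a.timestamps)):
            raise DataIntegrityError("triplet members must share one time base")
        expected = (Quantity.DISPLACEMENT, Quantity.VELOCITY, Quantity.ACCELERATION)
        got = (d.quantity, v.quantity, a.quantity)
        if got != expected:
            raise QuantityError(f"triplet quantities must be {expected}, got {got}")

    @property
    def timestamps(self) -> np.ndarray:
        return self.displacement.timestamps

    def by_symbol(self, symbol: str) -> SampledSignal:
        """Look up a member by the conventional column symbol D/V/A."""
        return {"D": self.displacement, "V": self.velocity, "A": self.acceleration}[symbol]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def resample_uniform(signal: SampledSignal, target_rate: float) -> SampledSignal:
    """Linearly interpolate a signal onto a uniform grid at ``target_rate``.

    The output grid is anchored at the first timestamp: t0 + k/target_rate
    for k = 0..floor((tN-t0)*target_rate), so it covers [t0, tN] without
    extrapolating. Axis and quantity are preserved.

    A warning is emitted when ``target_rate`` exceeds twice the effective
    input rate (upsampling past Nyquist cannot add information).
    """
    if target_rate <= 0:
        raise ConfigError(f"target_rate must be positive, got {target_rate}")
    if signal.n < 2:
        raise DataIntegrityError("resampling needs at least 2 samples")
    if target_rate > 2.0 * signal.rate:
        warnings.warn(
            f"target rate {target_rate:g} Hz exceeds twice the effective input "
            f"rate {signal.rate:.3g} Hz; interpolated samples carry no new information",
            RuntimeWarning,
            stacklevel=2,
        )
    t0, t_end = signal.timestamps[0], signal.timestamps[-1]
    n_out = int(np.floor((t_end - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / target_rate
    values = np.interp(grid, signal.timestamps, signal.values)
    return SampledSignal(grid, values, axis=signal.axis, quantity=signal.quantity,
                         nominal_rate=target_rate)


def _settling_padlen(fs: float, spec: FilterSpec, n: int) -> int:
    # ~3 time constants of the cutoff; capped so sosfiltfilt accepts it
    return int(min(n - 2, max(24, round(3.0 * fs / spec.cutoff))))


def butterworth(signal: SampledSignal, spec: FilterSpec, zero_phase: bool = True) -> SampledSignal:
    """Apply a Butterworth filter on a uniformly sampled signal.

    With ``zero_phase`` (the default) the filter runs forward and backward
    (``sosfiltfilt``): no phase lag, squared magnitude response. Edge
    transients are suppressed by reflect-padding roughly one settling
    length of the cutoff frequency. Single-pass mode (``zero_phase=False``)
    has the textbook magnitude response and a causal phase lag.
    """
    if signal.n < 2:
        raise DataIntegrityError("filtering needs at least 2 samples")
    if not signal.is_uniform():
        raise NonUniformSamplingError(
            "butterworth requires uniform sampling; resample first")
    fs = (signal.n - 1) / signal.duration
    if spec.cutoff >= fs / 2:
        raise ConfigError(
            f"cutoff {spec.cutoff:g} Hz is not below the Nyquist rate {fs / 2:g} Hz")
    sos = sps.butter(spec.order, spec.cutoff, btype=spec.kind, fs=fs, output="sos")
    if zero_phase:
        padlen = _settling_padlen(fs, spec, signal.n)
        filtered = sps.sosfiltfilt(sos, signal.values, padtype="even", padlen=padlen)
    else:
        filtered = sps.sosfilt(sos, signal.values)
    return signal.with_values(filtered)


def cumulative_integrate(signal: SampledSignal) -> SampledSignal:
    """Trapezoid-rule cumulative integral starting at 0.

    The quantity is demoted one level (acceleration -> velocity,
    velocity -> displacement); integrating displacement is rejected.
    Zero initial conditions reflect trials that begin seated and
    stationary; any residual offset is absorbed by drift correction.
    """
    if signal.quantity not in _DEMOTE:
        raise QuantityError("cannot integrate a displacement signal further")
    if signal.n < 2:
        raise DataIntegrityError("integration needs at least 2 samples")
    if not signal.is_uniform():
        raise NonUniformSamplingError("integrate requires uniform sampling; resample first")
    values = cumulative_trapezoid(signal.values, signal.timestamps, initial=0.0)
    return signal.with_values(values, quantity=_DEMOTE[signal.quantity])


def differentiate(signal: SampledSignal) -> SampledSignal:
    """Central-difference derivative (one-sided at the ends).

    The quantity is promoted one level; differentiating acceleration is
    rejected (jerk is outside the pipeline's scope).
    """
    if signal.quantity not in _PROMOTE:
        raise QuantityError("cannot differentiate an acceleration signal further")
    if signal.n < 2:
        raise DataIntegrityError("differentiation needs at least 2 samples")
    if not signal.is_uniform():
        raise NonUniformSamplingError("differentiate requires uniform sampling; resample first")
    values = np.gradient(signal.values, signal.timestamps)
    return signal.with_values(values, quantity=_PROMOTE[signal.quantity])
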