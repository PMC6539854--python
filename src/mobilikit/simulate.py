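"""Synthetic sit-to-stand and timed-up-and-go trials with sensor models.

Real recordings of these clinical tests are not publicly available, so the
pipeline is validated against a generator whose ground truth is known
exactly. Chair transfers and walking bouts are modelled as minimum-jerk
quintic transitions

    s(tau) = H * (10 tau^3 - 15 tau^4 + 6 tau^5),  tau = (t - t0) / T,

the standard smooth model of point-to-point human movement. Its peak
velocity is 1.875 H/T and peak acceleration ~5.7735 H/T^2; at the default
head excursion H = 0.30 m and rise time 0.6 s these land in the range of
peak rise velocities observed in adults (~0.9-1.2 m/s).

Two sensor channels are rendered from the analytic ground truth:

* an inertial channel — gravity-corrected acceleration at 128 Hz with
  additive white noise and a slowly varying bias b0 + b1 t, the minimal
  model producing the quadratic/cubic displacement drift that the
  high-pass and zero-displacement-update corrections exist to remove;
* a position channel — displacement at a jittered ~30 Hz clock with
  additive white noise, emulating a headset's fused head-position output.

All randomness flows from ``SimulationConfig.seed``; identical configs
produce bit-identical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .drift import ContactEvents
from .errors import ConfigError
from .features import PhaseEvents, Task
from .signal import Axis, KinematicTriplet, Quantity, SampledSignal

__all__ = ["SimulationConfig", "SimulatedTrial", "simulate_sts", "simulate_tug",
           "simulate", "render_imu", "render_position", "Task"]


# ---------------------------------------------------------------------------
# minimum-jerk primitives (quintic and its first two derivatives)
# ---------------------------------------------------------------------------

def _mj(u: np.ndarray) -> np.ndarray:
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)


def _mj_d1(u: np.ndarray) -> np.ndarray:
    return u ** 2 * (30.0 - 60.0 * u + 30.0 * u ** 2)


def _mj_d2(u: np.ndarray) -> np.ndarray:
    return u * (60.0 - 180.0 * u + 120.0 * u ** 2)


#: Peak velocity of a minimum-jerk transition of amplitude H over duration T
#: is MINJERK_PEAK_VEL * H / T.
MINJERK_PEAK_VEL = 1.875
#: Peak acceleration factor: max |a| = MINJERK_PEAK_ACC * H / T^2.
MINJERK_PEAK_ACC = 10.0 / np.sqrt(3.0)


class _Transition:
    """A minimum-jerk level change: +delta over [t0, t0+T].

    Outside the window the derivatives of the clipped quintic vanish
    identically (the quintic has zero velocity and acceleration at both
    ends), so no masking is needed.
    """

    def __init__(self, t0: float, duration: float, delta: float):
        self.t0, self.T, self.delta = t0, duration, delta

    def d(self, t: np.ndarray) -> np.ndarray:
        u = np.clip((t - self.t0) / self.T, 0.0, 1.0)
        return self.delta * _mj(u)

    def v(self, t: np.ndarray) -> np.ndarray:
        u = np.clip((t - self.t0) / self.T, 0.0, 1.0)
        return self.delta / self.T * _mj_d1(u)

    def a(self, t: np.ndarray) -> np.ndarray:
        u = np.clip((t - self.t0) / self.T, 0.0, 1.0)
        return self.delta / self.T ** 2 * _mj_d2(u)


class _Bounce:
    """Windowed sinusoid modelling vertical gait oscillation over one walking bout.

    The sine is multiplied by a minimum-jerk on/off envelope so the bout
    starts and ends with zero displacement, velocity and acceleration.
    """

    def __init__(self, t0: float, duration: float, amplitude: float, frequency: float):
        self.t0, self.T, self.A, self.w = t0, duration, amplitude, 2 * np.pi * frequency
        self.Te = min(0.4, duration / 4.0)

    def _env(self, t: np.ndarray):
        u1 = np.clip((t - self.t0) / self.Te, 0.0, 1.0)
        u2 = np.clip((self.t0 + self.T - t) / self.Te, 0.0, 1.0)
        E = _mj(u1) * _mj(u2)
        E1 = (_mj_d1(u1) * _mj(u2) - _mj(u1) * _mj_d1(u2)) / self.Te
        E2 = (_mj_d2(u1) * _mj(u2) - 2.0 * _mj_d1(u1) * _mj_d1(u2)
              + _mj(u1) * _mj_d2(u2)) / self.Te ** 2
        return E, E1, E2

    def _carrier(self, t: np.ndarray):
        ph = self.w * (t - self.t0)
        return np.sin(ph), self.w * np.cos(ph), -self.w ** 2 * np.sin(ph)

    def d(self, t):
        E, _, _ = self._env(t)
        s, _, _ = self._carrier(t)
        return self.A * E * s

    def v(self, t):
        E, E1, _ = self._env(t)
        s, s1, _ = self._carrier(t)
        return self.A * (E1 * s + E * s1)

    def a(self, t):
        E, E1, E2 = self._env(t)
        s, s1, s2 = self._carrier(t)
        return self.A * (E2 * s + 2.0 * E1 * s1 + E * s2)


class MotionProfile:
    """Sum of analytic motion components along one axis, evaluable at any t."""

    def __init__(self, components: Iterable[object], total_duration: float):
        self.components = list(components)
        self.total_duration = total_duration

    def d(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum((c.d(t) for c in self.components), np.zeros_like(t))

    def v(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum((c.v(t) for c in self.components), np.zeros_like(t))

    def a(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum((c.a(t) for c in self.components), np.zeros_like(t))

    def triplet(self, rate: float, axis: Axis = Axis.VT) -> KinematicTriplet:
        """Sample the analytic profile on a uniform grid as a kinematic triplet."""
        n = int(round(self.total_duration * rate)) + 1
        t = np.arange(n) / rate
        return KinematicTriplet(
            SampledSignal(t, self.d(t), axis=axis, quantity=Quantity.DISPLACEMENT,
                          nominal_rate=rate),
            SampledSignal(t, self.v(t), axis=axis, quantity=Quantity.VELOCITY,
                          nominal_rate=rate),
            SampledSignal(t, self.a(t), axis=axis, quantity=Quantity.ACCELERATION,
                          nominal_rate=rate),
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated trial.

    Motion defaults reproduce the clinical protocols (five sit-to-stand
    repetitions; a 3 m walk at normal pace for the timed-up-and-go), with
    a 0.30 m vertical head excursion per chair transfer. Sensor defaults
    are a 128 Hz inertial channel with 0.1 m/s^2 white noise and a
    0.05 + 0.005 t m/s^2 bias, and a ~30 Hz position channel with 5 ms
    clock jitter and 5 mm white noise.
    """

    task: Task = Task.STS
    # motion — chair transfer
    n_repetitions: int = 5
    rise_amplitude: float = 0.30     # H, vertical head excursion per rise (m)
    rise_duration: float = 0.6       # Tr (s)
    descent_duration: float = 1.0    # Td (s)
    stand_hold: float = 0.5          # pause upright between rise and descent (s)
    sit_hold: float = 0.5            # seated dwell, also the lead-in/out (s)
    # motion — walking (timed up and go)
    walk_distance: float = 3.0       # m
    walk_speed: float = 1.0          # mean outbound speed (m/s)
    step_frequency: float = 2.0      # gait-cycle rate; bounce runs at twice this (Hz)
    bounce_amplitude: float = 0.015  # vertical gait oscillation amplitude (m)
    turn_duration: float = 1.0       # s
    # sensors
    imu_rate: float = 128.0          # Hz
    position_rate: float = 30.0      # Hz (nominal; per-sample jitter applied)
    position_jitter_sd: float = 0.005   # s
    imu_noise_sd: float = 0.1        # m/s^2
    imu_bias_b0: float = 0.05        # m/s^2
    imu_bias_slope_b1: float = 0.005  # m/s^3
    position_noise_sd: float = 0.005  # m
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        positive = ("rise_amplitude", "rise_duration", "descent_duration",
                    "walk_distance", "walk_speed", "step_frequency",
                    "turn_duration", "imu_rate", "position_rate")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        nonneg = ("stand_hold", "sit_hold", "bounce_amplitude", "position_jitter_sd",
                  "imu_noise_sd", "imu_bias_b0", "position_noise_sd")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_repetitions < 1:
            raise ConfigError(f"n_repetitions must be >= 1, got {self.n_repetitions}")

    def noiseless(self) -> "SimulationConfig":
        """Copy with every noise/drift/jitter parameter set to zero."""
        return replace(self, position_jitter_sd=0.0, imu_noise_sd=0.0,
                       imu_bias_b0=0.0, imu_bias_slope_b1=0.0, position_noise_sd=0.0)


@dataclass(frozen=True)
class SimulatedTrial:
    """A ground-truth trial plus its rendered sensor channels.

    ``truth`` holds one analytic kinematic triplet per axis on the
    128 Hz (``imu_rate``) grid; ``imu`` and ``position`` are the noisy
    sensor renderings per axis. ``true_contacts``/``true_phases`` are the
    event times by construction, the oracle for every detector downstream.
    """

    truth: dict
    imu: dict
    position: dict
    true_contacts: ContactEvents
    true_phases: PhaseEvents
    config: SimulationConfig

    @property
    def truth_vt(self) -> KinematicTriplet:
        return self.truth[Axis.VT]

    @property
    def imu_vt(self) -> SampledSignal:
        return self.imu[Axis.VT]

    @property
    def position_vt(self) -> SampledSignal:
        return self.position[Axis.VT]


# ---------------------------------------------------------------------------
# trial construction
# ---------------------------------------------------------------------------


def _sts_profile(cfg: SimulationConfig):
    """Build the vertical profile and true events of a sit-to-stand trial."""
    H, Tr, Td = cfg.rise_amplitude, cfg.rise_duration, cfg.descent_duration
    comps: list[object] = []
    rise_on, rise_off, desc_on, desc_off, contacts = [], [], [], [], [0.0]
    t = cfg.sit_hold
    for _ in range(cfg.n_repetitions):
        comps.append(_Transition(t, Tr, +H))
        rise_on.append(t)
        rise_off.append(t + Tr)
        t += Tr + cfg.stand_hold
        comps.append(_Transition(t, Td, -H))
        desc_on.append(t)
        desc_off.append(t + Td)
        t += Td
        contacts.append(t)
        t += cfg.sit_hold
    profile = MotionProfile(comps, total_duration=t)
    events = PhaseEvents(rise_on, rise_off, desc_on, desc_off)
    return profile, ContactEvents(np.asarray(contacts)), events


def _tug_profile(cfg: SimulationConfig):
    """Vertical and anterior-posterior profiles and true events of a TUG trial."""
    H, Tr, Td = cfg.rise_amplitude, cfg.rise_duration, cfg.descent_duration
    T_walk = cfg.walk_distance / cfg.walk_speed
    f_bounce = 2.0 * cfg.step_frequency  # one vertical oscillation per step
    vt: list[object] = []
    ap: list[object] = []
    t = cfg.sit_hold
    vt.append(_Transition(t, Tr, +H))
    rise_on, rise_off = t, t + Tr
    t += Tr
    ap.append(_Transition(t, T_walk, +cfg.walk_distance))
    if cfg.bounce_amplitude > 0:
        vt.append(_Bounce(t, T_walk, cfg.bounce_amplitude, f_bounce))
    t += T_walk + cfg.turn_duration  # AP plateau during the turn
    ap.append(_Transition(t, T_walk, -cfg.walk_distance))
    if cfg.bounce_amplitude > 0:
        vt.append(_Bounce(t, T_walk, cfg.bounce_amplitude, f_bounce))
    t += T_walk
    vt.append(_Transition(t, Td, -H))
    desc_on, desc_off = t, t + Td
    t += Td
    contacts = ContactEvents(np.asarray([0.0, t]))
    t += cfg.sit_hold
    total = t
    events = PhaseEvents([rise_on], [rise_off], [desc_on], [desc_off])
    return (MotionProfile(vt, total), MotionProfile(ap, total)), contacts, events


# ---------------------------------------------------------------------------
# sensor rendering
# ---------------------------------------------------------------------------

_STREAM_IMU = 101
_STREAM_POSITION = 202


def render_imu(truth: KinematicTriplet, config: SimulationConfig,
               stream: int = 0) -> SampledSignal:
    """Render an inertial acceleration channel from ground truth.

    The truth acceleration is sampled on a uniform grid at
    ``config.imu_rate`` (linear interpolation when the truth grid
    differs), then corrupted with additive white Gaussian noise of sd
    ``imu_noise_sd`` and an additive bias b0 + b1 t. Gravity is assumed
    already removed upstream, matching a gravity-corrected input.

    ``stream`` decorrelates the noise of multiple channels rendered from
    one seed; calls with identical arguments are bit-identical.
    """
    rng = np.random.default_rng([config.seed, _STREAM_IMU, stream])
    src = truth.acceleration
    t0, t_end = src.timestamps[0], src.timestamps[-1]
    n = int(np.floor((t_end - t0) * config.imu_rate + 1e-9)) + 1
    t = t0 + np.arange(n) / config.imu_rate
    a = np.interp(t, src.timestamps, src.values)
    a = a + config.imu_bias_b0 + config.imu_bias_slope_b1 * (t - t0)
    if config.imu_noise_sd > 0:
        a = a + rng.normal(0.0, config.imu_noise_sd, size=n)
    return SampledSignal(t, a, axis=src.axis, quantity=Quantity.ACCELERATION,
                         nominal_rate=config.imu_rate)


def render_position(truth: KinematicTriplet, config: SimulationConfig,
                    stream: int = 0) -> SampledSignal:
    """Render a jittered ~30 Hz position channel from ground truth.

    Timestamps are the nominal grid plus Gaussian clock jitter (sd
    ``position_jitter_sd``, clipped to 40 % of the sample period so the
    clock stays strictly increasing); values are the truth displacement
    at those instants plus white noise of sd ``position_noise_sd``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_POSITION, stream])
    src = truth.displacement
    t0, t_end = src.timestamps[0], src.timestamps[-1]
    period = 1.0 / config.position_rate
    n = int(np.floor((t_end - t0) / period + 1e-9)) + 1
    t = t0 + np.arange(n) * period
    if config.position_jitter_sd > 0:
        jitter = rng.normal(0.0, config.position_jitter_sd, size=n)
        np.clip(jitter, -0.4 * period, 0.4 * period, out=jitter)
        t = t + jitter
        t[0] = max(t[0], t0)
        t[-1] = min(t[-1], t_end)
    d = np.interp(t, src.timestamps, src.values)
    if config.position_noise_sd > 0:
        d = d + rng.normal(0.0, config.position_noise_sd, size=n)
    return SampledSignal(t, d, axis=src.axis, quantity=Quantity.DISPLACEMENT,
                         nominal_rate=config.position_rate)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def simulate_sts(config: SimulationConfig) -> SimulatedTrial:
    """Simulate a five-time (or n-time) sit-to-stand trial.

    Vertical displacement is a concatenation of minimum-jerk rise /
    stand-hold / minimum-jerk descent / sit-hold cycles, returning exactly
    to zero at every chair contact. The anterior-posterior axis is static.
    """
    if config.task is not Task.STS:
        raise ConfigError(f"simulate_sts requires task=STS, got {config.task.value}")
    profile, contacts, phases = _sts_profile(config)
    truth_vt = profile.triplet(config.imu_rate, axis=Axis.VT)
    zero = MotionProfile([], profile.total_duration)
    truth_ap = zero.triplet(config.imu_rate, axis=Axis.AP)
    return SimulatedTrial(
        truth={Axis.VT: truth_vt, Axis.AP: truth_ap},
        imu={Axis.VT: render_imu(truth_vt, config, stream=0),
             Axis.AP: render_imu(truth_ap, config, stream=1)},
        position={Axis.VT: render_position(truth_vt, config, stream=0),
                  Axis.AP: render_position(truth_ap, config, stream=1)},
        true_contacts=contacts,
        true_phases=phases,
        config=config,
    )


def simulate_tug(config: SimulationConfig) -> SimulatedTrial:
    """Simulate a timed-up-and-go trial.

    Rise, outbound 3 m walk (anterior-posterior minimum-jerk reach with
    vertical gait bounce), turn plateau, return walk, descent. The
    anterior-posterior displacement peaks at ``walk_distance`` and
    returns to zero at the end.
    """
    if config.task is not Task.TUG:
        raise ConfigError(f"simulate_tug requires task=TUG, got {config.task.value}")
    (profile_vt, profile_ap), contacts, phases = _tug_profile(config)
    truth_vt = profile_vt.triplet(config.imu_rate, axis=Axis.VT)
    truth_ap = profile_ap.triplet(config.imu_rate, axis=Axis.AP)
    return SimulatedTrial(
        truth={Axis.VT: truth_vt, Axis.AP: truth_ap},
        imu={Axis.VT: render_imu(truth_vt, config, stream=0),
             Axis.AP: render_imu(truth_ap, config, stream=1)},
        position={Axis.VT: render_position(truth_vt, config, stream=0),
                  Axis.AP: render_position(truth_ap, config, stream=1)},
        true_contacts=contacts,
        true_phases=phases,
        config=config,
    )


def simulate(config: SimulationConfig) -> SimulatedTrial:
    """Dispatch to :func:`simulate_sts` or :func:`simulate_tug` by task."""
    return simulate_sts(config) if config.task is Task.STS else simulate_tug(config)
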