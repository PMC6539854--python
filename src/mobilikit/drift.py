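"""Acceleration-to-displacement conversion with drift correction.

Double integration of accelerometer data is unbounded in error: a constant
bias b produces a displacement error b·t²/2 (3.6 m after 12 s for a mere
0.05 m/s² bias), and white noise produces a random walk growing as t^{3/2}.
Two corrections are provided, individually or in sequence:

* a zero-phase 4th-order 0.1 Hz Butterworth high-pass on the integrated
  displacement, which removes the slow drift component; and
* the zero-displacement update (ZDU): sit-to-stand trials return the head
  to the same height at every chair contact, so the displacement measured
  at those instants *is* the accumulated drift. A continuous
  piecewise-linear curve through the contact-instant values is subtracted,
  pinning the corrected displacement to exactly zero at every contact.

With five sit-to-stand repetitions ZDU re-anchors the integral every
couple of seconds; in a timed-up-and-go trial only the start and end are
seated, so the single-span correction leaves a larger mid-trial residual —
the mechanism behind the poorer displacement agreement seen on that task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataIntegrityError, NoContactsError, QuantityError
from .signal import (
    HIGHPASS_DRIFT,
    LOWPASS_SMOOTHING,
    Axis,
    FilterSpec,
    KinematicTriplet,
    Quantity,
    SampledSignal,
    butterworth,
    cumulative_integrate,
    differentiate,
)

__all__ = [
    "ContactEvents",
    "double_integrate_vt",
    "highpass_drift_correct",
    "polynomial_detrend",
    "detect_chair_contacts",
    "zero_displacement_update",
    "build_kinematics",
]


@dataclass(frozen=True)
class ContactEvents:
    """Chair-contact instants used to anchor the zero-displacement update.

    ``includes_start`` records whether the first entry is the seated trial
    start rather than a detected post-descent contact; an n-repetition
    sit-to-stand trial then carries n+1 contacts.
    """

    contact_times: np.ndarray
    includes_start: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.contact_times, dtype=float)
        object.__setattr__(self, "contact_times", t)
        if t.ndim != 1 or t.size == 0:
            raise DataIntegrityError("contact_times must be a non-empty 1-D array")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataIntegrityError("contact_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.contact_times.size


def double_integrate_vt(accel: SampledSignal) -> SampledSignal:
    """Vertical displacement from vertical acceleration, no drift correction.

    Two trapezoid cumulative integrations with zero initial velocity and
    displacement (trials start seated and stationary). The output is the
    raw, drifting displacement; pass it to :func:`highpass_drift_correct`
    and/or :func:`zero_displacement_update`.
    """
    if accel.quantity is not Quantity.ACCELERATION:
        raise QuantityError(f"expected acceleration, got {accel.quantity.value}")
    if accel.axis is not Axis.VT:
        raise QuantityError(f"vertical integration expects the VT axis, got {accel.axis.value}")
    return cumulative_integrate(cumulative_integrate(accel))


def highpass_drift_correct(displacement: SampledSignal,
                           spec: FilterSpec = HIGHPASS_DRIFT) -> SampledSignal:
    """Remove integration drift with a zero-phase 0.1 Hz 4th-order high-pass.

    Warns when the record is shorter than ~10 s: a 0.1 Hz filter needs a
    few of its own time constants of data before the correction is
    trustworthy.
    """
    if displacement.duration < 10.0:
        warnings.warn(
            f"record of {displacement.duration:.1f} s is short for a "
            f"{spec.cutoff:g} Hz high-pass; drift correction may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return butterworth(displacement, spec, zero_phase=True)


def polynomial_detrend(displacement: SampledSignal, degree: int = 3) -> SampledSignal:
    """Subtract a least-squares polynomial trend of the given degree.

    A constant-plus-linear accelerometer bias integrates to a quadratic-
    plus-cubic displacement drift, so a cubic fit captures the bulk of
    the drift on records far too short for the 0.1 Hz high-pass to act.
    The fit also absorbs part of the genuine movement, so the result is
    only suitable as a *detection* aid (locating chair contacts), not as
    a corrected displacement — use :func:`zero_displacement_update` or
    :func:`highpass_drift_correct` for that.
    """
    fit = np.polynomial.Polynomial.fit(displacement.timestamps, displacement.values, degree)
    return displacement.with_values(displacement.values - fit(displacement.timestamps))


def detect_chair_contacts(displacement: SampledSignal,
                          min_separation: float = 1.0,
                          depth_frac: float = 0.25) -> ContactEvents:
    """Locate chair-contact instants in an STS-like vertical displacement.

    Candidate regions are the contiguous stretches where displacement sits
    within ``depth_frac`` of the signal's range above its global minimum
    (the seated level); regions closer than ``min_separation`` are merged.
    Within each region the contact is the first instant at which the
    vertical velocity has died away (below 5 % of its peak magnitude) —
    i.e. the moment the descent ends on the chair, rather than an
    arbitrary point of the flat seated dwell. A region starting at the
    first sample marks the seated trial start (``includes_start``).

    Raises
    ------
    NoContactsError
        If the signal has no vertical excursion (constant input) or no
        below-threshold region exists; the caller should fall back to
        high-pass drift correction.
    """
    t = displacement.timestamps
    d = displacement.values
    span = float(d.max() - d.min())
    if span < 1e-9:
        raise NoContactsError("signal has no vertical excursion; no contacts to detect")
    threshold = d.min() + depth_frac * span
    mask = d <= threshold
    if not mask.any():
        raise NoContactsError("no samples within the seated band; no contacts to detect")

    # contiguous below-threshold runs
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.r_[0 if mask[0] else [], edges[~mask[edges]] + 1].astype(int)
    ends = np.r_[edges[mask[edges]], (d.size - 1) if mask[-1] else []].astype(int)

    # merge runs separated by less than min_separation
    regions: list[list[int]] = []
    for s, e in zip(starts, ends):
        if regions and t[s] - t[regions[-1][1]] < min_separation:
            regions[-1][1] = e
        else:
            regions.append([s, e])

    v = np.gradient(d, t)
    v_eps = 0.05 * float(np.max(np.abs(v)))
    times = []
    for s, e in regions:
        quiet = np.flatnonzero(np.abs(v[s:e + 1]) <= v_eps)
        idx = s + quiet[0] if quiet.size else s + int(np.argmin(d[s:e + 1]))
        times.append(t[idx])
    times_arr = np.asarray(times)
    if times_arr.size > 1:  # enforce separation between picked instants
        keep = np.r_[True, np.diff(times_arr) >= min_separation]
        times_arr = times_arr[keep]
    return ContactEvents(times_arr, includes_start=bool(regions[0][0] == 0))


def zero_displacement_update(displacement: SampledSignal,
                             contacts: ContactEvents) -> SampledSignal:
    """Subtract a piecewise-linear drift estimate anchored at chair contacts.

    The displacement values at the contact instants (snapped to the sample
    grid) define a continuous piecewise-linear drift curve; before the
    first and after the last contact the nearest segment's line is
    extrapolated. Subtracting it makes the corrected displacement exactly
    zero at every contact sample. A single contact degenerates to removing
    one constant offset — the single-span correction used for
    timed-up-and-go trials.

    Linearity makes the correction exact for constant-bias-induced error
    between adjacent contacts up to the chord deviation of the quadratic,
    b·Δ²/8 for contact spacing Δ. A continuous (rather than stepwise)
    correction avoids injecting velocity spikes on later differentiation.
    """
    t = displacement.timestamps
    d = displacement.values
    tc = np.asarray(contacts.contact_times, dtype=float)
    if tc.min() < t[0] - 1e-9 or tc.max() > t[-1] + 1e-9:
        raise DataIntegrityError("contact times fall outside the signal's time span")
    idx = np.clip(np.rint(np.interp(tc, t, np.arange(t.size))).astype(int), 0, t.size - 1)
    idx = np.unique(idx)
    anchors_t = t[idx]
    anchors_d = d[idx]
    if anchors_t.size == 1:
        drift = np.full_like(d, anchors_d[0])
    else:
        drift = np.interp(t, anchors_t, anchors_d)
        # linear extrapolation with the edge segments' slopes
        s0 = (anchors_d[1] - anchors_d[0]) / (anchors_t[1] - anchors_t[0])
        s1 = (anchors_d[-1] - anchors_d[-2]) / (anchors_t[-1] - anchors_t[-2])
        before = t < anchors_t[0]
        after = t > anchors_t[-1]
        drift[before] = anchors_d[0] + s0 * (t[before] - anchors_t[0])
        drift[after] = anchors_d[-1] + s1 * (t[after] - anchors_t[-1])
    return displacement.with_values(d - drift)


def build_kinematics(displacement: SampledSignal,
                     lowpass: FilterSpec | None = LOWPASS_SMOOTHING) -> KinematicTriplet:
    """Derive the displacement/velocity/acceleration triplet.

    Velocity and acceleration are obtained by successive central-difference
    differentiation and, by default, smoothed with the 5 Hz low-pass
    (differentiation amplifies high-frequency noise). The displacement is
    passed through untouched so that zero-displacement-update anchors stay
    exactly zero.
    """
    velocity = differentiate(displacement)
    acceleration = differentiate(velocity)
    if lowpass is not None:
        fs = (displacement.n - 1) / displacement.duration
        if lowpass.cutoff < fs / 2:
            velocity = butterworth(velocity, lowpass)
            acceleration = butterworth(acceleration, lowpass)
    return KinematicTriplet(displacement, velocity, acceleration)
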