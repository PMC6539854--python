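"""End-to-end processing: channels in, agreement report and features out.

The stage order mirrors standard practice for this kind of validation
study: resample both channels to a common 30 Hz grid, low-pass at 5 Hz,
double-integrate the inertial channel to displacement, correct the
integration drift (high-pass filter and/or zero-displacement update),
derive the displacement/velocity/acceleration triplets, time-align the
devices by cross-correlation on displacement, then compute per-quantity
agreement statistics and the task's mobility features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .agreement import AgreementResult, align_pair, estimate_lag, nrmse, xcor_zero_lag
from .drift import (
    ContactEvents,
    build_kinematics,
    detect_chair_contacts,
    double_integrate_vt,
    highpass_drift_correct,
    polynomial_detrend,
    zero_displacement_update,
)
from .errors import ConfigError, MobilikitError, NoContactsError
from .features import FeatureSet, Task, extract_features
from .signal import (
    HIGHPASS_DRIFT,
    LOWPASS_SMOOTHING,
    FilterSpec,
    KinematicTriplet,
    SampledSignal,
    butterworth,
    resample_uniform,
)

__all__ = ["PipelineConfig", "DRIFT_STRATEGIES", "process_position", "process_imu",
           "run_pipeline", "run_trial"]

log = logging.getLogger("mobilikit")

#: Recognised drift-correction strategies for the inertial channel.
DRIFT_STRATEGIES = ("none", "hpf", "zdu", "hpf+zdu")


@dataclass(frozen=True)
class PipelineConfig:
    """Processing parameters shared by every stage.

    ``drift`` selects the inertial-channel drift correction. ``zdu`` (the
    default) anchors the displacement at every detected chair contact —
    per-cycle in a sit-to-stand trial; with ``zdu_single_span`` (the
    default for timed-up-and-go, where only start and end are seated)
    only the first and last contacts are used. ``hpf`` is the 0.1 Hz
    high-pass alternative and ``hpf+zdu`` runs both in sequence.
    """

    analysis_rate: float = 30.0
    lowpass: FilterSpec = LOWPASS_SMOOTHING
    highpass: FilterSpec = HIGHPASS_DRIFT
    drift: str = "zdu"
    zdu_single_span: bool | None = None   # None -> True for TUG, False for STS
    max_lag: float = 2.0
    contact_min_separation: float = 1.0
    contact_depth_frac: float = 0.25
    phase_threshold_frac: float = 0.1
    min_phase: float = 0.1

    def __post_init__(self) -> None:
        if self.drift not in DRIFT_STRATEGIES:
            raise ConfigError(f"drift must be one of {DRIFT_STRATEGIES}, got {self.drift!r}")
        if self.analysis_rate <= 0 or self.max_lag <= 0:
            raise ConfigError("analysis_rate and max_lag must be positive")


def _single_span(cfg: PipelineConfig, task: Task) -> bool:
    return task is Task.TUG if cfg.zdu_single_span is None else cfg.zdu_single_span


def process_position(position: SampledSignal,
                     cfg: PipelineConfig = PipelineConfig()) -> KinematicTriplet:
    """Headset-position path: resample to 30 Hz, 5 Hz low-pass, differentiate."""
    sig = resample_uniform(position, cfg.analysis_rate)
    sig = butterworth(sig, cfg.lowpass)
    log.debug("position path: resampled to %g Hz, low-passed at %g Hz, %d samples",
              cfg.analysis_rate, cfg.lowpass.cutoff, sig.n)
    return build_kinematics(sig, lowpass=cfg.lowpass)


def process_imu(accel: SampledSignal, task: Task | str,
                cfg: PipelineConfig = PipelineConfig(),
                contacts: ContactEvents | None = None
                ) -> tuple[KinematicTriplet, ContactEvents | None]:
    """Inertial path: resample, low-pass, double-integrate, drift-correct.

    For the zero-displacement update, chair contacts are detected on a
    cubic-detrended copy of the displacement (the raw integral drifts by
    metres, which would defeat any amplitude-based detector, and a
    0.1 Hz high-pass cannot settle on a ~10 s record); the update itself
    is applied to the signal being corrected, so its anchors are exact
    zeros. Explicit ``contacts`` override detection. Falls back to the
    high-pass correction when no contacts can be found.
    """
    task = Task(task)
    sig = resample_uniform(accel, cfg.analysis_rate)
    sig = butterworth(sig, cfg.lowpass)
    disp = double_integrate_vt(sig)
    used_contacts: ContactEvents | None = None
    if cfg.drift == "none":
        corrected = disp
    elif cfg.drift == "hpf":
        corrected = highpass_drift_correct(disp, cfg.highpass)
    else:  # zdu | hpf+zdu
        if contacts is None:
            try:
                contacts = detect_chair_contacts(
                    polynomial_detrend(disp),
                    min_separation=cfg.contact_min_separation,
                    depth_frac=cfg.contact_depth_frac)
            except NoContactsError:
                log.warning("no chair contacts found; falling back to high-pass correction")
                contacts = None
        if contacts is None:
            corrected = highpass_drift_correct(disp, cfg.highpass)
        else:
            if _single_span(cfg, task) and contacts.n > 2:
                contacts = ContactEvents(
                    contacts.contact_times[[0, -1]],
                    includes_start=contacts.includes_start)
            target = (highpass_drift_correct(disp, cfg.highpass)
                      if cfg.drift == "hpf+zdu" else disp)
            corrected = zero_displacement_update(target, contacts)
            used_contacts = contacts
    log.debug("imu path: drift=%s, %s contacts", cfg.drift,
              "no" if used_contacts is None else used_contacts.n)
    return build_kinematics(corrected, lowpass=cfg.lowpass), used_contacts


def run_pipeline(position: SampledSignal, imu: SampledSignal, task: Task | str,
                 cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Full two-device comparison for one trial.

    Returns a JSON-serializable report with exactly the keys ``lag_s``,
    ``nrmse_pct`` (per quantity A/V/D), ``xcor`` (same) and ``features``.
    The lag is estimated once, on displacement, and applied to all three
    quantities; the inertial-derived signals serve as the NRMSE
    reference. Lag estimation uses cubic-detrended copies so that any
    residual integration drift (which dominates the raw correlation when
    the zero-displacement update could only anchor the endpoints, as in
    timed-up-and-go) cannot drag the alignment; the agreement statistics
    are still computed on the actual signals. Features are computed from
    the position path (the device under validation).
    """
    task = Task(task)
    pos_kin = process_position(position, cfg)
    imu_kin, _ = process_imu(imu, task, cfg)
    lag = estimate_lag(polynomial_detrend(imu_kin.displacement),
                       polynomial_detrend(pos_kin.displacement), max_lag=cfg.max_lag)
    report: dict = {"lag_s": lag, "nrmse_pct": {}, "xcor": {}}
    for symbol in ("A", "V", "D"):
        ref, test = align_pair(imu_kin.by_symbol(symbol), pos_kin.by_symbol(symbol), lag)
        report["nrmse_pct"][symbol] = nrmse(ref, test)
        report["xcor"][symbol] = xcor_zero_lag(ref, test)
    features = extract_features(pos_kin, task, threshold_frac=cfg.phase_threshold_frac,
                                min_phase=cfg.min_phase)
    report["features"] = features.as_dict()
    log.info("trial processed: task=%s lag=%.3f s NRMSE(D)=%.2f%% Xcor(D)=%.3f",
             task.value, lag, report["nrmse_pct"]["D"], report["xcor"]["D"])
    return report


def run_trial(trial, cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Convenience wrapper: run the pipeline on a simulated trial's VT channels."""
    return run_pipeline(trial.position_vt, trial.imu_vt, trial.config.task, cfg)
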