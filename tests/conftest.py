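import numpy as np
import pytest

import mobilikit as mk


@pytest.fixture(scope="session")
def sts_noiseless() -> mk.SimulatedTrial:
    """Five-repetition sit-to-stand with all sensor noise and drift off."""
    return mk.simulate_sts(mk.SimulationConfig(seed=7).noiseless())


@pytest.fixture(scope="session")
def sts_noisy() -> mk.SimulatedTrial:
    """Five-repetition sit-to-stand at the default noise/drift levels."""
    return mk.simulate_sts(mk.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def tug_noiseless() -> mk.SimulatedTrial:
    return mk.simulate_tug(mk.SimulationConfig(task="TUG", seed=7).noiseless())


@pytest.fixture(scope="session")
def tug_noisy() -> mk.SimulatedTrial:
    return mk.simulate_tug(mk.SimulationConfig(task="TUG", seed=7))


def sine(freq: float, fs: float, duration: float, amplitude: float = 1.0,
         quantity=mk.Quantity.DISPLACEMENT) -> mk.SampledSignal:
    t = np.arange(int(duration * fs) + 1) / fs
    return mk.SampledSignal(t, amplitude * np.sin(2 * np.pi * freq * t),
                            quantity=quantity, nominal_rate=fs)


def steady_amplitude(signal: mk.SampledSignal, freq: float, tail: float,
                     guard: float = 0.0) -> float:
    """Amplitude of a sinusoid at a known frequency over the final ``tail`` seconds.

    Least-squares quadrature fit, immune to phase; used to measure filter
    gain after start-up transients have decayed. ``guard`` excludes the
    very end of the record (needed for zero-phase filters, whose
    transients sit at both edges).
    """
    t = signal.timestamps
    keep = (t >= t[-1] - guard - tail) & (t <= t[-1] - guard)
    tt, xx = t[keep], signal.values[keep]
    design = np.column_stack([np.sin(2 * np.pi * freq * tt),
                              np.cos(2 * np.pi * freq * tt),
                              np.ones_like(tt)])
    coef, *_ = np.linalg.lstsq(design, xx, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def truth_on(trial: mk.SimulatedTrial, timestamps: np.ndarray,
             member: str = "displacement") -> np.ndarray:
    """Ground-truth vertical kinematics interpolated onto an arbitrary grid."""
    src = getattr(trial.truth_vt, member)
    return np.interp(timestamps, src.timestamps, src.values)
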