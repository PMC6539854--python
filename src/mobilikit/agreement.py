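"""Device agreement statistics: time alignment, NRMSE, Xcor, Bland-Altman.

Two devices recording the same movement are compared by (1) estimating
their relative time lag with a normalized cross-correlation scan,
(2) trimming both to the common support, and (3) quantifying agreement:

* NRMSE — root-mean-square error divided by the reference signal's
  amplitude range, in percent; lower is better;
* Xcor — the Pearson correlation coefficient of the aligned samples at
  zero lag; ~1 indicates near-identical shape;
* Bland-Altman limits of agreement — mean paired difference ± 1.96 times
  its standard deviation, the interval expected to contain 95 % of the
  disagreements between two measurement methods;
* per-condition mean with a Student-t 95 % confidence interval, and a
  two-tailed two-sample t-test for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import DataIntegrityError
from .signal import SampledSignal

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "SummaryCI",
    "estimate_lag",
    "align_pair",
    "nrmse",
    "xcor_zero_lag",
    "summarize_ci",
    "bland_altman",
    "two_sample_ttest",
    "compare_signals",
]


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between one pair of aligned signals."""

    nrmse_pct: float
    xcor: float
    lag_s: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.nrmse_pct < 0:
            raise DataIntegrityError("nrmse_pct must be non-negative")
        if abs(self.xcor) > 1 + 1e-12:
            raise DataIntegrityError("correlation magnitude cannot exceed 1")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Limits-of-agreement analysis of paired measurements.

    ``means``/``diffs`` carry the per-pair points for the conventional
    Bland-Altman scatter plot.
    """

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise DataIntegrityError("limits of agreement must bracket the mean difference")


@dataclass(frozen=True)
class SummaryCI:
    """Mean of a metric across trials with its 95 % confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise DataIntegrityError("confidence interval must bracket the mean")


def _common_rate(x: SampledSignal, y: SampledSignal) -> float:
    fx = (x.n - 1) / x.duration
    fy = (y.n - 1) / y.duration
    if abs(fx - fy) > 1e-6 * fx:
        raise DataIntegrityError(
            f"sampling rates differ ({fx:.4g} vs {fy:.4g} Hz); resample first")
    return fx


def estimate_lag(x: SampledSignal, y: SampledSignal, max_lag: float = 2.0) -> float:
    """Time lag of ``y`` relative to ``x`` by normalized cross-correlation.

    Both signals are demeaned; the cross-correlation is evaluated at every
    integer-sample shift within ``±max_lag`` and normalized by the product
    of the overlapping segments' norms, making the estimate invariant to
    amplitude scaling. The returned lag is positive when ``y`` trails
    ``x`` (y(t) ≈ x(t − lag)) and is resolved to the sample grid; ties
    prefer the smallest magnitude.
    """
    fs = _common_rate(x, y)
    max_shift = int(round(max_lag * fs))
    if min(x.n, y.n) < 2 * max_shift:
        raise DataIntegrityError(
            f"signals too short ({min(x.n, y.n)} samples) for a ±{max_lag:g} s lag search")
    xd = x.values - x.values.mean()
    yd = y.values - y.values.mean()
    c = sps.correlate(yd, xd, mode="full")
    lags = sps.correlation_lags(yd.size, xd.size, mode="full")
    keep = np.abs(lags) <= max_shift
    c, lags = c[keep], lags[keep]

    # per-shift norms of the overlapping segments, via cumulative sums
    cx = np.concatenate([[0.0], np.cumsum(xd ** 2)])
    cy = np.concatenate([[0.0], np.cumsum(yd ** 2)])
    norms = np.empty_like(c)
    for i, s in enumerate(lags):
        if s >= 0:
            nov = min(x.n, y.n - s)  # x[0:nov] vs y[s:s+nov]
            ex = cx[nov] - cx[0]
            ey = cy[s + nov] - cy[s]
        else:
            nov = min(y.n, x.n + s)  # x[-s:-s+nov] vs y[0:nov]
            ex = cx[-s + nov] - cx[-s]
            ey = cy[nov] - cy[0]
        norms[i] = np.sqrt(ex * ey)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(norms > 0, c / norms, -np.inf)
    best = np.max(score)
    candidates = lags[score >= best - 1e-12]
    shift = candidates[np.argmin(np.abs(candidates))]
    return float(shift) / fs


def align_pair(x: SampledSignal, y: SampledSignal,
               lag: float) -> tuple[SampledSignal, SampledSignal]:
    """Shift ``y`` by ``lag`` and trim both signals to their common support.

    The returned signals share ``x``'s (trimmed) time base and have equal
    length: with a positive integer-sample shift k, sample ``x[i]`` is
    paired with ``y[i+k]``.
    """
    fs = _common_rate(x, y)
    k = int(round(lag * fs))
    n = min(x.n, y.n)
    if k >= 0:
        xv, yv = x.values[: n - k], y.values[k:n]
        tt = x.timestamps[: n - k]
    else:
        xv, yv = x.values[-k:n], y.values[: n + k]
        tt = x.timestamps[-k:n]
    if xv.size == 0:
        raise DataIntegrityError(f"lag of {lag:g} s leaves no overlapping samples")
    xa = SampledSignal(tt, xv, axis=x.axis, quantity=x.quantity, nominal_rate=x.nominal_rate)
    ya = SampledSignal(tt, yv, axis=y.axis, quantity=y.quantity, nominal_rate=y.nominal_rate)
    return xa, ya


def nrmse(reference: SampledSignal, test: SampledSignal) -> float:
    """Normalized RMSE in percent: 100 · RMSE / (max(ref) − min(ref)).

    Normalizing by the reference amplitude range expresses the error as a
    fraction of the movement's size, comparable across trials and
    quantities.
    """
    if reference.n != test.n:
        raise DataIntegrityError(f"length mismatch: {reference.n} vs {test.n}")
    if reference.n < 2:
        raise DataIntegrityError("nrmse needs at least 2 samples")
    span = float(reference.values.max() - reference.values.min())
    if span <= 0:
        raise DataIntegrityError("reference amplitude range is zero; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((test.values - reference.values) ** 2)))
    return 100.0 * rmse / span


def xcor_zero_lag(x: SampledSignal, y: SampledSignal) -> float:
    """Pearson correlation coefficient of the aligned sample pairs."""
    if x.n != y.n:
        raise DataIntegrityError(f"length mismatch: {x.n} vs {y.n}")
    if x.n < 3:
        raise DataIntegrityError("correlation needs at least 3 samples")
    if np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
        raise DataIntegrityError("correlation undefined for a constant signal")
    return float(np.corrcoef(x.values, y.values)[0, 1])


def summarize_ci(values) -> SummaryCI:
    """Mean and Student-t 95 % confidence interval of a list of metric values.

    The t multiplier (not 1.96) is used because per-condition sample sizes
    are small — a couple dozen trials, not asymptotic.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DataIntegrityError("summarize_ci needs at least 2 values")
    mean = float(v.mean())
    sem = float(v.std(ddof=1)) / np.sqrt(v.size)
    half = float(stats.t.ppf(0.975, v.size - 1)) * sem
    return SummaryCI(mean=mean, ci_low=mean - half, ci_high=mean + half, n=int(v.size))


def bland_altman(pairs) -> BlandAltmanResult:
    """Limits of agreement between two measurement methods.

    ``pairs`` is a sequence of (method_a, method_b) measurements of the
    same quantity. Differences are a − b; the limits of agreement are
    mean ± 1.96 × sd (sample standard deviation, n − 1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DataIntegrityError("bland_altman needs at least 2 (a, b) pairs")
    a, b = arr[:, 0], arr[:, 1]
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n_pairs=int(arr.shape[0]),
        means=(a + b) / 2.0,
        diffs=d,
    )


def two_sample_ttest(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t-test between independent groups.

    Defaults to the pooled-variance Student form; ``welch=True`` drops the
    equal-variance assumption. When both groups are degenerate (zero
    variance) the test returns t = 0, p = 1 for equal means and
    t = ±inf, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataIntegrityError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_signals(reference: SampledSignal, test: SampledSignal,
                    max_lag: float = 2.0) -> AgreementResult:
    """Full pairwise comparison: estimate lag, align, compute NRMSE and Xcor."""
    lag = estimate_lag(reference, test, max_lag=max_lag)
    ref_a, test_a = align_pair(reference, test, lag)
    return AgreementResult(
        nrmse_pct=nrmse(ref_a, test_a),
        xcor=xcor_zero_lag(ref_a, test_a),
        lag_s=lag,
        n_samples=ref_a.n,
    )
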