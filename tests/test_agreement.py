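"""Tests for agreement statistics against independent naive-formula oracles.

Every statistic is checked against a plain-Python evaluation of its
defining formula on fixed small vectors, independent of the vectorized
implementation paths.
"""

import math

import numpy as np
import pytest

import mobilikit as mk
from mobilikit.errors import DataIntegrityError


def sig(values, fs=30.0, quantity=mk.Quantity.DISPLACEMENT):
    values = np.asarray(values, dtype=float)
    return mk.SampledSignal(np.arange(values.size) / fs, values, quantity=quantity)


# fixed 20-sample vectors for the formula-oracle checks
RNG = np.random.default_rng(2026)
VEC_A = RNG.normal(0.0, 1.0, 20)
VEC_B = VEC_A + RNG.normal(0.0, 0.3, 20)


# -- naive oracles -----------------------------------------------------------

def naive_nrmse(ref, test):
    n = len(ref)
    rmse = math.sqrt(sum((test[i] - ref[i]) ** 2 for i in range(n)) / n)
    return 100.0 * rmse / (max(ref) - min(ref))


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((v - mx) ** 2 for v in x) * sum((v - my) ** 2 for v in y))
    return num / den


def naive_pooled_ttest(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def naive_best_lag(x, y, max_shift):
    """Argmax over integer shifts of the normalized overlap correlation."""
    xd = [v - sum(x) / len(x) for v in x]
    yd = [v - sum(y) / len(y) for v in y]
    best, best_s = -math.inf, 0
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            xs, ys = xd[: len(xd) - s] if s else xd, yd[s:]
        else:
            xs, ys = xd[-s:], yd[: len(yd) + s]
        nov = min(len(xs), len(ys))
        xs, ys = xs[:nov], ys[:nov]
        num = sum(a * b for a, b in zip(xs, ys))
        den = math.sqrt(sum(a * a for a in xs) * sum(b * b for b in ys))
        score = num / den if den > 0 else -math.inf
        if score > best + 1e-12 or (abs(score - best) <= 1e-12 and abs(s) < abs(best_s)):
            best, best_s = score, s
    return best_s


# -- lag estimation ----------------------------------------------------------

class TestLag:
    def test_identical_signals_have_zero_lag(self):
        x = sig(np.sin(np.arange(300) / 10))
        assert mk.estimate_lag(x, x, max_lag=2.0) == 0.0

    def test_ten_sample_delay_recovered_exactly(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=400)
        x = sig(base)
        y = sig(np.r_[np.zeros(10), base[:-10]])  # y trails x by 10 samples
        assert mk.estimate_lag(x, y, max_lag=2.0) == pytest.approx(10 / 30)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            base = rng.normal(size=120)
            shift = rng.integers(-12, 13)
            shifted = np.roll(base, shift) + rng.normal(0, 0.2, 120)
            x, y = sig(base), sig(shifted)
            expected = naive_best_lag(list(base), list(shifted), 20)
            assert mk.estimate_lag(x, y, max_lag=20 / 30) == pytest.approx(expected / 30)

    def test_noisy_lag_recovery_rate(self):
        # SNR 10 white-noise pairs: >= 95% of runs within +-1 sample
        rng = np.random.default_rng(99)
        hits = 0
        runs = 200
        for _ in range(runs):
            base = rng.normal(size=360)
            k = int(rng.integers(-30, 31))
            noisy = np.roll(base, k) + rng.normal(0, (1 / 10) ** 0.5, 360)
            lag = mk.estimate_lag(sig(base), sig(noisy), max_lag=1.5)
            if abs(lag * 30 - k) <= 1:
                hits += 1
        assert hits / runs >= 0.95

    def test_rate_mismatch_rejected(self):
        x = sig(np.sin(np.arange(300) / 10), fs=30.0)
        y = sig(np.sin(np.arange(300) / 10), fs=128.0)
        with pytest.raises(DataIntegrityError):
            mk.estimate_lag(x, y)


class TestAlign:
    def test_zero_lag_trims_to_common_span_only(self):
        x = sig(np.arange(100.0))
        y = sig(np.arange(100.0) * 2)
        xa, ya = mk.align_pair(x, y, 0.0)
        assert xa.n == ya.n == 100

    def test_ten_sample_lag_trims_symmetrically(self):
        x = sig(np.random.default_rng(0).normal(size=360))
        y = sig(np.random.default_rng(1).normal(size=360))
        xa, ya = mk.align_pair(x, y, 10 / 30)
        assert xa.n == ya.n == 350

    def test_align_then_reestimate_gives_zero_residual_lag(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=400)
        x = sig(base)
        y = sig(np.r_[np.zeros(7), base[:-7]])
        lag = mk.estimate_lag(x, y, max_lag=1.0)
        xa, ya = mk.align_pair(x, y, lag)
        assert mk.estimate_lag(xa, ya, max_lag=0.5) == 0.0


# -- NRMSE / Xcor ------------------------------------------------------------

class TestNrmse:
    def test_identical_signals_give_zero(self):
        x = sig(VEC_A)
        assert mk.nrmse(x, x) == 0.0

    def test_constant_offset_closed_form(self):
        t = np.arange(0, 10, 1 / 30)
        ref = sig(np.sin(2 * np.pi * 0.5 * t[: t.size]))
        test = sig(ref.values + 0.1)
        assert mk.nrmse(ref, test) == pytest.approx(100 * 0.1 / 2.0, rel=1e-3)

    def test_matches_naive_formula_on_fixed_vectors(self):
        assert mk.nrmse(sig(VEC_A), sig(VEC_B)) == pytest.approx(
            naive_nrmse(list(VEC_A), list(VEC_B)), abs=1e-10)

    def test_zero_range_reference_rejected(self):
        with pytest.raises(DataIntegrityError):
            mk.nrmse(sig(np.ones(20)), sig(VEC_A))

    def test_invariance_to_shared_offset_and_scale(self):
        ref, test = sig(VEC_A), sig(VEC_B)
        base = mk.nrmse(ref, test)
        shifted = mk.nrmse(sig(VEC_A + 5.0), sig(VEC_B + 5.0))
        scaled = mk.nrmse(sig(3.0 * VEC_A), sig(3.0 * VEC_B))
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base, abs=1e-9)


class TestXcor:
    def test_self_and_negated_correlation(self):
        x = sig(VEC_A)
        assert mk.xcor_zero_lag(x, x) == pytest.approx(1.0, abs=1e-12)
        assert mk.xcor_zero_lag(x, sig(-VEC_A)) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_naive_pearson_on_fixed_vectors(self):
        assert mk.xcor_zero_lag(sig(VEC_A), sig(VEC_B)) == pytest.approx(
            naive_pearson(list(VEC_A), list(VEC_B)), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DataIntegrityError):
            mk.xcor_zero_lag(sig(np.ones(20)), sig(VEC_A))

    def test_invariance_to_positive_affine_transform(self):
        base = mk.xcor_zero_lag(sig(VEC_A), sig(VEC_B))
        assert mk.xcor_zero_lag(sig(2.0 * VEC_A + 3.0), sig(VEC_B)) == pytest.approx(
            base, abs=1e-12)


# -- summary statistics ------------------------------------------------------

class TestSummaryCI:
    def test_degenerate_equal_values(self):
        out = mk.summarize_ci([4.2, 4.2, 4.2])
        assert (out.mean, out.ci_low, out.ci_high) == (4.2, 4.2, 4.2)

    def test_hand_computed_three_values(self):
        # mean 2, sd 1, t_{0.975,2} = 4.302653; CI = 2 +- 4.302653/sqrt(3)
        out = mk.summarize_ci([1.0, 2.0, 3.0])
        assert out.mean == pytest.approx(2.0)
        assert out.ci_low == pytest.approx(2.0 - 4.302653 / math.sqrt(3), abs=1e-4)
        assert out.ci_high == pytest.approx(2.0 + 4.302653 / math.sqrt(3), abs=1e-4)

    def test_coverage_of_the_t_interval(self):
        rng = np.random.default_rng(12)
        covered = 0
        reps = 1000
        for _ in range(reps):
            out = mk.summarize_ci(rng.normal(size=30))
            covered += out.ci_low <= 0.0 <= out.ci_high
        assert 0.93 <= covered / reps <= 0.97

    def test_too_few_values_rejected(self):
        with pytest.raises(DataIntegrityError):
            mk.summarize_ci([1.0])


class TestBlandAltman:
    def test_identical_pairs(self):
        out = mk.bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert out.mean_diff == out.loa_low == out.loa_high == 0.0

    def test_constant_offset(self):
        out = mk.bland_altman([(1.0, 1.5), (2.0, 2.5), (3.0, 3.5)])
        assert out.mean_diff == pytest.approx(-0.5)
        assert out.sd_diff == 0.0
        assert out.loa_low == out.loa_high == pytest.approx(-0.5)

    def test_hand_computed_example(self):
        out = mk.bland_altman([(10.0, 10.2), (12.0, 11.8), (11.0, 11.0)])
        assert out.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert out.sd_diff == pytest.approx(0.2, abs=1e-12)
        assert out.loa_low == pytest.approx(-0.392, abs=1e-10)
        assert out.loa_high == pytest.approx(+0.392, abs=1e-10)

    def test_swapping_methods_mirrors_the_limits(self):
        pairs = list(zip(VEC_A[:10], VEC_B[:10]))
        fwd = mk.bland_altman(pairs)
        rev = mk.bland_altman([(b, a) for a, b in pairs])
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff, abs=1e-12)
        assert rev.loa_low == pytest.approx(-fwd.loa_high, abs=1e-12)
        assert rev.loa_high == pytest.approx(-fwd.loa_low, abs=1e-12)

    def test_loa_width_is_1_96_sd(self):
        out = mk.bland_altman(list(zip(VEC_A, VEC_B)))
        assert out.loa_high - out.mean_diff == pytest.approx(1.96 * out.sd_diff, abs=1e-12)


class TestTTest:
    def test_identical_groups(self):
        t, p = mk.two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_pooled_formula(self):
        a, b = [1.1, 2.0, 2.9], [3.1, 4.0, 4.9]
        t, p = mk.two_sample_ttest(a, b)
        t0, p0 = naive_pooled_ttest(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_degenerate_zero_variance_contract(self):
        assert mk.two_sample_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = mk.two_sample_ttest([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and t == -math.inf

    def test_welch_flag_changes_unequal_variance_result(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 4, 30)
        t_pooled, _ = mk.two_sample_ttest(a, b)
        t_welch, _ = mk.two_sample_ttest(a, b, welch=True)
        assert t_pooled != t_welch


def test_compare_signals_end_to_end_matches_oracles():
    rng = np.random.default_rng(33)
    base = np.sin(np.arange(360) / 12) + rng.normal(0, 0.05, 360)
    shifted = np.r_[np.zeros(4), base[:-4]]
    res = mk.compare_signals(sig(base), sig(shifted), max_lag=1.0)
    assert res.lag_s == pytest.approx(4 / 30)
    ref = list(base[: 360 - 4])
    test = list(shifted[4:])
    assert res.nrmse_pct == pytest.approx(naive_nrmse(ref, test), abs=1e-10)
    assert res.xcor == pytest.approx(naive_pearson(ref, test), abs=1e-10)
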