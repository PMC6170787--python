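"""Oracle and property tests for the discriminating statistics.

Each statistic is checked against an independently coded brute-force
oracle written in plain Python loops, on deterministic pseudo-random
inputs.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surrseg.measures import (
    DegenerateSeriesError,
    HFDParams,
    SampEnParams,
    SLParams,
    higuchi_fd,
    katz_fd,
    lempel_ziv_complexity,
    sample_entropy,
    synchronization_likelihood,
)

# ---------------------------------------------------------------- oracles


def oracle_higuchi(x, k_max):
    """Step-by-step curve-length computation with plain loops."""
    x = list(map(float, x))
    n = len(x)
    log_k, log_l = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):  # 1-indexed offset
            n_int = (n - m) // k
            if n_int < 1:
                continue
            total = 0.0
            for i in range(1, n_int + 1):
                total += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
            lengths.append(total * (n - 1) / (n_int * k * k))
        log_k.append(math.log(k))
        log_l.append(math.log(sum(lengths) / len(lengths)))
    # closed-form OLS slope
    kbar = sum(log_k) / len(log_k)
    lbar = sum(log_l) / len(log_l)
    num = sum((a - kbar) * (b - lbar) for a, b in zip(log_k, log_l))
    den = sum((a - kbar) ** 2 for a in log_k)
    return -num / den


def oracle_katz(x):
    x = list(map(float, x))
    n = len(x) - 1
    total = 0.0
    for i in range(n):
        total += math.sqrt(1.0 + (x[i + 1] - x[i]) ** 2)
    extent = 0.0
    for i in range(len(x)):
        extent = max(extent, math.sqrt(i**2 + (x[i] - x[0]) ** 2))
    return math.log10(n) / (math.log10(n) + math.log10(extent / total))


def oracle_lz76(symbols):
    """Exhaustive-history parser by direct substring search."""
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    c = 0
    start = 0
    while start < n:
        end = start + 1
        # grow the word until it is NOT a substring of everything before
        # its last character (i.e. until it is novel)
        while end <= n and s[start:end] in s[: end - 1]:
            end += 1
        c += 1  # the word (novel, or exhausted at the sequence end)
        start = end
    return c


def oracle_sampen(x, m, r_factor):
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_factor * sd

    def count(length):
        nt = n - m  # both template sets range over the first n-m starts
        total = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if all(
                    abs(x[i + d] - x[j + d]) <= r for d in range(length)
                ):
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if b == 0:
        raise ZeroDivisionError
    if a == 0:
        return float("inf")
    return -math.log(a / b)


# ------------------------------------------------------------------ HFD


class TestHiguchiFD:
    def test_straight_line_is_one(self):
        x = np.arange(1000, dtype=float)
        assert higuchi_fd(x, HFDParams(k_max=8)) == pytest.approx(1.0, abs=1e-6)

    def test_line_any_slope_and_offset(self):
        x = -3.7 * np.arange(500) + 11.0
        assert higuchi_fd(x) == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_approaches_two(self):
        vals = [
            higuchi_fd(np.random.default_rng(seed).standard_normal(5000))
            for seed in range(50)
        ]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(50, 201))
            x = rng.standard_normal(n)
            k_max = int(rng.integers(2, 9))
            assert higuchi_fd(x, HFDParams(k_max=k_max)) == pytest.approx(
                oracle_higuchi(x, k_max), abs=1e-12
            )

    def test_scale_and_shift_invariant(self):
        x = np.random.default_rng(1).standard_normal(400)
        ref = higuchi_fd(x)
        assert higuchi_fd(5.0 * x - 2.0) == pytest.approx(ref, rel=1e-9)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            higuchi_fd(np.ones(500))

    def test_k_max_validation(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(10.0), HFDParams(k_max=8))
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(100.0), HFDParams(k_max=1))


# ------------------------------------------------------------------ KFD


class TestKatzFD:
    def test_monotone_line_is_one(self):
        for slope in (0.1, 1.0, -4.0):
            x = slope * np.arange(200, dtype=float)
            assert katz_fd(x) == pytest.approx(1.0, abs=1e-12)

    def test_zigzag_matches_hand_computation(self):
        x = [0.0, 1.0, 0.0, 1.0, 0.0]
        # L = 4*sqrt(2); d = max over i of sqrt(i^2 + (x_i - x_0)^2) = 4
        L = 4 * math.sqrt(2.0)
        expected = math.log10(4) / (math.log10(4) + math.log10(4 / L))
        assert katz_fd(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            assert katz_fd(x) == pytest.approx(oracle_katz(x), abs=1e-12)

    def test_shift_invariant(self):
        x = np.random.default_rng(3).standard_normal(128)
        assert katz_fd(x + 100.0) == pytest.approx(katz_fd(x), rel=1e-9)

    def test_constant_series_is_flat_line(self):
        # under the planar-curve convention a constant series is a
        # horizontal line: d = L exactly, so KFD = 1
        assert katz_fd(np.zeros(50)) == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------ LZC


class TestLempelZiv:
    def test_all_equal_sequence(self):
        # binarizes to all zeros; exhaustive history is 0 | 000...0
        res = lempel_ziv_complexity(np.ones(64))
        assert res.c == 2
        assert res.c == oracle_lz76(np.zeros(64, dtype=int))

    def test_alternating_sequence(self):
        x = np.tile([0.0, 1.0], 32)
        res = lempel_ziv_complexity(x)
        assert res.c == 3
        assert res.c == oracle_lz76((x > 0.5).astype(int))

    def test_normalization(self):
        x = np.tile([0.0, 1.0], 32)
        res = lempel_ziv_complexity(x)
        assert res.normalized == pytest.approx(res.c * np.log2(64) / 64)

    def test_matches_oracle_on_random_binary_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(20, 201))
            x = rng.standard_normal(n)
            symbols = (x > np.median(x)).astype(int)
            assert lempel_ziv_complexity(x).c == oracle_lz76(symbols)

    def test_monotone_transform_invariant(self):
        x = np.random.default_rng(5).standard_normal(200)
        assert lempel_ziv_complexity(np.exp(x)).c == lempel_ziv_complexity(x).c

    def test_ties_binarize_to_zero(self):
        # median equals the repeated value; > median is strict
        x = np.array([1.0, 1.0, 1.0, 2.0, 0.0])
        res = lempel_ziv_complexity(x)
        assert res.c == oracle_lz76([0, 0, 0, 1, 0])


# --------------------------------------------------------------- SampEn


class TestSampleEntropy:
    def test_alternating_series_is_zero(self):
        x = np.tile([1.0, -1.0], 50)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(404)
        for _ in range(100):
            n = int(rng.integers(30, 201))
            x = rng.uniform(-1, 1, n)
            m = int(rng.integers(1, 4))
            try:
                want = oracle_sampen(x, m, 0.2)
            except ZeroDivisionError:
                with pytest.raises(DegenerateSeriesError):
                    sample_entropy(x, SampEnParams(m_embed=m))
                continue
            got = sample_entropy(x, SampEnParams(m_embed=m))
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_sine_less_entropic_than_noise(self):
        t = np.arange(1000)
        sine = np.sin(2 * np.pi * t / 100.0)  # 10 cycles, 100 samples/cycle
        wins = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(1000)
            noise *= sine.std() / noise.std()
            wins += sample_entropy(sine) < sample_entropy(noise)
        assert wins == 20

    def test_scale_and_shift_invariant(self):
        x = np.random.default_rng(8).standard_normal(300)
        ref = sample_entropy(x)
        assert sample_entropy(3.0 * x + 7.0) == pytest.approx(ref, rel=1e-9)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            sample_entropy(np.full(100, 2.0))


# ------------------------------------------------------------------- SL

REDUCED = SLParams(lag_l=1, dim_m=3, n_rec=10, p_ref=0.05, w1=10, w2=210)


class TestSynchronizationLikelihood:
    def test_identical_signals_give_one(self, rng):
        x = rng.standard_normal(800)
        assert synchronization_likelihood(x, x, REDUCED) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_independent_noise_near_pref_baseline(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.standard_normal(800)
            y = r.standard_normal(800)
            vals.append(synchronization_likelihood(x, y, REDUCED))
        mean = np.mean(vals)
        assert 0.5 * REDUCED.p_ref <= mean <= 2.0 * REDUCED.p_ref

    def test_half_shared_between_baselines(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal(800)
            y = x.copy()
            y[400:] = r.standard_normal(400)
            vals.append(synchronization_likelihood(x, y, REDUCED))
        mean = np.mean(vals)
        assert 2.0 * REDUCED.p_ref < mean < 0.9

    def test_affine_invariance_per_channel(self, rng):
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        ref = synchronization_likelihood(x, y, REDUCED)
        got = synchronization_likelihood(2.0 * x - 1.0, -0.5 * y + 3.0, REDUCED)
        assert got == pytest.approx(ref, abs=1e-12)

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            synchronization_likelihood(
                rng.standard_normal(500), rng.standard_normal(400), REDUCED
            )

    def test_too_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            synchronization_likelihood(
                rng.standard_normal(50), rng.standard_normal(50), SLParams()
            )

    def test_default_params_consistency(self):
        p = SLParams()
        assert p.n_rec == round(p.p_ref * (p.w2 - p.w1))


# --------------------------------------------------- generic properties


@st.composite
def short_series(draw):
    n = draw(st.integers(min_value=30, max_value=120))
    seed = draw(st.integers(min_value=0, max_value=2**31))
    return np.random.default_rng(seed).standard_normal(n)


class TestGenericProperties:
    @given(short_series())
    @settings(max_examples=25, deadline=None)
    def test_fd_measures_in_unit_interval(self, x):
        # finite-sample HFD estimates can overshoot the ideal [1, 2]
        assert 1.0 <= higuchi_fd(x, HFDParams(k_max=4)) <= 2.5
        assert 1.0 <= katz_fd(x) <= 3.0

    @given(short_series())
    @settings(max_examples=25, deadline=None)
    def test_lzc_positive_and_deterministic(self, x):
        r1 = lempel_ziv_complexity(x)
        r2 = lempel_ziv_complexity(x)
        assert r1 == r2
        assert r1.c >= 1

    @given(short_series())
    @settings(max_examples=25, deadline=None)
    def test_sampen_non_negative(self, x):
        assert sample_entropy(x) >= 0.0


class TestEvaluateMeasures:
    def test_univariate_batch(self, rng):
        from surrseg.measures import evaluate_measures

        x = rng.standard_normal(400)
        values = evaluate_measures(x)
        by_name = {v.name: v for v in values}
        assert set(by_name) == {"HFD", "KFD", "LZC", "SampEn"}
        assert by_name["HFD"].value == pytest.approx(higuchi_fd(x))
        assert by_name["HFD"].params == {"k_max": 8}
        assert by_name["LZC"].params["c"] == lempel_ziv_complexity(x).c

    def test_sl_requires_two_channels(self, rng):
        from surrseg.measures import evaluate_measures

        with pytest.raises(ValueError, match="two-channel"):
            evaluate_measures(rng.standard_normal(800), names=("SL",))
        pair = rng.standard_normal((800, 2))
        (value,) = evaluate_measures(pair, names=("SL",), sl_params=REDUCED)
        assert 0.0 <= value.value <= 1.0

    def test_unknown_name_rejected(self, rng):
        from surrseg.measures import evaluate_measures

        with pytest.raises(KeyError):
            evaluate_measures(rng.standard_normal(100), names=("bogus",))
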