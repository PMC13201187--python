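"""HRV feature mathematics against literal brute-force oracles and the
analytic identities the formulas must satisfy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcgsleep import hrv

jj_lists = st.lists(st.floats(400.0, 1500.0), min_size=12, max_size=40)


# ---------------------------------------------------------------------- oracles

def brute_time_domain(jj):
    n = len(jj)
    mean = sum(jj) / n
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in jj) / (n - 1))
    diffs = [jj[i + 1] - jj[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d ** 2 for d in diffs) / len(diffs))
    pnn50 = sum(1 for d in diffs if abs(d) > 50) / len(diffs)
    return mean, sdnn, rmssd, pnn50


def brute_poincare(jj):
    diffs = [jj[i + 1] - jj[i] for i in range(len(jj) - 1)]
    sums = [jj[i + 1] + jj[i] for i in range(len(jj) - 1)]

    def sd(v):
        m = sum(v) / len(v)
        return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))

    return sd(diffs) / math.sqrt(2), sd(sums) / math.sqrt(2)


def brute_porta(jj):
    below = off = 0
    for i in range(len(jj) - 1):
        d = jj[i + 1] - jj[i]
        if d != 0:
            off += 1
            if d < 0:
                below += 1
    return 100.0 * below / off


def brute_renyi(jj, alpha, m, sigma):
    """Literal double loop over all embedded subsequence pairs."""
    n = len(jj) - m + 1
    rho = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            d2 = sum((jj[i + k] - jj[j + k]) ** 2 for k in range(m))
            acc += math.exp(-d2 / (2 * sigma ** 2))
        rho.append(acc / (sigma * math.sqrt(2 * math.pi)))
    total = sum(rho)
    rho = [r / total for r in rho]
    if abs(alpha - 1.0) < 1e-12:
        return -sum(r * math.log2(r) for r in rho)
    return math.log2(sum(r ** alpha for r in rho)) / (1 - alpha)


def brute_sampen_apen(jj, m, r):
    n = len(jj)
    mean = sum(jj) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in jj) / n)
    tol = r * sd

    def matches(mm, include_self):
        tpl = [jj[i:i + mm] for i in range(n - mm + 1)]
        cnt = 0
        for i in range(len(tpl)):
            for j in range(len(tpl)):
                if not include_self and i == j:
                    continue
                if max(abs(a - b) for a, b in zip(tpl[i], tpl[j])) <= tol:
                    cnt += 1
        return cnt, len(tpl)

    # SampEn over the common n - m template count
    nm = n - m
    b = 0
    for i in range(nm):
        for j in range(nm):
            if i != j and max(abs(jj[i + k] - jj[j + k]) for k in range(m)) <= tol:
                b += 1
    a, _ = matches(m + 1, include_self=False)
    sampen = -math.log(a / b)

    def phi(mm):
        tpl = [jj[i:i + mm] for i in range(n - mm + 1)]
        logs = []
        for i in range(len(tpl)):
            c = sum(1 for j in range(len(tpl))
                    if max(abs(x - y) for x, y in zip(tpl[i], tpl[j])) <= tol)
            logs.append(math.log(c / len(tpl)))
        return sum(logs) / len(logs)

    return sampen, phi(m) - phi(m + 1)


# ------------------------------------------------------------------ time domain

class TestTimeDomain:
    def test_constant_series_has_zero_variability(self):
        t = hrv.time_domain(np.full(20, 800.0))
        assert (t.sdnn, t.rmssd, t.pnn50) == (0.0, 0.0, 0.0)

    def test_single_difference_hand_values(self):
        t = hrv.time_domain([800.0, 860.0])
        assert t.rmssd == pytest.approx(60.0)
        assert t.pnn50 == 1.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        jj = 800 + 50 * rng.standard_normal(60)
        t = hrv.time_domain(jj)
        mean, sdnn, rmssd, pnn50 = brute_time_domain(list(jj))
        assert t.mean_jj == pytest.approx(mean, rel=1e-12)
        assert t.sdnn == pytest.approx(sdnn, rel=1e-12)
        assert t.rmssd == pytest.approx(rmssd, rel=1e-12)
        assert t.pnn50 == pytest.approx(pnn50)

    def test_too_short_flags_insufficient_data(self):
        with pytest.raises(hrv.InsufficientData):
            hrv.time_domain([800.0])


# ------------------------------------------------------------- frequency domain

def _sinusoid_tachogram(freq_hz, duration_s=300.0, mean_ms=800.0, amp_ms=40.0):
    t = [0.0]
    while t[-1] < duration_s:
        jj = mean_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t[-1])
        t.append(t[-1] + jj / 1000.0)
    onsets = np.array(t[1:])
    jj = mean_ms + amp_ms * np.sin(2 * np.pi * freq_hz * onsets)
    return onsets, jj


class TestFreqDomain:
    def test_lf_sinusoid_concentrates_in_lf_band(self):
        onsets, jj = _sinusoid_tachogram(0.10)
        f = hrv.freq_domain(onsets, jj)
        assert f.lf_power / (f.lf_power + f.hf_power) >= 0.95

    def test_hf_sinusoid_concentrates_in_hf_band(self):
        onsets, jj = _sinusoid_tachogram(0.30)
        f = hrv.freq_domain(onsets, jj)
        assert f.hf_power / (f.lf_power + f.hf_power) >= 0.95

    def test_normalized_units_sum_to_one(self):
        rng = np.random.default_rng(1)
        onsets = np.cumsum(rng.uniform(0.7, 0.9, 400))
        jj = 800 + 30 * rng.standard_normal(400)
        f = hrv.freq_domain(onsets, jj)
        assert f.lf_nu + f.hf_nu == pytest.approx(1.0)


# ---------------------------------------------------------------------- Poincaré

class TestPoincare:
    def test_constant_series_zero_dispersion(self):
        assert hrv.poincare_sd(np.full(10, 800.0)) == (0.0, 0.0)

    def test_alternating_series_dispersion_is_perpendicular_only(self):
        jj = np.tile([800.0, 820.0], 50)
        sd1, sd2 = hrv.poincare_sd(jj)
        # successive sums are constant -> sd2 = 0; diffs alternate +/-20
        assert sd2 == pytest.approx(0.0, abs=1e-9)
        assert sd1 == pytest.approx(20.0 / np.sqrt(2), rel=0.01)

    @settings(max_examples=30, derandomize=True)
    @given(jj_lists)
    def test_matches_direct_formula_oracle(self, jj):
        sd1, sd2 = hrv.poincare_sd(np.array(jj))
        b1, b2 = brute_poincare(jj)
        assert sd1 == pytest.approx(b1, rel=1e-9, abs=1e-9)
        assert sd2 == pytest.approx(b2, rel=1e-9, abs=1e-9)


class TestAsymmetry:
    def test_alternating_series_is_symmetric(self):
        # odd length balances the up- and down-steps exactly (20 each)
        jj = np.append(np.tile([800.0, 820.0], 20), 800.0)
        porta, guzik, *_ = hrv.asymmetry_indices(jj)
        assert porta == pytest.approx(50.0)
        assert guzik == pytest.approx(50.0)

    def test_strictly_increasing_series_has_no_points_below(self):
        porta, guzik, ehler, phase, area = hrv.asymmetry_indices(
            np.linspace(700, 900, 30))
        assert porta == 0.0
        assert guzik == pytest.approx(100.0)
        assert ehler > 0

    def test_time_reversal_complements_porta(self):
        rng = np.random.default_rng(5)
        jj = 800 + 40 * rng.standard_normal(50)
        p_fwd, *_ = hrv.asymmetry_indices(jj)
        p_rev, *_ = hrv.asymmetry_indices(jj[::-1])
        assert p_fwd + p_rev == pytest.approx(100.0)

    def test_all_points_on_identity_line_flagged(self):
        with pytest.raises(hrv.InsufficientData):
            hrv.asymmetry_indices(np.full(10, 800.0))

    @settings(max_examples=30, derandomize=True)
    @given(jj_lists)
    def test_porta_matches_counting_oracle(self, jj):
        d = np.diff(jj)
        if not np.any(d != 0):
            return
        porta, *_ = hrv.asymmetry_indices(np.array(jj))
        assert porta == pytest.approx(brute_porta(jj), abs=1e-9)


# ----------------------------------------------------------------------- STA

class TestSTA:
    def test_monotone_increasing_occupies_q1_only(self):
        sta = hrv.sta_features(np.linspace(700, 900, 20))
        assert sta.q_occupancy[0] == 1.0
        assert sta.q_occupancy[1:].sum() == 0.0

    def test_alternating_series_alternates_q2_q4(self):
        sta = hrv.sta_features(np.tile([800.0, 830.0], 20))
        assert sta.q_occupancy[1] == pytest.approx(0.5, abs=0.05)
        assert sta.q_occupancy[3] == pytest.approx(0.5, abs=0.05)
        assert sta.q_occupancy[0] == 0.0 and sta.q_occupancy[2] == 0.0

    def test_quadrant_distance_is_mean_radial_distance(self):
        jj = np.array([800.0, 810.0, 825.0, 845.0])  # diffs 10, 15, 20 -> Q1
        sta = hrv.sta_features(jj)
        expected = np.mean([np.hypot(10, 15), np.hypot(15, 20)])
        assert sta.q_dist[0] == pytest.approx(expected, rel=1e-12)

    def test_constant_series_is_degenerate(self):
        sta = hrv.sta_features(np.full(10, 800.0))
        assert sta.degenerate
        assert sta.q_occupancy.sum() == 0.0

    def test_occupancies_sum_to_one_when_populated(self):
        rng = np.random.default_rng(2)
        sta = hrv.sta_features(800 + 30 * rng.standard_normal(60))
        assert sta.q_occupancy.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------- entropy

class TestRenyi:
    def test_uniform_density_gives_log2_n_for_every_order(self):
        # constant series -> all embedded distances 0 -> uniform rho
        jj = np.full(12, 800.0)
        n = 12 - 2 + 1
        for alpha in (0.25, 0.5, 2.0, 5.0):
            assert hrv.renyi_entropy(jj, alpha) == pytest.approx(np.log2(n))

    def test_order_one_limit_converges_to_shannon(self):
        rng = np.random.default_rng(3)
        jj = 800 + 40 * rng.standard_normal(30)
        shannon = hrv.renyi_entropy(jj, 1.0, sigma=30.0)
        assert hrv.renyi_entropy(jj, 1.0 + 1e-6, sigma=30.0) == \
            pytest.approx(shannon, abs=1e-4)
        assert hrv.renyi_entropy(jj, 1.0 - 1e-6, sigma=30.0) == \
            pytest.approx(shannon, abs=1e-4)

    def test_matches_literal_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        jj = list(800 + 50 * rng.standard_normal(20))
        for alpha in (0.25, 1.0, 2.0, 5.0):
            got = hrv.renyi_entropy(np.array(jj), alpha, embed_m=2, sigma=35.0)
            assert got == pytest.approx(brute_renyi(jj, alpha, 2, 35.0),
                                        rel=1e-9)

    def test_profile_matches_individual_calls(self):
        rng = np.random.default_rng(8)
        jj = 800 + 40 * rng.standard_normal(40)
        prof = hrv.renyi_profile(jj, (0.25, 2.0), sigma=30.0)
        for alpha, h in prof.items():
            assert h == pytest.approx(hrv.renyi_entropy(jj, alpha, sigma=30.0))

    def test_entropy_non_increasing_in_order(self):
        rng = np.random.default_rng(6)
        jj = 800 + 40 * rng.standard_normal(50)
        orders = [0.25, 0.5, 1.0, 2.0, 5.0, 10.0]
        values = [hrv.renyi_entropy(jj, a, sigma=30.0) for a in orders]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError):
            hrv.renyi_entropy(np.arange(10.0), 2.0, sigma=-1.0)


class TestSampEnApEn:
    def test_constant_series_has_zero_entropy(self):
        assert hrv.sample_approx_entropy(np.full(30, 800.0)) == (0.0, 0.0)

    def test_periodic_series_less_complex_than_shuffled(self):
        rng = np.random.default_rng(9)
        periodic = np.tile([760.0, 800.0, 840.0, 800.0], 25)
        shuffled = periodic.copy()
        rng.shuffle(shuffled)
        s_p, _ = hrv.sample_approx_entropy(periodic)
        s_s, _ = hrv.sample_approx_entropy(shuffled)
        assert s_p < s_s

    def test_matches_nested_loop_oracle(self):
        # wide tolerance guarantees template matches at this short length
        rng = np.random.default_rng(10)
        jj = list(800 + 60 * rng.standard_normal(30))
        sampen, apen = hrv.sample_approx_entropy(np.array(jj), m=2, r=0.5)
        b_sampen, b_apen = brute_sampen_apen(jj, 2, 0.5)
        assert sampen == pytest.approx(b_sampen, rel=1e-9)
        assert apen == pytest.approx(b_apen, rel=1e-9)


class TestDFA:
    def test_white_noise_scaling_exponent_near_half(self):
        rng = np.random.default_rng(11)
        alphas = [hrv.dfa(rng.standard_normal(800))[0] for _ in range(20)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_scaling_exponent_near_three_halves(self):
        rng = np.random.default_rng(12)
        alphas = [hrv.dfa(np.cumsum(rng.standard_normal(800)))[0]
                  for _ in range(20)]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.1)

    def test_constant_offset_leaves_fluctuation_unchanged(self):
        rng = np.random.default_rng(13)
        x = 800 + 30 * rng.standard_normal(400)
        a1, a2 = hrv.dfa(x)
        b1, b2 = hrv.dfa(x + 500.0)
        assert a1 == pytest.approx(b1, rel=1e-9)
        assert a2 == pytest.approx(b2, rel=1e-9)


# ------------------------------------------------------------------- device HRV

class TestDeviceHRV:
    def test_constant_stroke_volume_gives_zero_rdepth(self):
        d = hrv.device_hrv(np.full(60, 1000.0), lf=10.0, hf=20.0)
        assert d.rdepth == 0.0 and d.hrv_rdepth == 0.0

    def test_equal_band_powers_pass_rdepth_through(self):
        rng = np.random.default_rng(14)
        sv = 1000 + 100 * rng.standard_normal(60)
        d = hrv.device_hrv(sv, lf=5.0, hf=5.0)
        assert d.hrv_rdepth == pytest.approx(d.rdepth)

    def test_square_wave_residual_matches_recurrence_oracle(self):
        sv = np.tile([900.0, 1100.0], 10)
        k = 0.5
        smooth = [sv[0]]
        for x in sv:
            smooth.append((1 - k) * smooth[-1] + k * x)
        expected = np.mean(np.abs(sv - np.array(smooth[1:])))
        d = hrv.device_hrv(sv, lf=10.0, hf=20.0, k=k)
        assert d.rdepth == pytest.approx(expected, rel=1e-12)
        assert d.hrv_rdepth == pytest.approx(2.0 * expected, rel=1e-12)

    def test_zero_lf_power_flagged(self):
        with pytest.raises(hrv.InsufficientData):
            hrv.device_hrv(np.ones(10), lf=0.0, hf=1.0)


# ----------------------------------------------------------- invariance properties

class TestInvariances:
    @settings(max_examples=25, derandomize=True)
    @given(jj_lists, st.floats(-200, 200))
    def test_shift_invariance(self, jj, c):
        jj = np.array(jj)
        t0, t1 = hrv.time_domain(jj), hrv.time_domain(jj + c)
        assert t1.sdnn == pytest.approx(t0.sdnn, rel=1e-6, abs=1e-6)
        assert t1.rmssd == pytest.approx(t0.rmssd, rel=1e-6, abs=1e-6)
        assert t1.mean_jj == pytest.approx(t0.mean_jj + c, rel=1e-9)
        p0, p1 = hrv.poincare_sd(jj), hrv.poincare_sd(jj + c)
        assert p1 == pytest.approx(p0, rel=1e-6, abs=1e-6)

    @settings(max_examples=25, derandomize=True)
    @given(jj_lists, st.floats(0.5, 3.0))
    def test_scale_equivariance(self, jj, lam):
        jj = np.array(jj)
        t0, t1 = hrv.time_domain(jj), hrv.time_domain(lam * jj)
        assert t1.sdnn == pytest.approx(lam * t0.sdnn, rel=1e-6, abs=1e-6)
        assert t1.rmssd == pytest.approx(lam * t0.rmssd, rel=1e-6, abs=1e-6)
        (s1a, s2a), (s1b, s2b) = hrv.poincare_sd(jj), hrv.poincare_sd(lam * jj)
        assert s1b == pytest.approx(lam * s1a, rel=1e-6, abs=1e-6)
        assert s2b == pytest.approx(lam * s2a, rel=1e-6, abs=1e-6)

    def test_shift_invariance_of_entropy_and_sta(self):
        rng = np.random.default_rng(15)
        jj = 800 + 40 * rng.standard_normal(60)
        s0 = hrv.sample_approx_entropy(jj)
        s1 = hrv.sample_approx_entropy(jj + 250.0)
        assert s1[0] == pytest.approx(s0[0], rel=1e-9)
        sta0, sta1 = hrv.sta_features(jj), hrv.sta_features(jj + 250.0)
        np.testing.assert_allclose(sta1.q_dist, sta0.q_dist, rtol=1e-9)
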